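"""Neutral-model construction: 4-fold-degenerate site extraction and
maximum-likelihood fitting of a time-reversible (REV/GTR) model on a fixed
topology.

Third codon positions of the eight four-fold codon families (CTN, GTN,
TCN, CCN, ACN, GCN, CGN, GGN) are treated as approximately neutrally
evolving; the model fitted to them is the null against which per-site
conservation/acceleration is judged. Degeneracy is judged from the
reference-species codon only, following the extraction convention of the
standard alignment tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import optimize

from .genome_tracks_io import AlignmentBlock, FeatureSet
from .phylo_likelihood import PhyloTree, compress_patterns, encode_columns, \
    pattern_log_likelihoods
from .subst_models import SubstitutionModel, build_model

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def _fourfold_third_positions() -> frozenset[str]:
    """First-two-base prefixes whose codon family is 4-fold degenerate,
    derived from the standard genetic code."""
    table = standard_dna_table.forward_table
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {table.get(b1 + b2 + b3) for b3 in "ACGT"}
            if len(aas) == 1 and None not in aas:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_third_positions()


def is_fourfold(codon: str) -> bool:
    return codon[:2].upper() in FOURFOLD_PREFIXES


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _ref_column_map(block: AlignmentBlock) -> tuple[np.ndarray, np.ndarray]:
    """(ref forward-strand positions of non-gap ref columns, column indices)."""
    ref = block.reference_row()
    text = ref.text
    cols = np.array([j for j, ch in enumerate(text) if ch != "-"], dtype=int)
    offsets = np.arange(len(cols))
    if ref.strand == "+":
        pos = ref.start + offsets
    else:
        # minus-strand reference rows: map to forward coordinates
        pos = ref.src_size - ref.start - 1 - offsets
    return pos, cols


def extract_4d_columns(blocks: list[AlignmentBlock], cds: FeatureSet,
                       ) -> list[dict]:
    """Alignment columns at 4-fold-degenerate third codon positions.

    Codons are read on the CDS strand (reverse complement for minus-strand
    CDS); a codon is used only when its three reference positions are
    consecutive, non-gap, and inside a single block. Emitted columns are
    dicts taxon -> character as stored in the alignment (forward strand),
    with gaps/N as missing.
    """
    # reference position -> (block index, column index)
    pos_map: dict[tuple[str, int], tuple[int, int]] = {}
    for bi, block in enumerate(blocks):
        ref = block.reference_row()
        pos, cols = _ref_column_map(block)
        for p, c in zip(pos, cols):
            pos_map[(ref.chrom, int(p))] = (bi, int(c))

    columns: list[dict] = []
    for iv in cds.intervals:
        strand = iv.strand or "+"
        length = len(iv) - iv.frame
        if length % 3 != 0:
            warnings.warn(
                f"CDS {iv.chrom}:{iv.start}-{iv.end} length {length} not a "
                "multiple of 3 after phase; trailing partial codon dropped")
        n_codons = length // 3
        for k in range(n_codons):
            if strand == "+":
                p0 = iv.start + iv.frame + 3 * k
                codon_pos = (p0, p0 + 1, p0 + 2)
            else:
                p0 = iv.end - 1 - iv.frame - 3 * k
                codon_pos = (p0, p0 - 1, p0 - 2)  # 5'->3' on minus strand
            hits = [pos_map.get((iv.chrom, p)) for p in codon_pos]
            if any(h is None for h in hits):
                continue
            if len({h[0] for h in hits}) != 1:
                continue  # codon straddles blocks: dropped
            bi = hits[0][0]
            block = blocks[bi]
            ref = block.reference_row()
            codon = "".join(ref.text[h[1]] for h in hits)
            if strand == "-":
                codon = codon.translate(_COMPLEMENT)
            if "N" in codon or "-" in codon or not is_fourfold(codon):
                continue
            third_col = hits[2][1]
            columns.append({r.species: r.text[third_col] for r in block.rows})
    return columns


@dataclass
class NeutralModel:
    """Fitted neutral model: tree with branch lengths + REV model."""
    tree: PhyloTree
    model: SubstitutionModel
    n_sites_fit: int = 0

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model.to_text())
            fh.write(f"n_sites_fit: {self.n_sites_fit}\n")
            fh.write(f"tree: {self.tree.to_newick()}\n")

    @staticmethod
    def load(path) -> "NeutralModel":
        with open(path) as fh:
            text = fh.read()
        tree_line = next(l for l in text.splitlines() if l.startswith("tree:"))
        n_line = next(l for l in text.splitlines() if l.startswith("n_sites_fit:"))
        tree = PhyloTree.from_newick(tree_line.partition(":")[2].strip())
        model = SubstitutionModel.from_text(text)
        return NeutralModel(tree, model, int(n_line.partition(":")[2]))


class FitError(RuntimeError):
    def __init__(self, message, best: NeutralModel | None = None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics


BL_FLOOR = 1e-8


def empirical_frequencies(encoded: np.ndarray) -> np.ndarray:
    counts = np.bincount(encoded[encoded < 4].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise FitError("no observed bases to estimate frequencies from")
    counts = np.maximum(counts, 1.0)  # pseudo-count guards all-zero bases
    return counts / counts.sum()


def fit_neutral_model(columns, topology: PhyloTree, *, min_columns: int = 100,
                      n_starts: int = 3, tol: float = 1e-6, seed: int = 0,
                      max_iter: int = 500) -> NeutralModel:
    """Fit branch lengths and REV exchangeabilities by maximum likelihood.

    Base frequencies are set empirically from the column base counts; the
    GT exchangeability is fixed at 1 for identifiability and the topology's
    root is collapsed to a trifurcation (root placement is unidentifiable
    under a reversible model). Multi-start quasi-Newton (L-BFGS-B) on
    log-transformed parameters.
    """
    if isinstance(columns, np.ndarray):
        enc = columns
        taxa = topology.leaf_labels
    else:
        columns = list(columns)
        taxa = topology.leaf_labels
        enc = encode_columns(columns, taxa)
    if enc.shape[0] < min_columns:
        raise FitError(f"need >= {min_columns} columns, got {enc.shape[0]}")
    tree = topology.unroot()
    # reorder pattern columns to the unrooted tree's leaf order
    order = [taxa.index(t) for t in tree.leaf_labels]
    pats, counts, _ = compress_patterns(enc[:, order])
    pi = empirical_frequencies(enc)

    edges = np.flatnonzero(tree.parent >= 0)
    n_edges = len(edges)

    def unpack(theta):
        bl = np.full(tree.n_nodes, 0.0)
        bl[edges] = np.exp(theta[:n_edges]) + BL_FLOOR
        exch = np.concatenate([np.exp(theta[n_edges:]), [1.0]])
        return bl, exch

    def neg_ll(theta):
        bl, exch = unpack(theta)
        model = build_model("REV", pi, exchangeabilities=exch)
        ll = np.dot(pattern_log_likelihoods(tree.with_branch_lengths(bl), model, pats),
                    counts)
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    start0 = np.concatenate([np.full(n_edges, np.log(0.05)), np.zeros(5)])
    for s in range(n_starts):
        x0 = start0 if s == 0 else start0 + rng.normal(0, 0.5, size=start0.shape)
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    bl, exch = unpack(best.x)
    model = build_model("REV", pi, exchangeabilities=exch)
    fitted = NeutralModel(tree.with_branch_lengths(bl), model, int(enc.shape[0]))
    if not (best.success or best.fun <= neg_ll(start0) + 1e-6):
        raise FitError(f"optimizer did not converge: {best.message}",
                       best=fitted, diagnostics=best)
    return fitted
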