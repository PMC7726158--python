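"""Synthetic multi-species genomes with known evolutionary ground truth.

The simulator evolves an ancestral sequence down a phylogeny by sampling
child states from the model's transition probabilities, region by region
at designated rate multipliers rho (rho < 1 conserved, 1 neutral, > 1
accelerated). The default scenario emulates the structure of a five-way
cichlid alignment: codon-structured CDS (supplying four-fold-degenerate
sites), UTRs and introns under moderate constraint, neutral intergenic
background and ancestral-repeat-like (AR) regions, and small numbers of
novel-ORF regions — 9 intergenic ones evolving fast and 27 intronic ones
evolving slow, echoing the mapped region counts of the study design.

Everything is a pure function of (plan, seed); a TruthManifest records
the per-region truth for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genome_tracks_io import AlignmentBlock, FeatureSet, GenomicInterval, MafRow
from .neutral_fit import FOURFOLD_PREFIXES
from .phylo_likelihood import PhyloTree
from .subst_models import BASES, SubstitutionModel, build_model, \
    transition_matrix

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASE_ARR = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class Region:
    label: str
    length: int
    rate_scale: float
    codon_structured: bool = False

    def __post_init__(self):
        if self.length < 1 or self.rate_scale < 0:
            raise ValueError("region needs length >= 1 and rate_scale >= 0")
        if self.codon_structured and self.length % 3 != 0:
            raise ValueError("codon-structured region length must be a multiple of 3")


@dataclass
class RegionPlan:
    regions: list[Region]
    taxa: list[str]
    tree: PhyloTree
    model: SubstitutionModel
    seed: int
    chrom: str = "chrSim"
    block_size: int = 10_000

    def total_length(self) -> int:
        return sum(r.length for r in self.regions)


@dataclass
class TruthManifest:
    regions: list[dict]  # {start, end, label, rate_scale}
    tree_newick: str
    model_text: str
    clock: dict | None = None

    def to_json(self) -> str:
        return json.dumps({"regions": self.regions, "tree": self.tree_newick,
                           "model": self.model_text, "clock": self.clock}, indent=1)

    @staticmethod
    def from_json(text: str) -> "TruthManifest":
        d = json.loads(text)
        return TruthManifest(d["regions"], d["tree"], d["model"], d.get("clock"))


def _sample_ancestor(rng, model, region: Region) -> np.ndarray:
    """Ancestral states; codon regions avoid stop codons by rejection."""
    if not region.codon_structured:
        return rng.choice(4, size=region.length, p=model.pi)
    out = np.empty(region.length, dtype=np.int64)
    for k in range(region.length // 3):
        while True:
            codon = rng.choice(4, size=3, p=model.pi)
            if "".join(BASES[c] for c in codon) not in STOP_CODONS:
                break
        out[3 * k: 3 * k + 3] = codon
    return out


def _site_scales(region: Region, ancestor: np.ndarray) -> np.ndarray:
    """Per-site rho: third positions of 4-fold ancestral codons evolve
    neutrally (rho = 1) inside codon-structured regions, so 4D extraction
    finds genuinely neutral sites."""
    scales = np.full(region.length, region.rate_scale)
    if region.codon_structured:
        for k in range(region.length // 3):
            prefix = BASES[ancestor[3 * k]] + BASES[ancestor[3 * k + 1]]
            if prefix in FOURFOLD_PREFIXES:
                scales[3 * k + 2] = 1.0
    return scales


def _evolve(tree: PhyloTree, model: SubstitutionModel, ancestor: np.ndarray,
            scales: np.ndarray, rng) -> dict[str, np.ndarray]:
    """Evolve states down the tree; distinct rho values share P-matrix sets."""
    states = {tree.root: ancestor}
    uniq = np.unique(scales)
    groups = {float(u): np.flatnonzero(scales == u) for u in uniq}
    for node in reversed(tree.postorder):  # preorder
        if node == tree.root:
            continue
        parent_states = states[tree.parent[node]]
        child = np.empty_like(parent_states)
        t = tree.branch_lengths[node]
        for u, idx in groups.items():
            P = transition_matrix(model, t * u)
            cum = np.cumsum(P, axis=1)
            r = rng.random(len(idx))
            child[idx] = (r[:, None] > cum[parent_states[idx]]).sum(axis=1)
        states[node] = child
    return {tree.taxa[i]: states[i] for i in tree.leaves}


def simulate_alignment(plan: RegionPlan,
                       ) -> tuple[list[AlignmentBlock], dict[str, FeatureSet],
                                  TruthManifest]:
    """Simulate the planned genome; returns gap-free MAF blocks over one
    synthetic reference chrom, per-label FeatureSets, and the truth."""
    rng = np.random.default_rng(plan.seed)
    tree = plan.tree
    if len(tree.leaf_labels) < 2:
        raise ValueError("tree needs >= 2 taxa")
    total = plan.total_length()
    seqs = {t: np.empty(total, dtype=np.int64) for t in tree.leaf_labels}
    manifest_regions = []
    intervals: dict[str, list[GenomicInterval]] = {}
    pos = 0
    for region in plan.regions:
        ancestor = _sample_ancestor(rng, plan.model, region)
        scales = _site_scales(region, ancestor)
        evolved = _evolve(tree, plan.model, ancestor, scales, rng)
        for t, arr in evolved.items():
            seqs[t][pos:pos + region.length] = arr
        iv = GenomicInterval(plan.chrom, pos, pos + region.length,
                             name=region.label,
                             strand="+" if region.codon_structured else None)
        intervals.setdefault(region.label, []).append(iv)
        manifest_regions.append({"start": pos, "end": pos + region.length,
                                 "label": region.label,
                                 "rate_scale": region.rate_scale})
        pos += region.length

    reference = plan.taxa[0]
    blocks = []
    for start in range(0, total, plan.block_size):
        end = min(start + plan.block_size, total)
        rows = []
        for t in plan.taxa:
            text = "".join(BASE_ARR[seqs[t][start:end]])
            rows.append(MafRow(t, plan.chrom, start, end - start, "+", total, text))
        blocks.append(AlignmentBlock(tuple(rows), reference_species=reference))

    features = {label: FeatureSet(label, ivs) for label, ivs in intervals.items()}
    manifest = TruthManifest(manifest_regions, tree.to_newick(),
                             plan.model.to_text())
    return blocks, features, manifest


def simulate_clock_sequences(topology: PhyloTree, node_ages: dict[frozenset, float],
                             clock_rate: float, length: int,
                             model: SubstitutionModel, seed: int,
                             ) -> dict[str, str]:
    """Evolve sequences on a clock tree: branch length = clock_rate x
    (parent age - child age). ``node_ages`` maps each internal clade
    (frozenset of descendant taxa) to its age in MY; leaves are at age 0."""
    from .clock_dating import _clades  # local import avoids a cycle

    if length < 1:
        raise ValueError("length must be >= 1")
    clades = _clades(topology)
    ages = np.zeros(topology.n_nodes)
    for i in topology.postorder:
        if topology.taxa[i] is None:
            ages[i] = node_ages[clades[i]]
    bl = np.zeros(topology.n_nodes)
    for i in range(topology.n_nodes):
        p = topology.parent[i]
        if p >= 0:
            if ages[p] <= ages[i] - 1e-12:
                raise ValueError(
                    f"child clade {sorted(clades[i])} older than its parent")
            bl[i] = clock_rate * (ages[p] - ages[i])
    clock_tree = topology.with_branch_lengths(bl)
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(4, size=length, p=model.pi)
    evolved = _evolve(clock_tree, model, ancestor, np.ones(length), rng)
    return {t: "".join(BASE_ARR[arr]) for t, arr in
            sorted(evolved.items())}


# --------------------------------------------------------------------------
# default five-taxon scenario
# --------------------------------------------------------------------------

CICHLID_TAXA = ["oreNil", "neoBri", "astBur", "metZeb", "punNye"]

#: cichlid-shaped topology; total length ~1 substitution/site so that
#: per-site rate tests carry signal at desk scale
CICHLID_TREE = ("(((punNye:0.08,metZeb:0.08):0.07,astBur:0.15):0.1,"
                "neoBri:0.25):0.05,oreNil:0.3")


def cichlid_tree() -> PhyloTree:
    return PhyloTree.from_newick("(" + CICHLID_TREE + ");")


def cichlid_model() -> SubstitutionModel:
    """GC-poor fish-like composition with transition bias."""
    return build_model("REV", [0.30, 0.20, 0.20, 0.30],
                       exchangeabilities=[1.0, 3.0, 0.8, 0.9, 3.2, 1.0])


def default_cichlid_scenario(seed: int = 42) -> RegionPlan:
    """Ready-made plan mirroring the study's feature structure.

    Rates: CDS 0.3 (codon-structured), UTRs 0.7, introns 0.9, intergenic
    and AR background 1.0, 9 novel-intergenic regions at 2.0, 27
    novel-intronic regions at 0.5, and >= 200 AR regions with a spread of
    lengths for length matching.
    """
    rng = np.random.default_rng(seed)
    regions: list[Region] = []

    def inter(lo=150, hi=600):
        return Region("intergenic", int(rng.integers(lo, hi)), 1.0)

    # gene-like units: 5'UTR - CDS - intron - CDS - 3'UTR
    for _ in range(30):
        regions.append(inter())
        regions.append(Region("5UTR", int(rng.integers(100, 300)), 0.7))
        regions.append(Region("CDS", 3 * int(rng.integers(60, 160)), 0.3,
                              codon_structured=True))
        regions.append(Region("intron", int(rng.integers(200, 800)), 0.9))
        regions.append(Region("CDS", 3 * int(rng.integers(60, 160)), 0.3,
                              codon_structured=True))
        regions.append(Region("3UTR", int(rng.integers(100, 300)), 0.7))
    # ancestral repeats: realistic right-skewed length distribution
    for _ in range(220):
        regions.append(inter(80, 300))
        length = int(np.clip(rng.lognormal(np.log(300), 0.5), 80, 2000))
        regions.append(Region("AR", length, 1.0))
    # novel regions (counts echo the mapped novel transcripts: 9 and 27)
    for _ in range(9):
        regions.append(inter())
        regions.append(Region("nORF-intergenic", int(rng.integers(250, 600)), 2.0))
    for _ in range(27):
        regions.append(inter())
        regions.append(Region("nORF-intronic", int(rng.integers(250, 600)), 0.5))
    regions.append(inter())
    perm = rng.permutation(len(regions))
    regions = [regions[i] for i in perm]
    return RegionPlan(regions=regions, taxa=list(CICHLID_TAXA),
                      tree=cichlid_tree(), model=cichlid_model(), seed=seed)
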