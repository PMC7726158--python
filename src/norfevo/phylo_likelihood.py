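"""Rooted phylogenies and Felsenstein-pruning likelihoods of alignment columns.

The tree is stored as flat arrays (postorder node list, parent indices,
branch lengths) so the pruning recursion vectorizes across many site
patterns at once. Missing observations ('-' or 'N') contribute a partial
vector of ones, i.e. they are marginalized out. Per-node renormalization
with accumulated log factors guards against underflow on long trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .subst_models import BASE_INDEX, SubstitutionModel, transition_matrices

MISSING = 4  # state code for '-' / 'N'


class TreeError(ValueError):
    pass


class LabelMismatchError(KeyError):
    """A column references a taxon absent from the tree (or vice versa)."""


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths in expected substitutions per site.

    Nodes are indexed in postorder with the root last; leaves carry taxon
    labels. ``parent[i]`` is the parent index (-1 for root) and
    ``branch_lengths[i]`` is the length of the edge above node ``i``.
    """

    parent: np.ndarray
    branch_lengths: np.ndarray
    children: list[list[int]]
    taxa: list[str | None]  # label for leaves, None for internal nodes
    postorder: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.parent)
        if len(self.branch_lengths) != n or len(self.taxa) != n:
            raise TreeError("inconsistent node arrays")
        if np.any(self.branch_lengths < 0) or np.any(~np.isfinite(self.branch_lengths)):
            raise TreeError("branch lengths must be finite and >= 0")
        labels = [t for t in self.taxa if t is not None]
        if len(set(labels)) != len(labels):
            raise TreeError("taxon labels must be unique")
        order = []
        def visit(i):
            for c in self.children[i]:
                visit(c)
            order.append(i)
        visit(self.root)
        self.postorder = np.array(order)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaf_labels(self) -> list[str]:
        return [t for t in self.taxa if t is not None]

    @property
    def leaves(self) -> list[int]:
        return [i for i, t in enumerate(self.taxa) if t is not None]

    def total_length(self) -> float:
        return float(self.branch_lengths[self.parent >= 0].sum())

    def with_branch_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), np.asarray(lengths, float).copy(),
                         [list(c) for c in self.children], list(self.taxa))

    def scaled(self, factor: float) -> "PhyloTree":
        return self.with_branch_lengths(self.branch_lengths * factor)

    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation.

        Under a reversible model only the sum of the two root-adjacent
        branch lengths is identifiable; fitting is done on this form.
        """
        root = self.root
        if len(self.children[root]) != 2:
            return self
        a, b = self.children[root]
        # merge the shorter-subtree child into the other's branch
        absorb, keep = (a, b) if self.taxa[a] is None else (b, a)
        if self.taxa[absorb] is not None and self.taxa[keep] is not None:
            return self  # two-leaf tree: nothing to collapse
        new_parent = self.parent.copy()
        new_bl = self.branch_lengths.copy()
        children = [list(c) for c in self.children]
        for c in children[absorb]:
            new_parent[c] = root
        children[root] = [c for c in children[root] if c != absorb] + children[absorb]
        new_bl[keep] = new_bl[keep] + new_bl[absorb]
        # drop node `absorb` by compacting indices
        keep_idx = [i for i in range(self.n_nodes) if i != absorb]
        remap = {old: new for new, old in enumerate(keep_idx)}
        parent = np.array([remap[new_parent[i]] if new_parent[i] >= 0 else -1
                           for i in keep_idx])
        bl = new_bl[keep_idx]
        ch = [[remap[c] for c in children[i]] for i in keep_idx]
        taxa = [self.taxa[i] for i in keep_idx]
        return PhyloTree(parent, bl, ch, taxa)

    # ----- newick -----
    def to_newick(self) -> str:
        def fmt(i):
            if self.taxa[i] is not None:
                s = self.taxa[i]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0:
                s += f":{self.branch_lengths[i]:.10g}"
            return s
        return fmt(self.root) + ";"

    @staticmethod
    def from_newick(newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return PhyloTree.from_dendropy(dt)

    @staticmethod
    def from_dendropy(dt: dendropy.Tree) -> "PhyloTree":
        nodes = list(dt.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        bl = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        taxa: list[str | None] = [None] * len(nodes)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                bl[i] = n.edge.length if n.edge.length is not None else 0.0
            if n.is_leaf():
                taxa[i] = n.taxon.label if n.taxon is not None else None
        return PhyloTree(parent, bl, children, taxa)

    @staticmethod
    def read(path) -> "PhyloTree":
        with open(path) as fh:
            return PhyloTree.from_newick(fh.read())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


# ----- columns and patterns -----

def encode_columns(columns, taxa: list[str]) -> np.ndarray:
    """Encode SiteColumns (taxon -> base char) as an int matrix (ncol, ntaxa).

    States 0..3 for A,C,G,T; 4 for missing ('-', 'N', or absent key only if
    explicitly present as missing — an absent taxon raises).
    """
    out = np.empty((len(columns), len(taxa)), dtype=np.int8)
    for i, col in enumerate(columns):
        for j, taxon in enumerate(taxa):
            try:
                ch = col[taxon]
            except KeyError:
                raise LabelMismatchError(
                    f"column {i} lacks an entry for taxon {taxon!r}") from None
            out[i, j] = BASE_INDEX.get(ch.upper(), MISSING)
    return out


def compress_patterns(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and the inverse index."""
    pats, inverse, counts = np.unique(encoded, axis=0, return_inverse=True,
                                      return_counts=True)
    return pats, counts, inverse


def pattern_log_likelihoods(tree: PhyloTree, model: SubstitutionModel,
                            patterns: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Log-likelihood of each site pattern under the model with all branch
    lengths multiplied by ``scale`` (the all-branches rate parameter).

    ``patterns`` is (npat, ntaxa) int8 with taxa ordered as ``tree.leaf_labels``.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    npat = patterns.shape[0]
    leaves = tree.leaves
    if patterns.shape[1] != len(leaves):
        raise LabelMismatchError(
            f"patterns have {patterns.shape[1]} taxa, tree has {len(leaves)}")
    P = transition_matrices(model, tree.branch_lengths * scale)
    partial = np.ones((tree.n_nodes, npat, 4))
    for j, node in enumerate(leaves):
        states = patterns[:, j]
        obs = states < 4
        partial[node][obs] = np.eye(4)[states[obs]]
    log_factor = np.zeros(npat)
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        acc = np.ones((npat, 4))
        for c in kids:
            acc *= partial[c] @ P[c].T
        m = acc.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        partial[node] = acc / m[:, None]
        log_factor += np.log(m)
    lik = partial[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_factor


def column_log_likelihood(tree: PhyloTree, model: SubstitutionModel,
                          column: dict, scale: float = 1.0) -> float:
    """Pruning log-likelihood of a single column (taxon -> state char)."""
    extra = set(column) - set(tree.leaf_labels)
    if extra:
        raise LabelMismatchError(f"column taxa not in tree: {sorted(extra)}")
    enc = encode_columns([column], tree.leaf_labels)
    return float(pattern_log_likelihoods(tree, model, enc, scale)[0])


def total_log_likelihood(tree: PhyloTree, model: SubstitutionModel,
                         columns, scale: float = 1.0) -> float:
    """Sum of per-column log-likelihoods (independent sites)."""
    if len(columns) == 0:
        raise ValueError("column list must be non-empty")
    if isinstance(columns, np.ndarray):
        enc = columns
    else:
        enc = encode_columns(list(columns), tree.leaf_labels)
    pats, counts, _ = compress_patterns(enc)
    return float(np.dot(pattern_log_likelihoods(tree, model, pats, scale), counts))
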