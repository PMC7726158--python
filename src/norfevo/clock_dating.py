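"""Strict-molecular-clock Bayesian divergence-time estimation.

A Metropolis–Hastings sampler over internal node ages of a fixed topology:
the likelihood is the pruning likelihood of the alignment on the clock
tree (branch length = clock_rate x age difference x optional per-locus
rate multiplier), the tree prior is a Yule (pure-birth) density over node
ages with the birth rate sampled under a broad exponential hyperprior, and
one designated MRCA carries a lognormal fossil calibration parameterized
by its REAL-SPACE mean and standard deviation (e.g. 45.5 +/- 0.5 million
years for the cichlid crown group). A zero-column alignment gives a
constant likelihood, which is the prior-only mode used to verify
calibration recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phylo_likelihood import PhyloTree, compress_patterns
from .subst_models import BASE_INDEX, SubstitutionModel

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


def lognormal_from_real_moments(mean_real: float, sd_real: float,
                                ) -> tuple[float, float]:
    """Log-space (mu, sigma) of the lognormal with the given real-space
    mean and standard deviation: sigma^2 = ln(1 + (sd/mean)^2),
    mu = ln(mean) - sigma^2 / 2."""
    if mean_real <= 0 or sd_real <= 0:
        raise ConfigurationError("real-space mean and sd must be positive")
    sigma2 = np.log1p((sd_real / mean_real) ** 2)
    mu = np.log(mean_real) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class CalibrationPrior:
    """Lognormal age calibration on the MRCA of a taxon set."""
    node: frozenset
    mean_real: float
    sd_real: float
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self):
        mu, sigma = lognormal_from_real_moments(self.mean_real, self.sd_real)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    def log_density(self, age: float) -> float:
        if age <= 0:
            return -np.inf
        z = (np.log(age) - self.mu) / self.sigma
        return -np.log(age * self.sigma * np.sqrt(2 * np.pi)) - 0.5 * z * z


@dataclass
class DatingConfig:
    model: SubstitutionModel
    clock_rate: float  # substitutions / site / MY — no default on purpose
    chain_length: int = 1_000_000
    burn_in: float = 0.1
    thinning: int | None = None  # None: thin to ~10,000 retained samples
    seed: int = 0
    birth_rate: float | None = None  # None: sampled (Exp hyperprior, mean 10)
    birth_rate_hyper_mean: float = 10.0
    rate_multiplier: float = 1.0  # per-locus deviation from the neutral rate

    def __post_init__(self):
        if self.chain_length < 1000:
            raise ConfigurationError("chain_length must be >= 1000")
        if not (0 <= self.burn_in < 1):
            raise ConfigurationError("burn_in must be in [0, 1)")
        if self.clock_rate <= 0:
            raise ConfigurationError("clock_rate must be > 0")


@dataclass
class DatingResult:
    """Posterior samples of internal node ages (MY), identified by clade."""
    clades: list[frozenset]
    age_samples: np.ndarray  # (n_samples, n_internal)
    birth_rate_samples: np.ndarray
    log_posterior: np.ndarray
    acceptance: dict[str, float]

    def clade_index(self, clade: frozenset) -> int:
        return self.clades.index(clade)


def _clades(tree: PhyloTree) -> list[frozenset]:
    clade = [frozenset() for _ in range(tree.n_nodes)]
    for i in tree.postorder:
        if tree.taxa[i] is not None:
            clade[i] = frozenset([tree.taxa[i]])
        else:
            clade[i] = frozenset().union(*(clade[c] for c in tree.children[i]))
    return clade


def mrca_clade(tree: PhyloTree, taxa) -> tuple[int, frozenset]:
    """Node index and clade of the MRCA of a taxon set."""
    taxa = frozenset(taxa)
    unknown = taxa - set(tree.leaf_labels)
    if unknown:
        raise ConfigurationError(f"unknown taxa: {sorted(unknown)}")
    clades = _clades(tree)
    best = None
    for i, cl in enumerate(clades):
        if taxa <= cl and (best is None or len(cl) < len(clades[best])):
            best = i
    return best, clades[best]


def _encode_alignment(sequences: dict[str, str], taxa: list[str]) -> np.ndarray:
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ConfigurationError(f"sequences of unequal length: {sorted(lengths)}")
    missing = set(taxa) - set(sequences)
    if missing:
        raise ConfigurationError(f"no sequence for taxa: {sorted(missing)}")
    length = lengths.pop() if lengths else 0
    enc = np.full((length, len(taxa)), 4, dtype=np.int8)
    for j, t in enumerate(taxa):
        enc[:, j] = [BASE_INDEX.get(ch, 4) for ch in sequences[t].upper()]
    return enc


def run_mcmc(sequences: dict[str, str], topology: PhyloTree,
             calibration: CalibrationPrior, config: DatingConfig,
             ) -> DatingResult:
    """Sample internal node ages under strict-clock likelihood x Yule prior
    x lognormal calibration. Identical seed and config give an identical
    trace."""
    tree = topology
    taxa = tree.leaf_labels
    n_tips = len(taxa)
    internal = [i for i in tree.postorder if tree.taxa[i] is None]
    n_int = len(internal)
    int_index = {node: k for k, node in enumerate(internal)}
    root = tree.root
    clades = _clades(tree)

    calib_node, calib_clade = mrca_clade(tree, calibration.node)
    if calib_clade != frozenset(calibration.node):
        raise ConfigurationError(
            f"calibrated taxa {sorted(calibration.node)} are not monophyletic "
            f"(MRCA clade is {sorted(calib_clade)})")

    enc = _encode_alignment(sequences, taxa)
    has_data = enc.shape[0] > 0
    if has_data:
        pats, counts, _ = compress_patterns(enc)
        # precomputed pruning workspace: leaf one-hot partials and the
        # model eigensystem, so a likelihood evaluation allocates nothing
        # tree-shaped per MCMC step
        vals, right, left = config.model._eig
        leaf_partial = {}
        eye5 = np.vstack([np.eye(4), np.ones(4)])
        for j, node in enumerate(tree.leaves):
            leaf_partial[node] = eye5[pats[:, j]]
        edges = np.flatnonzero(tree.parent >= 0)
        edge_pos = {int(e): k for k, e in enumerate(edges)}

    # node depth (edges to root) for initial age spreading
    depth = np.zeros(tree.n_nodes, dtype=int)
    for i in reversed(tree.postorder):  # preorder
        for c in tree.children[i]:
            depth[c] = depth[i] + 1
    max_depth = max(depth[i] for i in tree.leaves)

    ages = np.zeros(tree.n_nodes)
    root_age0 = calibration.mean_real
    for i in internal:
        ages[i] = root_age0 * (1.0 - depth[i] / (max_depth + 1))
    ages[root] = root_age0

    rng = np.random.default_rng(config.seed)
    lam = config.birth_rate if config.birth_rate is not None else \
        1.0 / config.birth_rate_hyper_mean
    sample_lam = config.birth_rate is None
    hyper_rate = 1.0 / config.birth_rate_hyper_mean

    def log_likelihood(a: np.ndarray) -> float:
        if not has_data:
            return 0.0
        ts = (a[tree.parent[edges]] - a[edges]) * \
            config.clock_rate * config.rate_multiplier
        P = np.einsum("ij,nj,jk->nik", right, np.exp(np.outer(ts, vals)), left)
        np.clip(P, 0.0, None, out=P)
        partial = {}
        for node in tree.postorder:
            kids = tree.children[node]
            if not kids:
                partial[node] = leaf_partial[node]
                continue
            acc = None
            for c in kids:
                term = partial[c] @ P[edge_pos[c]].T
                acc = term if acc is None else acc * term
            partial[node] = acc
        lik = partial[root] @ config.model.pi
        return float(np.dot(np.log(lik), counts))

    def log_prior(a: np.ndarray, lam_: float) -> float:
        total_internal_age = sum(a[i] for i in internal)
        lp = (n_tips - 1) * np.log(lam_) - lam_ * total_internal_age
        lp += calibration.log_density(a[calib_node])
        return lp

    def valid(a: np.ndarray) -> bool:
        for i in internal:
            for c in tree.children[i]:
                if a[c] >= a[i]:
                    return False
        return True

    ll = log_likelihood(ages)
    lp = log_prior(ages, lam)

    burn = int(config.chain_length * config.burn_in)
    post = config.chain_length - burn
    thin = config.thinning or max(1, post // 10_000)
    root_step = 0.05   # log-scale step for root age
    tree_step = 0.02   # log-scale step for whole-tree scale
    proposed = {"slide": 0, "root": 0, "tree_scale": 0}
    accepted = {"slide": 0, "root": 0, "tree_scale": 0}

    kept_ages, kept_lam, kept_lpost = [], [], []
    n_ops = 3
    for step in range(config.chain_length):
        op = rng.integers(n_ops)
        new_ages = ages
        log_hastings = 0.0
        if op == 0:  # single internal non-root node: uniform slide in window
            kind = "slide"
            free = [i for i in internal if i != root]
            if free:
                node = free[rng.integers(len(free))]
                lo = max(ages[c] for c in tree.children[node])
                hi = ages[tree.parent[node]]
                new_ages = ages.copy()
                new_ages[node] = lo + rng.random() * (hi - lo)
            else:
                kind, node = "root", root  # 2-taxon tree: only the root moves
                u = (rng.random() - 0.5) * 2 * root_step
                new_ages = ages.copy()
                new_ages[root] = ages[root] * np.exp(u)
                log_hastings = u
        elif op == 1:  # root age log-scale move
            kind = "root"
            u = (rng.random() - 0.5) * 2 * root_step
            new_ages = ages.copy()
            new_ages[root] = ages[root] * np.exp(u)
            log_hastings = u
        else:  # whole-tree scale
            kind = "tree_scale"
            u = (rng.random() - 0.5) * 2 * tree_step
            m = np.exp(u)
            new_ages = ages.copy()
            for i in internal:
                new_ages[i] *= m
            log_hastings = n_int * u
        proposed[kind] += 1
        if valid(new_ages):
            new_ll = log_likelihood(new_ages)
            new_lp = log_prior(new_ages, lam)
            if np.log(rng.random() + 1e-300) < \
                    (new_ll + new_lp) - (ll + lp) + log_hastings:
                ages, ll, lp = new_ages, new_ll, new_lp
                accepted[kind] += 1
        if sample_lam:
            # Gibbs: lambda | ages ~ Gamma(n_tips, sum_ages + hyper rate)
            total_internal_age = sum(ages[i] for i in internal)
            lam = rng.gamma(n_tips, 1.0 / (total_internal_age + hyper_rate))
            lp = log_prior(ages, lam)
        if step < burn and step > 0 and step % 500 == 0:
            # auto-tune scale steps toward ~30% acceptance (burn-in only)
            for key, ref in (("root", root_step), ("tree_scale", tree_step)):
                if proposed[key] >= 50:
                    rate = accepted[key] / proposed[key]
                    factor = np.exp(np.clip(rate - 0.3, -0.5, 0.5))
                    if key == "root":
                        root_step = float(np.clip(root_step * factor, 1e-4, 2.0))
                    else:
                        tree_step = float(np.clip(tree_step * factor, 1e-4, 2.0))
                    proposed[key] = accepted[key] = 0
        if step >= burn and (step - burn) % thin == 0:
            kept_ages.append([ages[i] for i in internal])
            kept_lam.append(lam)
            kept_lpost.append(ll + lp)

    acc = {k: (accepted[k] / proposed[k] if proposed[k] else float("nan"))
           for k in proposed}
    return DatingResult(
        clades=[clades[i] for i in internal],
        age_samples=np.array(kept_ages),
        birth_rate_samples=np.array(kept_lam),
        log_posterior=np.array(kept_lpost),
        acceptance=acc,
    )


@dataclass
class TmrcaSummary:
    mean: float
    median: float
    ci_low: float
    ci_high: float
    n_samples: int


def tmrca(result: DatingResult, taxa, topology: PhyloTree) -> TmrcaSummary:
    """Posterior summary of the MRCA age of a taxon pair (or set)."""
    _, clade = mrca_clade(topology, taxa)
    samples = result.age_samples[:, result.clade_index(clade)]
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return TmrcaSummary(float(samples.mean()), float(np.median(samples)),
                        float(lo), float(hi), len(samples))
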