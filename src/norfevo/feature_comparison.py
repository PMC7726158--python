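"""Mapping site scores onto genomic features and comparing feature classes.

Score distributions of annotation classes (CDS, UTRs, introns, intergenic,
ancestral repeats, novel regions) are compared by ECDF and Welch's
unequal-variance t-test. Because novel regions are few relative to
ancestral repeats (AR), significance is assessed by repeatedly drawing one
length-matched AR per novel region and testing the pooled per-site score
distributions — the length-matched resampling procedure, 10,000 iterations
at alpha = 0.05 in the full-scale analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .conacc_scoring import SiteScoreTrack
from .genome_tracks_io import FeatureSet, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class FeatureScores:
    """Per-interval site scores for one feature class.

    ``region_score`` of an interval is the mean of its per-site scores
    (the region-level aggregation); intervals with no scored site are
    reported as unmapped and excluded from distributions.
    """
    label: str
    intervals: list[GenomicInterval]
    per_interval: list[np.ndarray]
    unmapped: list[GenomicInterval] = field(default_factory=list)

    @property
    def region_scores(self) -> np.ndarray:
        return np.array([s.mean() for s in self.per_interval])

    @property
    def pooled(self) -> np.ndarray:
        if not self.per_interval:
            return np.array([])
        return np.concatenate(self.per_interval)

    @property
    def n_scored_sites(self) -> int:
        return int(sum(len(s) for s in self.per_interval))


def map_scores(track: SiteScoreTrack, features: FeatureSet) -> FeatureScores:
    """Assign every scored site to each overlapping interval (half-open)."""
    arrays = track.site_arrays()
    mapped, per_interval, unmapped = [], [], []
    for iv in features.intervals:
        if iv.chrom not in arrays:
            unmapped.append(iv)
            continue
        pos, val = arrays[iv.chrom]
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        if hi > lo:
            mapped.append(iv)
            per_interval.append(val[lo:hi])
        else:
            unmapped.append(iv)
    if unmapped:
        log.info("%s: %d/%d intervals had no scored site", features.label,
                 len(unmapped), len(features.intervals))
    return FeatureScores(features.label, mapped, per_interval, unmapped)


def ecdf(scores) -> list[tuple[float, float]]:
    """Right-continuous ECDF on sorted unique values; last fraction is 1."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("ecdf of empty sample")
    values, counts = np.unique(scores, return_counts=True)
    frac = np.cumsum(counts) / scores.size
    return list(zip(values.tolist(), frac.tolist()))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


LENGTH_TOL_BP = 20
LENGTH_TOL_FRAC = 0.10


def _length_tolerance(target_len: int) -> float:
    return max(LENGTH_TOL_BP, LENGTH_TOL_FRAC * target_len)


def _candidate_lists(ar: FeatureSet, targets: FeatureSet) -> list[np.ndarray]:
    """Per-target indices of length-matched AR intervals (nearest fallback)."""
    ar_lens = np.array([len(iv) for iv in ar.intervals])
    out = []
    for iv in targets.intervals:
        tol = _length_tolerance(len(iv))
        cand = np.flatnonzero(np.abs(ar_lens - len(iv)) <= tol)
        if cand.size == 0:
            nearest = int(np.argmin(np.abs(ar_lens - len(iv))))
            log.warning("no AR within %.0f bp of target length %d; using "
                        "nearest (length %d)", tol, len(iv), ar_lens[nearest])
            cand = np.array([nearest])
        out.append(cand)
    return out


def length_matched_sample(ar: FeatureSet, targets: FeatureSet,
                          rng_seed) -> list[GenomicInterval]:
    """One uniformly drawn length-matched AR interval per target.

    Matching tolerance is max(20 bp, 10% of the target length); when no AR
    falls within tolerance the globally nearest-length AR is used.
    """
    if len(ar) == 0:
        raise ValueError("AR feature set is empty")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    return [ar.intervals[int(rng.choice(cand))]
            for cand in _candidate_lists(ar, targets)]


@dataclass
class ResamplingResult:
    n_iter: int
    alpha: float
    t_statistics: list[float]
    dfs: list[float]
    p_values: list[float]
    seed: int

    @property
    def n_significant(self) -> int:
        return int(sum(p < self.alpha for p in self.p_values))

    def to_json(self) -> str:
        return json.dumps({
            "n_iter": self.n_iter, "alpha": self.alpha, "seed": self.seed,
            "n_significant": self.n_significant,
            "t_statistics": self.t_statistics, "dfs": self.dfs,
            "p_values": self.p_values,
        }, indent=1)


def run_resampling(track: SiteScoreTrack, ar: FeatureSet, targets: FeatureSet,
                   n_iter: int = 10000, alpha: float = 0.05,
                   seed: int = 0) -> ResamplingResult:
    """Length-matched AR resampling significance procedure.

    Each iteration draws one length-matched AR per target, pools the
    per-site scores of the drawn ARs, and Welch-tests them against the
    pooled per-site scores of the targets; ``n_significant`` counts
    iterations with p < alpha. Iteration i uses the seeded substream
    (seed, i), so the result is reproducible and independent of order.
    """
    if n_iter < 1 or not (0 < alpha < 1):
        raise ValueError("need n_iter >= 1 and 0 < alpha < 1")
    target_scores = map_scores(track, targets)
    if target_scores.unmapped:
        bad = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in target_scores.unmapped]
        raise ValueError(f"targets with no scored site: {bad}")
    pooled_targets = target_scores.pooled

    ar_scores = map_scores(track, ar)
    mapped_ar = FeatureSet(ar.label, ar_scores.intervals)
    if len(mapped_ar) == 0:
        raise ValueError("no AR interval carries scored sites")
    ar_site_arrays = ar_scores.per_interval
    candidates = _candidate_lists(mapped_ar, targets)

    ts, dfs, ps = [], [], []
    for i in range(n_iter):
        rng = np.random.default_rng([seed, i])
        idx = [int(rng.choice(cand)) for cand in candidates]
        pooled_ar = np.concatenate([ar_site_arrays[k] for k in idx])
        t, df, p = welch_t(pooled_ar, pooled_targets)
        ts.append(t)
        dfs.append(df)
        ps.append(p)
    return ResamplingResult(n_iter, alpha, ts, dfs, ps, seed)
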