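"""Base-wise conservation-acceleration (CONACC) scoring.

For every reference-anchored alignment column, a single rate-scale
parameter rho multiplying ALL branch lengths of the neutral tree is fitted
by maximum likelihood ("all branches" test) and compared with the neutral
model (rho = 1) by a likelihood-ratio test. The signed score is
-log10(p) for conserved sites (rho_hat < 1) and +log10(p) for accelerated
sites (rho_hat > 1), so positive scores mean conservation and negative
scores acceleration.

The p-value uses the upper tail of chi-square with 1 df (the LRT method's
default reference distribution); near the rho >= 0 boundary this is
conservative relative to the 50:50 point-mass/chi-square mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .genome_tracks_io import AlignmentBlock
from .neutral_fit import NeutralModel
from .phylo_likelihood import MISSING, pattern_log_likelihoods
from .subst_models import BASE_INDEX

log = logging.getLogger(__name__)

RHO_MAX = 20.0
SCORE_CAP = 20.0
RHO_TOL = 1e-6


@dataclass(frozen=True)
class SiteScore:
    chrom: str
    pos: int  # 0-based reference coordinate
    rho_hat: float
    lrt: float
    p: float
    conacc: float


@dataclass
class SiteScoreTrack:
    """Per-site scores anchored to reference coordinates.

    Unscored positions are simply absent; ``site_arrays`` exposes the
    (positions, conacc) arrays per chrom for WIG export and mapping.
    """
    reference_species: str
    scores: list[SiteScore] = field(default_factory=list)
    _arrays: dict | None = field(default=None, repr=False)

    def add(self, score: SiteScore) -> None:
        self.scores.append(score)
        self._arrays = None

    def finalize(self) -> None:
        self.scores.sort(key=lambda s: (s.chrom, s.pos))
        seen = set()
        for s in self.scores:
            key = (s.chrom, s.pos)
            if key in seen:
                raise ValueError(f"duplicate score at {s.chrom}:{s.pos}")
            seen.add(key)
        self._arrays = None

    def site_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(positions, conacc) arrays per chrom; cached between calls."""
        if self._arrays is None:
            out: dict[str, tuple[list, list]] = {}
            for s in self.scores:
                pos, val = out.setdefault(s.chrom, ([], []))
                pos.append(s.pos)
                val.append(s.conacc)
            self._arrays = {c: (np.array(p), np.array(v))
                            for c, (p, v) in out.items()}
        return self._arrays

    def __len__(self) -> int:
        return len(self.scores)


def _pattern_fields(neutral: NeutralModel, pattern: np.ndarray,
                    ) -> tuple[float, float, float, float] | None:
    """(rho_hat, lrt, p, conacc) for one encoded pattern, or None if
    unscoreable (fewer than one observed state)."""
    pat = pattern[None, :]
    tree, model = neutral.tree, neutral.model

    def negll(rho):
        return -float(pattern_log_likelihoods(tree, model, pat, rho)[0])

    ll1 = -negll(1.0)
    res = optimize.minimize_scalar(negll, bounds=(0.0, RHO_MAX), method="bounded",
                                   options={"xatol": RHO_TOL})
    rho_hat, ll_hat = float(res.x), -float(res.fun)
    # endpoints: bounded Brent never evaluates the exact boundary
    for cand in (0.0, 1.0):
        ll_c = -negll(cand)
        if ll_c >= ll_hat:
            rho_hat, ll_hat = cand, ll_c
    lrt = max(0.0, 2.0 * (ll_hat - ll1))
    if abs(rho_hat - 1.0) < RHO_TOL or lrt == 0.0:
        return 1.0, 0.0, 1.0, 0.0
    p = float(chi2.sf(lrt, df=1))
    p = max(p, 1e-300)
    conacc = -np.log10(p) if rho_hat < 1.0 else np.log10(p)
    conacc = float(np.clip(conacc, -SCORE_CAP, SCORE_CAP))
    return rho_hat, lrt, p, conacc


def site_lrt(neutral: NeutralModel, column: dict, *, min_present: int = 2,
             ) -> SiteScore | None:
    """All-branches LRT for a single column; None when unscoreable."""
    taxa = neutral.tree.leaf_labels
    pattern = np.array([BASE_INDEX.get(column.get(t, "-").upper(), MISSING)
                        for t in taxa], dtype=np.int8)
    if int(np.sum(pattern < 4)) < min_present:
        return None
    fields = _pattern_fields(neutral, pattern)
    rho_hat, lrt, p, conacc = fields
    return SiteScore("", -1, rho_hat, lrt, p, conacc)


def score_alignment(neutral: NeutralModel, blocks: list[AlignmentBlock],
                    min_present: int = 2,
                    cache: dict | None = None) -> SiteScoreTrack:
    """Score every reference-anchored column of filtered, sorted blocks.

    Columns where the reference has a gap, or with fewer than
    ``min_present`` non-missing taxa, receive no score. Identical site
    patterns share one LRT computation (pattern caching), which is what
    makes genome-scale scoring tractable.
    """
    taxa = neutral.tree.leaf_labels
    if cache is None:
        cache = {}
    track = SiteScoreTrack(reference_species=blocks[0].reference_species
                           if blocks else "")
    for block in blocks:
        ref = block.row_for(block.reference_species)
        if ref is None:
            log.warning("block with species %s lacks reference %r; skipped",
                        block.species, block.reference_species)
            continue
        texts = {}
        for t in taxa:
            row = block.row_for(t)
            texts[t] = row.text if row is not None else "-" * block.width
        enc = np.full((block.width, len(taxa)), MISSING, dtype=np.int8)
        for j, t in enumerate(taxa):
            enc[:, j] = [BASE_INDEX.get(ch, MISSING) for ch in texts[t].upper()]
        ref_cols = [j for j, ch in enumerate(ref.text) if ch != "-"]
        if ref.strand == "+":
            ref_pos = ref.start + np.arange(len(ref_cols))
        else:
            ref_pos = ref.src_size - ref.start - 1 - np.arange(len(ref_cols))
        for p, j in zip(ref_pos, ref_cols):
            pattern = enc[j]
            if int(np.sum(pattern < 4)) < min_present:
                continue
            key = pattern.tobytes()
            if key not in cache:
                cache[key] = _pattern_fields(neutral, pattern)
            fields = cache[key]
            if fields is None:
                continue
            rho_hat, lrt, pval, conacc = fields
            track.add(SiteScore(ref.chrom, int(p), rho_hat, lrt, pval, conacc))
    track.finalize()
    return track
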