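"""Score-to-feature mapping, Welch tests and the AR resampling procedure."""

import math

import numpy as np
import pytest

from norfevo import feature_comparison as fc
from norfevo.conacc_scoring import SiteScore, SiteScoreTrack
from norfevo.genome_tracks_io import FeatureSet, GenomicInterval


def make_track(sites):
    t = SiteScoreTrack(reference_species="ref")
    for chrom, pos, score in sites:
        t.add(SiteScore(chrom, pos, 1.0, 0.0, 1.0, score))
    t.finalize()
    return t


def fs(label, triples):
    return FeatureSet(label, [GenomicInterval(c, s, e) for c, s, e in triples])


class TestMapScores:
    def test_interval_mean(self):
        track = make_track([("c1", 10, 1.0), ("c1", 11, 2.0), ("c1", 12, 3.0)])
        mapped = fc.map_scores(track, fs("x", [("c1", 10, 13)]))
        assert mapped.region_scores.tolist() == [2.0]
        assert mapped.n_scored_sites == 3

    def test_unmapped_interval_excluded(self):
        track = make_track([("c1", 10, 1.0)])
        mapped = fc.map_scores(track, fs("x", [("c1", 10, 11), ("c1", 50, 60)]))
        assert len(mapped.per_interval) == 1
        assert len(mapped.unmapped) == 1

    def test_half_open_boundary(self):
        track = make_track([("c1", 9, 1.0), ("c1", 12, 2.0), ("c1", 13, 9.0)])
        mapped = fc.map_scores(track, fs("x", [("c1", 10, 13)]))
        assert mapped.pooled.tolist() == [2.0]


class TestEcdf:
    def test_duplicates(self):
        assert fc.ecdf([1, 1, 2]) == [(1, pytest.approx(2 / 3)), (2, 1.0)]

    def test_single_value(self):
        assert fc.ecdf([5.0]) == [(5.0, 1.0)]

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        e1 = dict(fc.ecdf(x))
        e2 = dict(fc.ecdf(x + 1))
        for v in e1:
            if v in e2:
                assert e1[v] >= e2[v]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fc.ecdf([])


def welch_oracle(x, y):
    """Textbook Welch equations, independent of scipy."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


class TestWelchT:
    def test_matches_closed_form(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 4.0, 5.0, 9.0]
        t, df, p = fc.welch_t(x, y)
        t0, df0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        from scipy.stats import t as tdist
        assert p == pytest.approx(2 * tdist.sf(abs(t0), df0), abs=1e-10)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        t, df, p = fc.welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        x, y = [1.0, 2.0, 3.0, 7.0], [4.0, 5.0, 9.0]
        t1, _, p1 = fc.welch_t(x, y)
        t2, _, p2 = fc.welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fc.welch_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            fc.welch_t([1.0], [2.0, 3.0])


class TestLengthMatchedSample:
    def _ar(self, lengths):
        return FeatureSet("AR", [GenomicInterval("c1", 1000 * i, 1000 * i + l)
                                 for i, l in enumerate(lengths)])

    def test_tolerance_and_fallback(self):
        ar = self._ar([295, 300, 800])
        targets = fs("t", [("c2", 0, 300), ("c2", 500, 1000)])
        draws = {tuple(len(iv) for iv in
                       fc.length_matched_sample(ar, targets, seed))
                 for seed in range(40)}
        firsts = {d[0] for d in draws}
        seconds = {d[1] for d in draws}
        assert firsts <= {295, 300} and len(firsts) == 2
        assert seconds == {300}  # nearest-length fallback (500 +/- 50 empty)

    def test_within_tolerance_or_nearest(self):
        ar = self._ar([100, 210, 500, 950])
        targets = fs("t", [("c2", 0, 200), ("c2", 0, 1000)])
        for seed in range(10):
            for iv, target in zip(fc.length_matched_sample(ar, targets, seed),
                                  targets.intervals):
                tol = max(20, 0.1 * len(target))
                nearest = min((abs(l - len(target)), l)
                              for l in (100, 210, 500, 950))[1]
                assert abs(len(iv) - len(target)) <= tol or len(iv) == nearest

    def test_seed_determinism(self):
        ar = self._ar([100, 110, 120, 90, 95])
        targets = fs("t", [("c2", 0, 100)] * 5)
        a = fc.length_matched_sample(ar, targets, 7)
        b = fc.length_matched_sample(ar, targets, 7)
        c = fc.length_matched_sample(ar, targets, 8)
        assert a == b
        assert a != c

    def test_empty_ar_rejected(self):
        with pytest.raises(ValueError):
            fc.length_matched_sample(FeatureSet("AR", []),
                                     fs("t", [("c2", 0, 100)]), 0)


def _resampling_setup(seed=0, n_ar=30, shift=0.0):
    """A track covering AR intervals and two targets; targets optionally
    shifted in score."""
    rng = np.random.default_rng(seed)
    sites = []
    ar_ivs = []
    pos = 0
    for i in range(n_ar):
        length = int(rng.integers(80, 120))
        ar_ivs.append(("c1", pos, pos + length))
        for p in range(pos, pos + length):
            sites.append(("c1", p, float(rng.normal())))
        pos += length + 10
    target_ivs = []
    for i in range(2):
        length = 100
        target_ivs.append(("c1", pos, pos + length))
        for p in range(pos, pos + length):
            sites.append(("c1", p, float(rng.normal() + shift)))
        pos += length + 10
    return make_track(sites), fs("AR", ar_ivs), fs("t", target_ivs)


class TestRunResampling:
    def test_single_iteration(self):
        track, ar, targets = _resampling_setup()
        res = fc.run_resampling(track, ar, targets, n_iter=1, alpha=0.05, seed=1)
        assert len(res.p_values) == 1
        assert res.n_significant in (0, 1)

    def test_seed_reproducibility(self):
        track, ar, targets = _resampling_setup()
        r1 = fc.run_resampling(track, ar, targets, n_iter=20, seed=5)
        r2 = fc.run_resampling(track, ar, targets, n_iter=20, seed=5)
        assert r1 == r2

    def test_shifted_targets_usually_significant(self):
        track, ar, targets = _resampling_setup(shift=1.5)
        res = fc.run_resampling(track, ar, targets, n_iter=50, seed=2)
        assert res.n_significant >= 45

    def test_unmapped_target_rejected(self):
        track, ar, _ = _resampling_setup()
        bad = fs("t", [("c9", 0, 100)])
        with pytest.raises(ValueError, match="no scored site"):
            fc.run_resampling(track, ar, bad, n_iter=1, seed=0)

    def test_invalid_parameters_rejected(self):
        track, ar, targets = _resampling_setup()
        with pytest.raises(ValueError):
            fc.run_resampling(track, ar, targets, n_iter=0, seed=0)
        with pytest.raises(ValueError):
            fc.run_resampling(track, ar, targets, alpha=1.5, seed=0)
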