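"""MAF/BED/WIG round trips, filtering semantics and interval algebra."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from norfevo import genome_tracks_io as gio
from norfevo.conacc_scoring import SiteScore, SiteScoreTrack

MAF_TEXT = """##maf version=1

a score=100
s ref.LG1 10 5 + 1000 ACG-TA
s sp2.c7 3 6 + 500 ACGCTA
s sp3.c1 0 6 - 400 ACGCTA
s sp4.c2 5 6 + 800 AAGCTA
s sp5.c9 2 6 + 600 ACGCAA

a
s ref.LG1 30 4 + 1000 AC-GT
s sp2.c7 9 5 + 500 ACTGT
s sp3.c1 6 5 - 400 ACTGT
s sp4.c2 11 5 + 800 ACTGA
"""


@pytest.fixture
def maf_file(tmp_path):
    p = tmp_path / "test.maf"
    p.write_text(MAF_TEXT)
    return p


class TestMaf:
    def test_parse(self, maf_file):
        blocks = gio.read_maf(maf_file, reference_species="ref")
        assert len(blocks) == 2
        assert len(blocks[0].rows) == 5 and len(blocks[1].rows) == 4
        ref = blocks[0].reference_row()
        assert (ref.chrom, ref.start, ref.size, ref.src_size) == ("LG1", 10, 5, 1000)

    def test_round_trip(self, maf_file, tmp_path):
        blocks = gio.read_maf(maf_file, reference_species="ref")
        out = tmp_path / "rt.maf"
        gio.write_maf(blocks, out)
        assert gio.read_maf(out, reference_species="ref") == blocks

    def test_malformed_s_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text("##maf version=1\na\ns ref.LG1 10 5 + 1000\n")
        with pytest.raises(gio.MafParseError, match="line 3"):
            gio.read_maf(p)

    def test_size_text_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text("##maf version=1\na\ns ref.LG1 10 10 + 1000 ACG-TACGT\n")
        with pytest.raises(gio.ValidationError, match="size=10"):
            gio.read_maf(p)


class TestFilterMaf:
    def _block(self, texts, species=None):
        species = species or [f"sp{i}" for i in range(len(texts))]
        rows = tuple(
            gio.MafRow(sp, "c", 0, sum(ch != "-" for ch in t), "+", 100, t)
            for sp, t in zip(species, texts))
        return gio.AlignmentBlock(rows, reference_species=species[0])

    def test_min_rows_five(self):
        b4 = self._block(["ACGT"] * 4)
        b5 = self._block(["ACGT"] * 5)
        assert gio.filter_maf([b4, b5], min_rows=5) == [b5]

    def test_gap_only_column_removed(self):
        b = self._block(["AC-T", "AG-T"])
        (out,) = gio.filter_maf([b], min_rows=1)
        assert [r.text for r in out.rows] == ["ACT", "AGT"]
        assert all(r.size == 3 for r in out.rows)

    def test_no_gap_only_columns_is_identity(self):
        b = self._block(["AC-T", "AGCT"])
        assert gio.filter_maf([b], min_rows=1) == [b]

    def test_idempotent(self):
        blocks = [self._block(["A-C--T", "A-C-GT", "--C--T"])]
        once = gio.filter_maf(blocks, min_rows=2)
        assert gio.filter_maf(once, min_rows=2) == once


class TestSortMaf:
    def _block_at(self, chrom, start, tag):
        rows = (gio.MafRow("ref", chrom, start, 4, "+", 1000, "ACGT"),
                gio.MafRow(tag, "x", 0, 4, "+", 1000, "ACGT"))
        return gio.AlignmentBlock(rows, reference_species="ref")

    def test_sorted_by_start_with_stable_ties(self):
        blocks = [self._block_at("LG1", 100, "a"),
                  self._block_at("LG1", 20, "b"),
                  self._block_at("LG1", 20, "c")]
        out = gio.sort_maf(blocks)
        assert [b.rows[1].species for b in out] == ["b", "c", "a"]

    def test_chrom_order_lexicographic(self):
        blocks = [self._block_at("LG2", 0, "a"), self._block_at("LG1", 50, "b")]
        assert [b.reference_row().chrom for b in gio.sort_maf(blocks)] == \
            ["LG1", "LG2"]

    def test_missing_reference_raises(self):
        rows = (gio.MafRow("spX", "c", 0, 4, "+", 100, "ACGT"),)
        block = gio.AlignmentBlock(rows, reference_species="ref")
        with pytest.raises(gio.ValidationError, match="lacks reference"):
            gio.sort_maf([block])


def _track(chrom_sites):
    t = SiteScoreTrack(reference_species="ref")
    for chrom, pos, score in chrom_sites:
        t.add(SiteScore(chrom, pos, 1.0, 0.0, 1.0, score))
    t.finalize()
    return t


class TestWig:
    def test_run_grouping(self, tmp_path):
        # 1-based positions 5,6,7 and 10 -> 0-based 4,5,6 and 9
        track = _track([("c1", p, float(p)) for p in (4, 5, 6, 9)])
        path = tmp_path / "t.wig"
        gio.write_wig(track, path)
        stanzas = [l for l in path.read_text().splitlines()
                   if l.startswith("fixedStep")]
        assert len(stanzas) == 2
        assert "start=5" in stanzas[0] and "start=10" in stanzas[1]

    def test_empty_track_header_only(self, tmp_path):
        path = tmp_path / "e.wig"
        gio.write_wig(_track([]), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_wig_to_bed_round_trip(self, tmp_path):
        sites = [("c1", p, s) for p, s in
                 [(4, 1.5), (5, -2.0), (6, 0.25), (9, 3.0)]]
        path = tmp_path / "t.wig"
        gio.write_wig(_track(sites), path)
        records = gio.wig_to_bed(path)
        assert [(iv.start, score) for iv, score in records] == \
            [(p, s) for _, p, s in sites]
        assert all(iv.end - iv.start == 1 for iv, _ in records)

    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "c.wig"
        path.write_text("fixedStep chrom=c1 start=100 step=1\n1\n2\n3\n")
        starts = [iv.start for iv, _ in gio.wig_to_bed(path)]
        assert starts == [99, 100, 101]

    def test_nan_score_rejected(self, tmp_path):
        path = tmp_path / "n.wig"
        path.write_text("fixedStep chrom=c1 start=1 step=1\nNaN\n")
        with pytest.raises(gio.ValidationError, match="non-finite"):
            gio.wig_to_bed(path)

    def test_variable_step_rejected(self, tmp_path):
        path = tmp_path / "v.wig"
        path.write_text("variableStep chrom=c1\n5 1.0\n")
        with pytest.raises(gio.ValidationError, match="variableStep"):
            gio.wig_to_bed(path)


def _fs(label, triples):
    return gio.FeatureSet(label, [gio.GenomicInterval(c, s, e)
                                  for c, s, e in triples])


class TestComplement:
    def test_basic(self):
        fs = _fs("f", [("c1", 10, 20), ("c1", 50, 60)])
        out = gio.complement_intervals(fs, {"c1": 100})
        assert [(iv.start, iv.end) for iv in out.intervals] == \
            [(0, 10), (20, 50), (60, 100)]

    def test_full_coverage_empty(self):
        assert len(gio.complement_intervals(_fs("f", [("c1", 0, 100)]),
                                            {"c1": 100})) == 0

    def test_overlaps_merged_first(self):
        fs = _fs("f", [("c1", 10, 30), ("c1", 20, 40)])
        out = gio.complement_intervals(fs, {"c1": 100})
        assert [(iv.start, iv.end) for iv in out.intervals] == [(0, 10), (40, 100)]

    def test_interval_beyond_chrom_rejected(self):
        with pytest.raises(gio.ValidationError, match="exceeds"):
            gio.complement_intervals(_fs("f", [("c1", 0, 200)]), {"c1": 100})

    def test_involution_on_merged_sets(self):
        sizes = {"c1": 500, "c2": 300}
        fs = _fs("f", [("c1", 10, 60), ("c1", 40, 90), ("c1", 200, 250),
                       ("c2", 0, 100)])
        back = gio.complement_intervals(
            gio.complement_intervals(fs, sizes), sizes)
        merged = gio.merge_intervals(fs)
        assert [(iv.chrom, iv.start, iv.end) for iv in back.intervals] == \
            [(iv.chrom, iv.start, iv.end) for iv in merged.intervals]

    def test_against_bedtools(self, tmp_path):
        """Independent oracle: bedtools complement on a random interval set."""
        rng = np.random.default_rng(0)
        ivs = sorted({(int(s), int(s + l)) for s, l in
                      zip(rng.integers(0, 900, 30), rng.integers(1, 80, 30))})
        fs = _fs("f", [("c1", s, e) for s, e in ivs])
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"c1\t{s}\t{e}\n" for s, e in ivs))
        genome = tmp_path / "g.txt"
        genome.write_text("c1\t1000\n")
        try:
            out = subprocess.run(
                ["bedtools", "complement", "-i", bed, "-g", genome],
                capture_output=True, text=True, check=True)
        except FileNotFoundError:
            pytest.skip("bedtools not on PATH")
        expected = [tuple(map(int, l.split("\t")[1:3]))
                    for l in out.stdout.splitlines()]
        got = [(iv.start, iv.end)
               for iv in gio.complement_intervals(fs, {"c1": 1000}).intervals]
        assert got == expected


class TestIntersectMinOverlap:
    def test_fraction_threshold(self):
        a = _fs("a", [("c1", 0, 100)])
        b = _fs("b", [("c1", 0, 80)])
        assert len(gio.intersect_min_overlap(a, b, 0.8)) == 1
        assert len(gio.intersect_min_overlap(a, b, 0.81)) == 0

    def test_contained_always_kept(self):
        a = _fs("a", [("c1", 10, 20)])
        b = _fs("b", [("c1", 0, 100)])
        assert len(gio.intersect_min_overlap(a, b, 1.0)) == 1

    def test_piecewise_overlap_sums(self):
        a = _fs("a", [("c1", 0, 100)])
        b = _fs("b", [("c1", 0, 40), ("c1", 50, 90)])
        assert len(gio.intersect_min_overlap(a, b, 0.8)) == 1
        assert len(gio.intersect_min_overlap(a, b, 0.81)) == 0


@settings(derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.integers(0, 450), st.integers(1, 50)),
                min_size=1, max_size=20))
def test_complement_union_covers_chrom(pairs):
    """Input union + complement tile the chromosome exactly."""
    fs = _fs("f", [("c1", s, s + l) for s, l in pairs])
    comp = gio.complement_intervals(fs, {"c1": 500})
    covered = np.zeros(500, dtype=int)
    for iv in gio.merge_intervals(fs).intervals:
        covered[iv.start:iv.end] += 1
    for iv in comp.intervals:
        covered[iv.start:iv.end] += 1
    assert np.all(covered == 1)
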