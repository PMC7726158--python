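"""I/O for the genome-track formats the pipeline touches, plus interval algebra.

Formats: MAF 1.0 multiple alignments, BED intervals, fixed-step WIG score
tracks, two-column chrom-sizes TSV. Coordinates follow BED semantics
(0-based, half-open) everywhere in the API; WIG is 1-based at the file
boundary only, matching the convention of the BEDOPS/UCSC toolchain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-")


class MafParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


# --------------------------------------------------------------------------
# MAF
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MafRow:
    """One 's' line: strand-relative start per the MAF convention."""
    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chrom}"

    def forward_start(self) -> int:
        """Start on the forward strand regardless of row strand."""
        if self.strand == "+":
            return self.start
        return self.src_size - self.start - self.size


@dataclass(frozen=True)
class AlignmentBlock:
    rows: tuple[MafRow, ...]
    reference_species: str | None = None

    def __post_init__(self):
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValidationError(f"unequal row widths in block: {sorted(widths)}")
        for r in self.rows:
            ungapped = sum(1 for ch in r.text if ch not in GAP_CHARS)
            if ungapped != r.size:
                raise ValidationError(
                    f"row {r.src}: size={r.size} but text has {ungapped} non-gap chars")

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(r.species for r in self.rows)

    def row_for(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None

    def reference_row(self) -> MafRow:
        ref = self.row_for(self.reference_species)
        if ref is None:
            raise ValidationError(
                f"block lacks reference species {self.reference_species!r}")
        return ref


def _parse_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, _, chrom = src.partition(".")
        return sp, chrom
    return src, src


def read_maf(path, reference_species: str | None = None) -> list[AlignmentBlock]:
    """Parse a MAF 1.0 file into alignment blocks (row order preserved)."""
    blocks: list[AlignmentBlock] = []
    rows: list[MafRow] = []
    in_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#") or not line.strip():
                if in_block and rows:
                    blocks.append(AlignmentBlock(tuple(rows), reference_species))
                    rows, in_block = [], False
                continue
            if line.startswith("a"):
                if in_block and rows:
                    blocks.append(AlignmentBlock(tuple(rows), reference_species))
                rows, in_block = [], True
            elif line.startswith("s "):
                fields = line.split()
                if len(fields) != 7:
                    raise MafParseError(
                        f"line {lineno}: 's' line has {len(fields)} fields, expected 7")
                _, src, start, size, strand, src_size, text = fields
                sp, chrom = _parse_src(src)
                try:
                    row = MafRow(sp, chrom, int(start), int(size), strand,
                                 int(src_size), text)
                except ValueError as e:
                    raise MafParseError(f"line {lineno}: {e}") from None
                if strand not in "+-":
                    raise MafParseError(f"line {lineno}: bad strand {strand!r}")
                rows.append(row)
            # i/e/q lines are ignored
    if in_block and rows:
        blocks.append(AlignmentBlock(tuple(rows), reference_species))
    return blocks


def write_maf(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("\na\n")
            for r in b.rows:
                fh.write(f"s {r.src} {r.start} {r.size} {r.strand} "
                         f"{r.src_size} {r.text}\n")


def filter_maf(blocks, min_rows: int = 5) -> list[AlignmentBlock]:
    """Drop blocks with fewer than ``min_rows`` rows and remove gap-only columns.

    The default of 5 keeps only blocks where all five aligned genomes are
    present, the filter applied before genome-wide scoring.
    """
    if min_rows < 1:
        raise ValueError("min_rows must be >= 1")
    out = []
    for b in blocks:
        if len(b.rows) < min_rows:
            continue
        texts = [r.text for r in b.rows]
        keep = [j for j in range(len(texts[0]))
                if any(t[j] not in GAP_CHARS for t in texts)]
        if len(keep) == len(texts[0]):
            out.append(b)
            continue
        new_rows = []
        for r in b.rows:
            text = "".join(r.text[j] for j in keep)
            size = sum(1 for ch in text if ch not in GAP_CHARS)
            new_rows.append(replace(r, text=text, size=size))
        out.append(AlignmentBlock(tuple(new_rows), b.reference_species))
    return out


def sort_maf(blocks, reference_species: str | None = None) -> list[AlignmentBlock]:
    """Stable sort by (reference chrom, reference forward-strand start)."""
    def key(b: AlignmentBlock):
        ref_sp = reference_species or b.reference_species
        ref = b.row_for(ref_sp)
        if ref is None:
            raise ValidationError(
                f"block with species {b.species} lacks reference {ref_sp!r}")
        return (ref.chrom, ref.forward_start())
    return sorted(blocks, key=key)


# --------------------------------------------------------------------------
# intervals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    frame: int = 0  # CDS phase: offset of the first complete codon

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FeatureSet:
    """Named collection of genomic intervals, kept sorted by (chrom, start)."""
    label: str
    intervals: list[GenomicInterval]

    def __post_init__(self):
        if not self.label:
            raise ValidationError("FeatureSet label must be non-empty")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def read_bed(path, label: str | None = None) -> FeatureSet:
    """Read BED3/BED6 (+ optional 7th 'frame' column for CDS phase)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                f = line.split()
            iv = GenomicInterval(
                f[0], int(f[1]), int(f[2]),
                name=f[3] if len(f) > 3 else None,
                strand=f[5] if len(f) > 5 and f[5] in "+-" else None,
                frame=int(f[6]) if len(f) > 6 else 0,
            )
            intervals.append(iv)
    return FeatureSet(label or "features", intervals)


def write_bed(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for iv in features.intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def merge_intervals(features: FeatureSet) -> FeatureSet:
    """Union of possibly-overlapping intervals, per chrom."""
    merged = []
    for chrom, ivs in features.by_chrom().items():
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return FeatureSet(features.label, merged)


def complement_intervals(features: FeatureSet, sizes: dict[str, int],
                         label: str = "intergenic") -> FeatureSet:
    """Per-chrom set complement of the merged intervals within [0, length).

    This is how intergenic regions are defined: everything not covered by
    any annotation (bedtools-complement semantics). Chroms present in
    ``sizes`` but absent from ``features`` are returned whole.
    """
    merged = merge_intervals(features)
    out = []
    by_chrom = merged.by_chrom()
    for chrom, length in sizes.items():
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.end > length:
                raise ValidationError(
                    f"interval {chrom}:{iv.start}-{iv.end} exceeds chrom length {length}")
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            out.append(GenomicInterval(chrom, pos, length))
    for chrom in by_chrom:
        if chrom not in sizes:
            raise ValidationError(f"chrom {chrom!r} missing from chrom sizes")
    return FeatureSet(label, out)


def intersect_min_overlap(a: FeatureSet, b: FeatureSet,
                          min_frac: float = 0.8) -> FeatureSet:
    """Intervals of ``a`` whose overlap with the union of ``b`` covers at
    least ``min_frac`` of their own length.

    With the 0.8 default this is the ancestral-repeat rule: repeat-masked
    intervals retained only when >= 80% covered by the conserved-alignment
    track.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    b_merged = merge_intervals(b).by_chrom()
    kept = []
    for chrom, ivs in a.by_chrom().items():
        b_ivs = b_merged.get(chrom, [])
        starts = np.array([x.start for x in b_ivs])
        ends = np.array([x.end for x in b_ivs])
        for iv in ivs:
            if len(b_ivs) == 0:
                overlap = 0
            else:
                overlap = int(np.sum(np.clip(np.minimum(ends, iv.end)
                                             - np.maximum(starts, iv.start), 0, None)))
            if overlap >= min_frac * len(iv) - 1e-9:
                kept.append(iv)
    return FeatureSet(a.label, kept)


# --------------------------------------------------------------------------
# WIG
# --------------------------------------------------------------------------

def write_wig(track, path, track_name: str = "conacc") -> None:
    """Write a score track as fixedStep WIG (1-based, step=1).

    ``track`` must provide ``site_arrays() -> dict[chrom, (pos0, score)]``
    with strictly increasing 0-based positions per chrom. Unscored
    positions fall between stanzas; no placeholder values are written.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for chrom, (pos, score) in track.site_arrays().items():
            pos = np.asarray(pos)
            score = np.asarray(score, dtype=float)
            if len(pos) == 0:
                continue
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions on {chrom} must be strictly increasing")
            breaks = np.flatnonzero(np.diff(pos) != 1)
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks + 1, [len(pos)]])
            for s, e in zip(run_starts, run_ends):
                fh.write(f"fixedStep chrom={chrom} start={pos[s] + 1} step=1\n")
                for v in score[s:e]:
                    fh.write(f"{v:.6g}\n")


def wig_to_bed(path) -> list[tuple[GenomicInterval, float]]:
    """fixedStep WIG -> one 1-bp BED record per scored site (0-based)."""
    out = []
    chrom, pos = None, None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("track") or line.startswith("#"):
                continue
            if line.startswith("variableStep"):
                raise ValidationError(
                    f"line {lineno}: variableStep WIG is not supported")
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # to 0-based
                if int(fields.get("step", 1)) != 1:
                    raise ValidationError(f"line {lineno}: only step=1 supported")
                continue
            if chrom is None:
                raise ValidationError(f"line {lineno}: value before any declaration")
            val = float(line)
            if not np.isfinite(val):
                raise ValidationError(f"line {lineno}: non-finite score {line!r}")
            out.append((GenomicInterval(chrom, pos, pos + 1), val))
            pos += 1
    return out
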