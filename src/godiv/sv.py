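"""Structural-variant call filtering, validation and rate normalisation.

This module implements the downstream logic applied to SV calls that were
produced upstream by a paired-end caller and a local assembler (both
consumed here as plain files, never re-run):

* hard filters on raw calls — minimum size (100 bp), minimum caller
  quality (1000), both breakpoint ends assembled, distance from
  telomeres/centromeres (30 kbp), and a 90% reciprocal-overlap filter
  against transposable elements for DEL/INS/INV/DUP calls;
* validation of each surviving call against the split-alignment geometry
  of a breakpoint-spanning contig (gap/overlap differences of at least
  100 bp between contig and reference, reverse-orientation segments for
  inversions, two reference chromosomes for translocations);
* breakpoint concordance between assembly and caller (+/- 100 bp);
* per-strain SV rates normalised per Mbp and per unit genetic distance,
  and the fraction of calls with a breakpoint within 100 bp of an LTR
  retrotransposon.

Coordinates are 1-based inclusive on input (VCF convention) and converted
to half-open ``[start, end)`` internally; BED tracks are read as the
0-based half-open intervals they already are.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SVCall",
    "Segment",
    "SplitAlignment",
    "AnnotationTrack",
    "read_sv_calls",
    "read_bed_track",
    "read_split_alignments",
    "filter_sv_calls",
    "reciprocal_overlap",
    "validate_sv",
    "breakpoints_concordant",
    "tra_breakpoints_concordant",
    "count_breakpoints",
    "sv_rate",
    "ltr_association",
    "svs_per_strain",
]

SV_TYPES = ("DEL", "INS", "INV", "DUP", "TRA")
#: types subject to the reciprocal transposable-element overlap filter
TE_FILTERED_TYPES = ("DEL", "INS", "INV", "DUP")

MIN_SIZE = 100
MIN_QUALITY = 1000
EXCLUSION_FLANK = 30_000
TE_RECIPROCAL = 0.90
GAP_DELTA = 100
CONCORDANCE_TOL = 100
LTR_WITHIN = 100


@dataclass
class SVCall:
    """One structural-variant call with its two breakpoints."""

    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    size: int
    quality: float
    left_assembled: bool = True
    right_assembled: bool = True
    id: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.size < 0:
            raise ValueError("SV size must be non-negative")
        if self.sv_type != "TRA" and self.chrom1 != self.chrom2:
            raise ValueError(f"{self.sv_type} breakpoints must share a chromosome")

    def interval(self) -> tuple[str, int, int]:
        """Half-open reference interval spanned by an intra-chromosomal call."""
        lo, hi = sorted((self.pos1, self.pos2))
        return self.chrom1, lo - 1, hi

    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


@dataclass(frozen=True)
class Segment:
    """One aligned block of a contig (all coordinates half-open)."""

    contig_start: int
    contig_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    orientation: str  # "+" or "-"

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


#: maximum allowed contig overlap between consecutive split-alignment
#: segments, as a fraction of either segment
MAX_CONTIG_OVERLAP = 0.75


@dataclass
class SplitAlignment:
    """Split alignment of one breakpoint-spanning contig to the reference."""

    contig_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.contig_start, s.contig_end))
        for s1, s2 in zip(self.segments, self.segments[1:]):
            ov = s1.contig_end - s2.contig_start
            if ov > MAX_CONTIG_OVERLAP * min(s1.length, s2.length):
                raise ValueError(
                    f"contig {self.contig_id!r}: consecutive segments overlap by "
                    f"{ov} bp, more than {MAX_CONTIG_OVERLAP:.0%} of a segment"
                )


class AnnotationTrack:
    """Sorted per-chromosome interval track (telomere/centromere, TE, LTR)."""

    def __init__(self, name: str, intervals: list[tuple[str, int, int]]):
        self.name = name
        self.intervals = sorted(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(
                    f"track {name!r}: malformed interval {chrom}:{start}-{end}"
                )
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def __len__(self) -> int:
        return len(self.intervals)

    def near(self, chrom: str, pos: int, within: int) -> bool:
        """Is the 1-based position within ``within`` bp (inclusive) of any
        interval?"""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        p0 = pos - 1  # 0-based point on the track axis
        return bool(tree.overlap(p0 - within, p0 + within + 1))

    def max_reciprocal_overlap(self, chrom: str, start: int, end: int) -> float:
        """Largest reciprocal overlap of [start, end) with any interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return 0.0
        best = 0.0
        for iv in tree.overlap(start, end):
            best = max(best, reciprocal_overlap((start, end), (iv.begin, iv.end)))
        return best


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SV_TSV_COLUMNS = [
    "sv_type", "chrom1", "pos1", "chrom2", "pos2",
    "size", "quality", "left_assembled", "right_assembled",
]


def _to_bool(v) -> bool:
    return str(v).strip().lower() in ("1", "true", "t", "yes")


def read_sv_calls(path: str | os.PathLike, format: str = "tsv") -> list[SVCall]:
    """Read SV calls from a BEDPE-like TSV (headered) or a VCF.

    VCF records use symbolic ALTs with INFO keys ``SVTYPE``, ``END``,
    ``SVLEN`` and, for translocations, ``CHR2``/``POS2``; breakpoint
    assembly status is carried in ``LEFT_ASM``/``RIGHT_ASM`` flags and the
    caller quality in QUAL.
    """
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t")
        missing = [c for c in SV_TSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"SV table missing column(s): {', '.join(missing)}")
        return [
            SVCall(
                str(r.sv_type), str(r.chrom1), int(r.pos1), str(r.chrom2),
                int(r.pos2), int(r.size), float(r.quality),
                _to_bool(r.left_assembled), _to_bool(r.right_assembled),
                id=str(getattr(r, "id", None)) if hasattr(r, "id") else None,
            )
            for r in frame.itertuples(index=False)
        ]
    if format == "vcf":
        from cyvcf2 import VCF

        calls = []
        for rec in VCF(str(path)):
            svtype = rec.INFO.get("SVTYPE")
            if svtype not in SV_TYPES:
                continue
            pos1 = rec.POS
            if svtype == "TRA":
                chrom2 = rec.INFO.get("CHR2", rec.CHROM)
                pos2 = int(rec.INFO.get("POS2", pos1))
            else:
                chrom2 = rec.CHROM
                pos2 = int(rec.INFO.get("END", pos1))
            size = abs(int(rec.INFO.get("SVLEN", pos2 - pos1)))
            calls.append(
                SVCall(
                    svtype, rec.CHROM, pos1, chrom2, pos2, size,
                    float(rec.QUAL or 0.0),
                    bool(rec.INFO.get("LEFT_ASM")), bool(rec.INFO.get("RIGHT_ASM")),
                    id=rec.ID,
                )
            )
        return calls
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'vcf'")


def read_bed_track(path: str | os.PathLike, name: str) -> AnnotationTrack:
    """Read a 3+ column BED file into an annotation track."""
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return AnnotationTrack(name, [])
    return AnnotationTrack(
        name,
        [
            (str(r[0]), int(r[1]), int(r[2]))
            for r in frame.itertuples(index=False)
        ],
    )


SPLIT_TSV_COLUMNS = [
    "contig_id", "contig_start", "contig_end",
    "ref_chrom", "ref_start", "ref_end", "orientation",
]


def read_split_alignments(path: str | os.PathLike) -> dict[str, SplitAlignment]:
    """Read split alignments from a headered TSV, one row per segment."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SPLIT_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"split-alignment table missing column(s): {', '.join(missing)}")
    out: dict[str, list[Segment]] = {}
    for r in frame.itertuples(index=False):
        out.setdefault(str(r.contig_id), []).append(
            Segment(
                int(r.contig_start), int(r.contig_end), str(r.ref_chrom),
                int(r.ref_start), int(r.ref_end), str(r.orientation),
            )
        )
    return {cid: SplitAlignment(cid, segs) for cid, segs in out.items()}


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two half-open intervals on one chromosome:
    ``min(overlap/|a|, overlap/|b|)``."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        raise ValueError("zero-length interval")
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def filter_sv_calls(
    calls: list[SVCall],
    tracks: dict[str, AnnotationTrack],
    min_size: int = MIN_SIZE,
    min_quality: float = MIN_QUALITY,
    exclusion_flank: int = EXCLUSION_FLANK,
    te_reciprocal: float = TE_RECIPROCAL,
) -> tuple[list[SVCall], list[tuple[SVCall, str]]]:
    """Apply the hard call filters; a call is rejected if ANY rule fires.

    Rules, in reporting order (the first firing rule labels the
    rejection; the passing set does not depend on the order):
    ``size`` (< min_size), ``quality`` (< min_quality),
    ``left_unassembled``, ``right_unassembled``, ``telomere_centromere``
    (a breakpoint within ``exclusion_flank`` of the track), and
    ``te_overlap`` (>= ``te_reciprocal`` reciprocal overlap with a TE;
    DEL/INS/INV/DUP only).

    ``tracks`` maps track names (``telomere_centromere``, ``TE``) to
    :class:`AnnotationTrack`; missing tracks disable their rule.
    """
    telcen = tracks.get("telomere_centromere")
    te = tracks.get("TE")
    passing: list[SVCall] = []
    rejected: list[tuple[SVCall, str]] = []
    for call in calls:
        reason = None
        if call.size < min_size:
            reason = "size"
        elif call.quality < min_quality:
            reason = "quality"
        elif not call.left_assembled:
            reason = "left_unassembled"
        elif not call.right_assembled:
            reason = "right_unassembled"
        elif telcen is not None and any(
            telcen.near(c, p, exclusion_flank) for c, p in call.breakpoints()
        ):
            reason = "telomere_centromere"
        elif (
            te is not None
            and call.sv_type in TE_FILTERED_TYPES
            and te.max_reciprocal_overlap(*call.interval()) >= te_reciprocal
        ):
            reason = "te_overlap"
        if reason is None:
            passing.append(call)
        else:
            rejected.append((call, reason))
    return passing, rejected


# ---------------------------------------------------------------------------
# Validation against local assembly
# ---------------------------------------------------------------------------


def _ref_gap(s1: Segment, s2: Segment) -> int:
    """Signed gap between the inner edges of two reference intervals:
    positive separation, or minus the overlap when they intersect."""
    return max(s2.ref_start - s1.ref_end, s1.ref_start - s2.ref_end)


def validate_sv(call: SVCall, sa: SplitAlignment) -> bool:
    """Does the split-alignment geometry support the call?

    * DEL — some consecutive segment pair on one chromosome has a
      reference gap at least 100 bp larger than the contig gap;
    * INS — contig gap at least 100 bp larger than the reference gap;
    * INV — some segment of >= 100 bp aligns in reverse orientation;
    * DUP — reference overlap of consecutive segments exceeds their
      contig overlap by >= 100 bp;
    * TRA — segments map to two different chromosomes.
    """
    if call.sv_type not in SV_TYPES:
        raise ValueError(f"unknown SV type {call.sv_type!r}")
    segs = sa.segments
    if call.sv_type == "INV":
        return any(s.orientation == "-" and s.length >= GAP_DELTA for s in segs)
    if call.sv_type == "TRA":
        return len({s.ref_chrom for s in segs}) >= 2
    if len(segs) < 2:
        return False
    for s1, s2 in zip(segs, segs[1:]):
        if s1.ref_chrom != s2.ref_chrom:
            continue
        contig_gap = s2.contig_start - s1.contig_end
        ref_gap = _ref_gap(s1, s2)
        if call.sv_type == "DEL" and ref_gap - contig_gap >= GAP_DELTA:
            return True
        if call.sv_type == "INS" and contig_gap - ref_gap >= GAP_DELTA:
            return True
        if call.sv_type == "DUP":
            ref_ov = max(0, -ref_gap)
            contig_ov = max(0, -contig_gap)
            if ref_ov - contig_ov >= GAP_DELTA:
                return True
    return False


def breakpoints_concordant(
    bp_assembly: int, bp_caller: int, tol: int = CONCORDANCE_TOL
) -> bool:
    """Same-chromosome breakpoint agreement within +/- tol (inclusive)."""
    return abs(bp_assembly - bp_caller) <= tol


def tra_breakpoints_concordant(
    asm_bp1: tuple[str, int],
    asm_bp2: tuple[str, int],
    call: SVCall,
    tol: int = CONCORDANCE_TOL,
) -> bool:
    """Translocation concordance: one assembly breakpoint must match a
    caller breakpoint within tol on the same chromosome, and the other
    assembly breakpoint must lie on the mate's chromosome."""
    caller = call.breakpoints()
    for a, b in ((asm_bp1, asm_bp2), (asm_bp2, asm_bp1)):
        for (c1, p1), (c2, _) in ((caller[0], caller[1]), (caller[1], caller[0])):
            if a[0] == c1 and abs(a[1] - p1) <= tol and b[0] == c2:
                return True
    return False


# ---------------------------------------------------------------------------
# Rates and associations
# ---------------------------------------------------------------------------


def count_breakpoints(calls: list[SVCall], per_sv: int = 2) -> int:
    """Total breakpoints; every SV contributes ``per_sv`` (default 2)."""
    return per_sv * len(calls)


def sv_rate(
    breakpoint_count: int, genome_size_bp: int, genetic_distance: float
) -> float:
    """SV breakpoints per Mbp per unit genetic distance."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if genetic_distance <= 0:
        raise ValueError("genetic distance must be positive")
    return breakpoint_count / (genome_size_bp / 1e6) / genetic_distance


def ltr_association(
    calls: list[SVCall], ltr: AnnotationTrack, within: int = LTR_WITHIN
) -> tuple[int, float]:
    """Count and fraction of calls with a breakpoint within ``within`` bp
    (inclusive) of an LTR retrotransposon interval."""
    if not calls:
        raise ValueError("empty call list")
    count = sum(
        1
        for call in calls
        if any(ltr.near(c, p, within) for c, p in call.breakpoints())
    )
    return count, count / len(calls)


def svs_per_strain(total_svs: int, n_strains: int) -> float:
    """Average SVs per strain, reported to 2 decimals."""
    if n_strains <= 0:
        raise ValueError("strain count must be positive")
    return round(total_svs / n_strains, 2)
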