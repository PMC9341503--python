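"""Genomic-interval data model and interval algebra.

All coordinates are 0-based, end-exclusive (BED convention).  Printed locus
coordinates from the literature are ingested verbatim as ``(start, end)`` with
the end exclusive, so that the familiar "length = end - start" arithmetic holds
exactly (e.g. the 41-kb D_H broad domain).

The algebra here (gap-aware merging, multi-set support partition, coverage
fractions) is the foundation every calling stage builds on.  Gap merging is
strict: two intervals are joined iff they overlap, are book-ended, or are
separated by a gap *strictly smaller* than ``max_gap`` — this mirrors the
"skipping gaps <1 kb" rule used throughout domain consensus building.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

VALID_STRANDS = ("+", "-", ".")

#: Chromatin states treated as "active background": canonical active enhancer
#: (9), active non-canonical H3K4me3 enhancer (10) and active promoter (11).
ACTIVE_STATES = frozenset({9, 10, 11})

#: Polycomb-repressed regulatory state.
POLYCOMB_STATE = 7

VALID_MARKS = frozenset(
    {"H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "H3K9me3", "H3K36me3", "DNase"}
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def clip(self, locus: "GenomicInterval") -> "GenomicInterval | None":
        """Restrict to ``locus``; ``None`` if disjoint."""
        if not self.overlaps(locus):
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start, locus.start),
            min(self.end, locus.end),
            self.strand,
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Distance in bp between nearest edges; 0 if overlapping or book-ended.

    Intervals on different chromosomes return ``math.inf`` so that
    nearest-feature searches are total.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, a.start - b.end, b.start - a.end)


def merge_with_gap(
    intervals: Iterable[GenomicInterval], max_gap: int = 1000
) -> list[GenomicInterval]:
    """Union intervals, additionally joining runs separated by gaps < ``max_gap``.

    Overlapping and book-ended intervals always merge (plain set union);
    positive gaps merge iff strictly smaller than ``max_gap``.  Output is
    sorted, disjoint with pairwise gaps >= ``max_gap``, strand-agnostic, and
    the operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            gap = iv.start - cur_end
            if gap <= 0 or gap < max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def union_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Plain set union (overlapping/book-ended intervals coalesced)."""
    return merge_with_gap(intervals, 0)


def subtract_intervals(
    intervals: Iterable[GenomicInterval], region: GenomicInterval
) -> list[GenomicInterval]:
    """Remove ``region`` from each interval, splitting where it cuts through."""
    out: list[GenomicInterval] = []
    for iv in intervals:
        if not iv.overlaps(region):
            out.append(iv)
            continue
        if iv.start < region.start:
            out.append(GenomicInterval(iv.chrom, iv.start, region.start, iv.strand))
        if region.end < iv.end:
            out.append(GenomicInterval(iv.chrom, region.end, iv.end, iv.strand))
    return out


def intersect_support(
    interval_sets: Sequence[Iterable[GenomicInterval]],
) -> list[tuple[GenomicInterval, int]]:
    """Partition covered bases into maximal runs of constant support.

    Support of a base = number of input sets covering it (each set is unioned
    internally first, so a set counts at most once per base).  Output is
    sorted; the total base×support mass equals the summed per-set coverage.
    """
    if len(interval_sets) == 0:
        raise ValueError("at least one input interval set is required")
    events: dict[str, list[tuple[int, int]]] = {}
    for s in interval_sets:
        for iv in union_intervals(list(s)):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[tuple[GenomicInterval, int]] = []
    for chrom in sorted(events):
        pts = sorted(events[chrom])
        depth = 0
        prev_pos: int | None = None
        runs: list[tuple[int, int, int]] = []
        for pos, grp in itertools.groupby(pts, key=lambda t: t[0]):
            if depth > 0 and prev_pos is not None and pos > prev_pos:
                runs.append((prev_pos, pos, depth))
            depth += sum(d for _, d in grp)
            prev_pos = pos
        # coalesce book-ended runs with equal support into maximal runs
        for start, end, sup in runs:
            if out and out[-1][0].chrom == chrom and out[-1][0].end == start and out[-1][1] == sup:
                prev_iv, _ = out.pop()
                out.append((GenomicInterval(chrom, prev_iv.start, end), sup))
            else:
                out.append((GenomicInterval(chrom, start, end), sup))
    return out


def coverage_fraction(
    target: GenomicInterval, features: Iterable[GenomicInterval]
) -> float:
    """Fraction of ``target`` bases covered by the union of ``features``.

    Features on other chromosomes are ignored; double-covered bases count once.
    """
    if target.length <= 0:  # unreachable through the constructor, kept as guard
        raise ValueError("zero-length target")
    covered = 0
    for iv in union_intervals([f for f in features if f.chrom == target.chrom]):
        covered += iv.overlap_length(target)
    return covered / target.length


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


# ---------------------------------------------------------------------------
# Track-level containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSegment:
    """One chromatin-state segment: an interval labelled with a state."""

    interval: GenomicInterval
    state: int | str


@dataclass
class SegmentationTrack:
    """Chromatin-state segmentation of one sample.

    Segments are sorted by (chrom, start) and non-overlapping within a
    chromosome.  Use :meth:`from_segments` to build a validated track from
    arbitrary input (book-ended/overlapping same-state segments are merged;
    overlapping segments with different states are rejected).
    """

    sample_id: str
    segments: list[StateSegment]
    cell_type: str = ""
    disease_status: str = "healthy"
    resolution: int = 200

    def __post_init__(self) -> None:
        if self.disease_status not in ("healthy", "malignant"):
            raise ValueError(f"bad disease_status {self.disease_status!r}")
        prev: StateSegment | None = None
        for seg in self.segments:
            if prev is not None and prev.interval.chrom == seg.interval.chrom:
                if seg.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping segments in track {self.sample_id}: "
                        f"{prev.interval} and {seg.interval}"
                    )
                if seg.interval.start < prev.interval.start:
                    raise ValueError(f"unsorted segments in track {self.sample_id}")
            prev = seg

    @classmethod
    def from_segments(
        cls,
        sample_id: str,
        segments: Iterable[StateSegment],
        **kwargs,
    ) -> "SegmentationTrack":
        segs = sorted(
            segments, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end)
        )
        merged: list[StateSegment] = []
        for seg in segs:
            if merged:
                prev = merged[-1]
                same_chrom = prev.interval.chrom == seg.interval.chrom
                if same_chrom and seg.interval.start < prev.interval.end:
                    if seg.state != prev.state:
                        raise ValueError(
                            f"overlapping segments with different states: "
                            f"{prev.interval}({prev.state}) vs {seg.interval}({seg.state})"
                        )
                    merged[-1] = StateSegment(
                        GenomicInterval(
                            prev.interval.chrom,
                            prev.interval.start,
                            max(prev.interval.end, seg.interval.end),
                        ),
                        prev.state,
                    )
                    continue
                if (
                    same_chrom
                    and seg.interval.start == prev.interval.end
                    and seg.state == prev.state
                ):
                    merged[-1] = StateSegment(
                        GenomicInterval(
                            prev.interval.chrom, prev.interval.start, seg.interval.end
                        ),
                        prev.state,
                    )
                    continue
            merged.append(seg)
        return cls(sample_id=sample_id, segments=merged, **kwargs)

    @property
    def state_alphabet(self) -> set:
        return {s.state for s in self.segments}

    def filter_states(self, states: Iterable) -> list[GenomicInterval]:
        wanted = set(states)
        return [s.interval for s in self.segments if s.state in wanted]


@dataclass
class PeakTrack:
    """Peaks of one histone mark (or DNase) for one sample.

    Peaks are unioned at construction time (book-ended duplicates merged).
    """

    sample_id: str
    mark: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {sorted(VALID_MARKS)}")
        self.peaks = union_intervals(self.peaks)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: a stranded body and the derived TSS."""

    gene_id: str
    body: GenomicInterval
    strand: str
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            derived = self.body.start if self.strand == "+" else self.body.end - 1
            object.__setattr__(self, "tss", derived)
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(
                f"tss {self.tss} outside body {self.body} for gene {self.gene_id}"
            )
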