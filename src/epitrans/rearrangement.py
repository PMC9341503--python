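"""Rearrangement models and epigenomic-translocation detection.

Genomic rearrangements (cut-and-paste insertion of a donor segment,
reciprocal translocation, small sequence insertion) are formalised as
piecewise coordinate maps onto derivative chromosomes.  The detector then
asks the epigenomic question: has the H3K4me3 broad domain *left* its
wild-type donor locus (residual coverage below a loss threshold) and
*appeared* over the body of an acceptor oncogene (coverage above a gain
threshold)?  Both together constitute an epigenomic translocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .calling import ConsensusRegion, DomainCall
from .intervals import (
    GeneModel,
    GenomicInterval,
    coverage_fraction,
    interval_gap,
    union_intervals,
)

EVENT_TYPES = ("cut_paste_insertion", "reciprocal_translocation", "sequence_insertion")


@dataclass(frozen=True)
class RearrangementEvent:
    """One structural event.

    ``cut_paste_insertion``: ``donor`` segment excised and inserted at
    ``acceptor_site`` (chrom, position), optionally inverted.
    ``reciprocal_translocation``: exchange of terminal segments at the two
    ``breakpoints``.  ``sequence_insertion``: a few-bp insertion that creates
    a regulatory element in place; it does not shift coordinates at pipeline
    resolution and is modelled as activation at ``acceptor_site``.
    """

    event_id: str
    event_type: str
    donor: GenomicInterval | None = None
    breakpoints: tuple[tuple[str, int], tuple[str, int]] | None = None
    acceptor_site: tuple[str, int] | None = None
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.orientation not in ("forward", "inverted"):
            raise ValueError(f"orientation must be forward/inverted, got {self.orientation!r}")
        if self.event_type == "cut_paste_insertion":
            if self.donor is None or self.acceptor_site is None:
                raise ValueError("cut_paste_insertion requires donor and acceptor_site")
        elif self.event_type == "reciprocal_translocation":
            if self.breakpoints is None or len(self.breakpoints) != 2:
                raise ValueError("reciprocal_translocation requires exactly two breakpoints")
        elif self.event_type == "sequence_insertion":
            if self.acceptor_site is None:
                raise ValueError("sequence_insertion requires acceptor_site")


@dataclass(frozen=True)
class MapSegment:
    """One piece of a derivative map: source ``[src_start, src_end)`` maps to
    ``dst_chrom`` starting at ``dst_start`` (reversed when ``orientation`` is
    ``inverted``)."""

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    orientation: str = "forward"

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    def map_position(self, pos: int) -> int:
        if not (self.src_start <= pos < self.src_end):
            raise ValueError(f"position {pos} outside segment")
        if self.orientation == "forward":
            return self.dst_start + (pos - self.src_start)
        return self.dst_start + (self.src_end - 1 - pos)


@dataclass(frozen=True)
class MappedPiece:
    source: GenomicInterval
    mapped: GenomicInterval | None  # None => unmapped piece

    @property
    def is_mapped(self) -> bool:
        return self.mapped is not None


@dataclass
class DerivativeMap:
    """Piecewise, injective map from reference to derivative coordinates."""

    event_id: str
    segments: list[MapSegment]

    def map_position(self, chrom: str, pos: int) -> tuple[str, int] | None:
        for seg in self.segments:
            if seg.src_chrom == chrom and seg.src_start <= pos < seg.src_end:
                return seg.dst_chrom, seg.map_position(pos)
        return None

    def map_interval(self, query: GenomicInterval) -> list[MappedPiece]:
        """Split ``query`` at map-segment boundaries and map each piece.

        Pieces outside all mapped segments come back with ``mapped=None``.
        Mapped length is conserved and output pieces never overlap.
        """
        cuts = {query.start, query.end}
        for seg in self.segments:
            if seg.src_chrom != query.chrom:
                continue
            for p in (seg.src_start, seg.src_end):
                if query.start < p < query.end:
                    cuts.add(p)
        bounds = sorted(cuts)
        pieces: list[MappedPiece] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            src = GenomicInterval(query.chrom, lo, hi, query.strand)
            seg = next(
                (
                    s
                    for s in self.segments
                    if s.src_chrom == query.chrom and s.src_start <= lo and hi <= s.src_end
                ),
                None,
            )
            if seg is None:
                pieces.append(MappedPiece(source=src, mapped=None))
                continue
            if seg.orientation == "forward":
                d0 = seg.map_position(lo)
                mapped = GenomicInterval(seg.dst_chrom, d0, d0 + (hi - lo), src.strand)
            else:
                d_last = seg.map_position(lo)  # maps to highest derivative base
                d_first = seg.map_position(hi - 1)
                flipped = {"+": "-", "-": "+", ".": "."}[src.strand]
                mapped = GenomicInterval(seg.dst_chrom, d_first, d_last + 1, flipped)
            pieces.append(MappedPiece(source=src, mapped=mapped))
        return pieces

    def to_chain_frame(self) -> pd.DataFrame:
        rows = [
            {
                "src_chrom": s.src_chrom,
                "src_start": s.src_start,
                "src_end": s.src_end,
                "dst_chrom": s.dst_chrom,
                "dst_start": s.dst_start,
                "dst_end": s.dst_start + s.length,
                "strand": "+" if s.orientation == "forward" else "-",
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


def build_derivative_map(
    event: RearrangementEvent, chrom_sizes: Mapping[str, int]
) -> DerivativeMap:
    """Build the piecewise coordinate map of an event's derivative
    chromosome(s)."""

    def _check(chrom: str, pos: int) -> None:
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos <= chrom_sizes[chrom]):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome size")

    segs: list[MapSegment] = []
    if event.event_type == "cut_paste_insertion":
        donor = event.donor
        acc_chrom, p = event.acceptor_site
        _check(donor.chrom, donor.end)
        _check(acc_chrom, p)
        der_a = f"der({acc_chrom})"
        der_d = f"der({donor.chrom})"
        L = donor.length
        if p > 0:
            segs.append(MapSegment(acc_chrom, 0, p, der_a, 0))
        segs.append(MapSegment(donor.chrom, donor.start, donor.end, der_a, p, event.orientation))
        if p < chrom_sizes[acc_chrom]:
            segs.append(MapSegment(acc_chrom, p, chrom_sizes[acc_chrom], der_a, p + L))
        if donor.start > 0:
            segs.append(MapSegment(donor.chrom, 0, donor.start, der_d, 0))
        if donor.end < chrom_sizes[donor.chrom]:
            segs.append(
                MapSegment(donor.chrom, donor.end, chrom_sizes[donor.chrom], der_d, donor.start)
            )
    elif event.event_type == "reciprocal_translocation":
        (chrom_a, b1), (chrom_b, b2) = event.breakpoints
        _check(chrom_a, b1)
        _check(chrom_b, b2)
        der_a, der_b = f"der({chrom_a})", f"der({chrom_b})"
        if b1 > 0:
            segs.append(MapSegment(chrom_a, 0, b1, der_a, 0))
        if b2 < chrom_sizes[chrom_b]:
            segs.append(MapSegment(chrom_b, b2, chrom_sizes[chrom_b], der_a, b1))
        if b2 > 0:
            segs.append(MapSegment(chrom_b, 0, b2, der_b, 0))
        if b1 < chrom_sizes[chrom_a]:
            segs.append(MapSegment(chrom_a, b1, chrom_sizes[chrom_a], der_b, b2))
    else:  # sequence_insertion: identity at pipeline resolution
        acc_chrom, p = event.acceptor_site
        _check(acc_chrom, p)
        segs.append(MapSegment(acc_chrom, 0, chrom_sizes[acc_chrom], acc_chrom, 0))
    return DerivativeMap(event_id=event.event_id, segments=segs)


# ---------------------------------------------------------------------------
# Epigenomic translocation detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionThresholds:
    """Verdict thresholds.

    ``donor_loss``: donor broad-domain footprint coverage below which the
    domain counts as lost (default 0.10, mirroring the <10% low-background
    criterion).  ``acceptor_gain``: gene-body coverage at or above which a
    broad domain counts as gained (default 0.50 — "most of the gene body").
    """

    donor_loss: float = 0.10
    acceptor_gain: float = 0.50


@dataclass(frozen=True)
class RelocationReport:
    sample_id: str
    donor_locus: GenomicInterval
    acceptor_gene: GeneModel
    donor_bd_coverage: float
    acceptor_body_bd_coverage: float
    verdict: str
    accessibility_coverage: float | None = None
    expression_value: float | None = None


def _verdict(donor_cov: float, acceptor_cov: float, thr: DetectionThresholds) -> str:
    lost = donor_cov < thr.donor_loss
    gained = acceptor_cov >= thr.acceptor_gain
    if lost and gained:
        return "relocated"
    if gained:
        return "partial"
    return "not_relocated"


def detect_epigenomic_translocation(
    sample_calls: Sequence[DomainCall],
    wt_consensus: Sequence[ConsensusRegion | GenomicInterval],
    donor_locus: GenomicInterval,
    acceptor_genes: Sequence[GeneModel],
    thresholds: DetectionThresholds = DetectionThresholds(),
    sample_id: str | None = None,
    dnase_peaks: Sequence[GenomicInterval] | None = None,
    expression: Mapping[str, float] | None = None,
) -> list[RelocationReport]:
    """Per acceptor gene: donor-loss / acceptor-gain evidence and verdict.

    ``donor_bd_coverage`` is the fraction of the wild-type donor broad-domain
    footprint (consensus regions clipped to ``donor_locus``) still covered by
    the sample's broad-domain calls; ``acceptor_body_bd_coverage`` is the
    fraction of the gene body covered by them.
    """
    if not acceptor_genes:
        raise ValueError("no acceptor genes supplied")
    wt_ivs = [r.interval if isinstance(r, ConsensusRegion) else r for r in wt_consensus]
    footprint = [
        clipped for iv in wt_ivs if (clipped := iv.clip(donor_locus)) is not None
    ]
    if not footprint:
        raise ValueError(f"no wild-type broad domain defined within donor locus {donor_locus}")
    bd_ivs = union_intervals(
        [c.interval for c in sample_calls if c.element_kind == "BD"]
    )
    foot_len = sum(iv.length for iv in footprint)
    covered = sum(
        ov.length
        for iv in footprint
        for m in bd_ivs
        if (ov := m.clip(iv)) is not None
    )
    donor_cov = covered / foot_len
    sid = sample_id or (sample_calls[0].sample_id if sample_calls else "unknown")
    reports = []
    for gene in sorted(acceptor_genes, key=lambda g: (g.body.chrom, g.body.start)):
        acc_cov = coverage_fraction(gene.body, bd_ivs)
        access = (
            coverage_fraction(gene.body, dnase_peaks) if dnase_peaks is not None else None
        )
        expr = expression.get(gene.gene_id) if expression is not None else None
        reports.append(
            RelocationReport(
                sample_id=sid,
                donor_locus=donor_locus,
                acceptor_gene=gene,
                donor_bd_coverage=donor_cov,
                acceptor_body_bd_coverage=acc_cov,
                verdict=_verdict(donor_cov, acc_cov, thresholds),
                accessibility_coverage=access,
                expression_value=expr,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[RelocationReport]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "acceptor_gene": r.acceptor_gene.gene_id,
            "donor_bd_coverage": r.donor_bd_coverage,
            "acceptor_body_bd_coverage": r.acceptor_body_bd_coverage,
            "accessibility_coverage": r.accessibility_coverage,
            "expression_value": r.expression_value,
            "verdict": r.verdict,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def bidirectional_effect_scan(
    sample_calls: Sequence[DomainCall],
    insertion_site: tuple[str, int],
    neighbor_genes: Sequence[GeneModel],
    flank: int = 500_000,
    gain_threshold: float = 0.50,
) -> pd.DataFrame:
    """Broad-domain gene-body coverage for every gene within ``flank`` of an
    insertion site — a relocated super-enhancer can seed broad domains over
    genes on *both* sides of its landing point."""
    chrom, pos = insertion_site
    site = GenomicInterval(chrom, pos, pos + 1)
    bd_ivs = union_intervals(
        [c.interval for c in sample_calls if c.element_kind == "BD"]
    )
    rows = []
    for gene in sorted(neighbor_genes, key=lambda g: (g.body.chrom, g.body.start)):
        dist = interval_gap(gene.body, site)
        if dist > flank:
            continue
        cov = coverage_fraction(gene.body, bd_ivs)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "distance_to_insertion": int(dist),
                "bd_body_coverage": cov,
                "flagged": cov >= gain_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "distance_to_insertion", "bd_body_coverage", "flagged"]
    )
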