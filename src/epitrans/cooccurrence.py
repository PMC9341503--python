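"""Genome-wide proximity of H3K4me3 broad domains to super-enhancers.

Anchors (broad domains, or 1-kb control promoters overlapping a TSS) are
profiled by distance to the nearest super-enhancer in 100-kb bins up to 5 Mb,
after excluding super-enhancers that overlap a broad domain or a
broad-domain-bearing gene.  The headline contrast — proportion of anchors
with a super-enhancer within 100 kb — is tested with Fisher's exact test;
per-bin contrasts are Benjamini–Hochberg corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import ConsensusRegion, DomainCall
from .intervals import (
    ACTIVE_STATES,
    GeneModel,
    GenomicInterval,
    PeakTrack,
    SegmentationTrack,
    coverage_fraction,
    interval_gap,
)

CONTROL_PROMOTER_WIDTH = 1000
DEFAULT_BIN_WIDTH = 100_000
DEFAULT_MAX_DISTANCE = 5_000_000


@dataclass(frozen=True)
class Anchor:
    interval: GenomicInterval
    gene_id: str | None = None


@dataclass
class AnchorSet:
    """Anchors of one kind: broad domains or 1-kb control promoters."""

    kind: str
    anchors: list[Anchor]

    def __post_init__(self) -> None:
        if self.kind not in ("broad_domain", "control_promoter"):
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        if self.kind == "control_promoter":
            for a in self.anchors:
                if a.interval.length != CONTROL_PROMOTER_WIDTH:
                    raise ValueError(
                        f"control promoter {a.interval} is not {CONTROL_PROMOTER_WIDTH} bp"
                    )


@dataclass
class ProximityProfile:
    """Nearest-super-enhancer distances binned per anchor."""

    kind: str
    bin_counts: np.ndarray
    beyond_max: int
    n_anchors: int
    bin_width: int = DEFAULT_BIN_WIDTH
    max_distance: int = DEFAULT_MAX_DISTANCE

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if int(self.bin_counts.sum()) + self.beyond_max != self.n_anchors:
            raise ValueError("profile does not conserve anchors")

    @property
    def n_bins(self) -> int:
        return self.max_distance // self.bin_width

    @property
    def within_first_bin(self) -> int:
        """Anchors with a super-enhancer strictly within one bin width (100 kb)."""
        return int(self.bin_counts[0])

    def proportion_within_first_bin(self) -> float:
        return self.within_first_bin / self.n_anchors if self.n_anchors else float("nan")


def _intervals(items: Iterable) -> list[GenomicInterval]:
    out = []
    for x in items:
        if isinstance(x, GenomicInterval):
            out.append(x)
        elif isinstance(x, (DomainCall,)):
            out.append(x.interval)
        elif isinstance(x, ConsensusRegion):
            out.append(x.interval)
        elif isinstance(x, Anchor):
            out.append(x.interval)
        else:
            raise TypeError(f"cannot interpret {type(x).__name__} as an interval")
    return out


def select_control_promoters(
    genes: Sequence[GeneModel],
    h3k4me3_peaks: PeakTrack,
    bd_calls: Sequence,
    width: int = CONTROL_PROMOTER_WIDTH,
) -> AnchorSet:
    """Select narrow-promoter control anchors.

    A gene contributes a ``width``-bp window centred on its TSS iff an
    H3K4me3 peak overlaps the window and no broad domain overlaps the gene
    body or the promoter window of *any* transcription start site of that
    gene (genes with a broad domain at an alternative TSS are excluded).
    """
    bds = _intervals(bd_calls)
    half = width // 2
    by_gene: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(g)
    anchors: list[Anchor] = []
    for gene_id in sorted(by_gene):
        isoforms = by_gene[gene_id]
        windows = [
            GenomicInterval(g.body.chrom, max(0, g.tss - half), g.tss - half + width)
            for g in isoforms
        ]
        excluded = any(
            bd.overlaps(g.body) or bd.overlaps(w)
            for bd in bds
            for g, w in zip(isoforms, windows)
        )
        if excluded:
            continue
        for w in windows:
            if any(p.overlaps(w) for p in h3k4me3_peaks.peaks):
                anchors.append(Anchor(interval=w, gene_id=gene_id))
                break
    return AnchorSet(kind="control_promoter", anchors=anchors)


def apply_se_exclusions(
    ses: Sequence,
    bds: Sequence,
    genes: Sequence[GeneModel],
) -> list[GenomicInterval]:
    """Drop super-enhancers overlapping a broad domain and/or the body of a
    gene that carries a broad domain."""
    se_ivs = _intervals(ses)
    bd_ivs = _intervals(bds)
    bd_gene_bodies = [
        g.body for g in genes if any(bd.overlaps(g.body) for bd in bd_ivs)
    ]
    kept = []
    for se in se_ivs:
        if any(se.overlaps(bd) for bd in bd_ivs):
            continue
        if any(se.overlaps(body) for body in bd_gene_bodies):
            continue
        kept.append(se)
    return kept


def proximity_profile(
    anchors: AnchorSet,
    ses: Sequence,
    bin_width: int = DEFAULT_BIN_WIDTH,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> ProximityProfile:
    """Bin each anchor's nearest-super-enhancer edge distance.

    Bins are half-open ``[k*bin_width, (k+1)*bin_width)``; the search is
    same-chromosome only, so anchors on super-enhancer-free chromosomes land
    in ``beyond_max``.
    """
    se_ivs = _intervals(ses)
    se_by_chrom: dict[str, list[GenomicInterval]] = {}
    for se in se_ivs:
        se_by_chrom.setdefault(se.chrom, []).append(se)
    n_bins = max_distance // bin_width
    counts = np.zeros(n_bins, dtype=int)
    beyond = 0
    for a in anchors.anchors:
        cands = se_by_chrom.get(a.interval.chrom, [])
        d = min((interval_gap(a.interval, se) for se in cands), default=float("inf"))
        if d < max_distance:
            counts[int(d // bin_width)] += 1
        else:
            beyond += 1
    return ProximityProfile(
        kind=anchors.kind,
        bin_counts=counts,
        beyond_max=beyond,
        n_anchors=len(anchors.anchors),
        bin_width=bin_width,
        max_distance=max_distance,
    )


@dataclass
class ProximityTestReport:
    """Headline 2x2 Fisher test plus BH-corrected per-bin contrasts."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    significant: bool
    alpha: float
    bd_proportion_within: float
    ctrl_proportion_within: float
    per_bin: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.per_bin


def compare_proximity(
    bd_profile: ProximityProfile,
    ctrl_profile: ProximityProfile,
    alpha: float = 0.05,
) -> ProximityTestReport:
    """Test whether broad domains have a proximal super-enhancer (within one
    bin width) more often than control promoters."""
    if bd_profile.n_anchors == 0 or ctrl_profile.n_anchors == 0:
        raise ValueError("both profiles must contain at least one anchor")
    if (
        bd_profile.bin_width != ctrl_profile.bin_width
        or bd_profile.max_distance != ctrl_profile.max_distance
    ):
        raise ValueError("profiles use different binning")
    a = bd_profile.within_first_bin
    b = bd_profile.n_anchors - a
    c = ctrl_profile.within_first_bin
    d = ctrl_profile.n_anchors - c
    table = ((a, b), (c, d))
    if (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1.0", stacklevel=2)
        odds, p = float("nan"), 1.0
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    bd_counts = np.append(bd_profile.bin_counts, bd_profile.beyond_max)
    ctrl_counts = np.append(ctrl_profile.bin_counts, ctrl_profile.beyond_max)
    labels = [f"bin_{k}" for k in range(bd_profile.n_bins)] + ["beyond_max"]
    pvals = []
    for bd_k, ctrl_k in zip(bd_counts, ctrl_counts):
        t = (
            (int(bd_k), bd_profile.n_anchors - int(bd_k)),
            (int(ctrl_k), ctrl_profile.n_anchors - int(ctrl_k)),
        )
        if (t[0][0] + t[1][0] == 0) or (t[0][1] + t[1][1] == 0):
            pvals.append(1.0)
        else:
            pvals.append(stats.fisher_exact(t, alternative="two-sided")[1])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    per_bin = pd.DataFrame(
        {
            "bin": labels,
            "bd_count": bd_counts,
            "ctrl_count": ctrl_counts,
            "p_value": pvals,
            "q_value": qvals,
            "significant": reject,
        }
    )
    return ProximityTestReport(
        table=table,
        odds_ratio=float(odds),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
        bd_proportion_within=bd_profile.proportion_within_first_bin(),
        ctrl_proportion_within=ctrl_profile.proportion_within_first_bin(),
        per_bin=per_bin,
    )


@dataclass(frozen=True)
class ExclusivityCall:
    region: ConsensusRegion
    cell_type: str
    background_coverages: Mapping[str, float]
    exclusive: bool


def classify_exclusivity(
    region: ConsensusRegion,
    cell_type: str,
    active_tracks_by_celltype: Mapping[str, SegmentationTrack | Sequence[GenomicInterval]],
    active_states: frozenset = ACTIVE_STATES,
    threshold: float = 0.10,
) -> ExclusivityCall:
    """A region is cell-type exclusive iff every *other* cell type's
    active-chromatin background covers strictly less than ``threshold`` of it."""
    coverages: dict[str, float] = {}
    for ct in sorted(active_tracks_by_celltype):
        if ct == cell_type:
            continue
        src = active_tracks_by_celltype[ct]
        if isinstance(src, SegmentationTrack):
            ivs = src.filter_states(active_states)
        else:
            ivs = list(src)
        coverages[ct] = coverage_fraction(region.interval, ivs)
    exclusive = all(cov < threshold for cov in coverages.values())
    return ExclusivityCall(
        region=region,
        cell_type=cell_type,
        background_coverages=coverages,
        exclusive=exclusive,
    )
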