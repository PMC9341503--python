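"""Domain calling: H3K4me3 broad domains, super-enhancers, broad promoters
and Polycomb regions, from chromatin-state tracks or mark-peak tracks, plus
cross-sample consensus building.

The calling rules mirror the chromatin-state consensus procedure used for
BLUEPRINT B-cell maps: filter segments to the element's state subset
(state 9 for super-enhancers, state 7 for Polycomb, states 10+11 for
promoters/broad domains), merge runs skipping gaps < 1 kb, and keep regions
strictly exceeding the element's size threshold (> 2 kb genome-wide broad
domains, > 5 kb genome-wide super-enhancers, > 2.5 kb locus super-enhancers
and promoters; the locus broad-domain scan uses a 15-kb minimum, inclusive).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    PeakTrack,
    SegmentationTrack,
    intersect_support,
    merge_with_gap,
    union_intervals,
)

ELEMENT_KINDS = ("BD", "SE", "promoter", "polycomb")


@dataclass(frozen=True)
class ElementRule:
    """How one element kind is called.

    ``source`` selects the input channel: ``states`` (chromatin-state
    segments) or ``marks`` (histone-mark peaks).  ``min_size`` is a strict
    lower bound unless ``min_size_inclusive``.
    """

    rule_id: str
    element_kind: str
    source: str
    state_set: frozenset = frozenset()
    mark_set: frozenset = frozenset()
    min_size: int = 2000
    min_size_inclusive: bool = False
    merge_gap: int = 1000

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.element_kind!r}")
        if self.source not in ("states", "marks"):
            raise ValueError(f"rule source must be 'states' or 'marks', got {self.source!r}")
        if self.min_size <= 0:
            raise ValueError("min_size must be positive")
        if bool(self.state_set) == bool(self.mark_set):
            raise ValueError("exactly one of state_set/mark_set must be populated")

    def passes_size(self, length: int) -> bool:
        return length >= self.min_size if self.min_size_inclusive else length > self.min_size


def _rule(rule_id, kind, source, *, states=(), marks=(), min_size, inclusive=False):
    return ElementRule(
        rule_id=rule_id,
        element_kind=kind,
        source=source,
        state_set=frozenset(states),
        mark_set=frozenset(marks),
        min_size=min_size,
        min_size_inclusive=inclusive,
    )


#: Default state-based rules (sizes in bp).
STATE_RULES: dict[str, ElementRule] = {
    "bd_genomewide": _rule("bd_genomewide", "BD", "states", states={10, 11}, min_size=2000),
    "bd_locus": _rule("bd_locus", "BD", "states", states={10, 11}, min_size=15000, inclusive=True),
    "se_genomewide": _rule("se_genomewide", "SE", "states", states={9}, min_size=5000),
    "se_locus": _rule("se_locus", "SE", "states", states={9}, min_size=2500),
    "promoter": _rule("promoter", "promoter", "states", states={10, 11}, min_size=2500),
    "polycomb": _rule("polycomb", "polycomb", "states", states={7}, min_size=200, inclusive=True),
}

#: Default mark-based rules.
MARK_RULES: dict[str, ElementRule] = {
    "bd_marks": _rule("bd_marks", "BD", "marks", marks={"H3K4me3"}, min_size=2000),
    "se_marks": _rule("se_marks", "SE", "marks", marks={"H3K4me1", "H3K27ac"}, min_size=5000),
}


@dataclass(frozen=True)
class DomainCall:
    """A called element with provenance."""

    interval: GenomicInterval
    element_kind: str
    sample_id: str
    rule_id: str
    component_segments: int = 1


@dataclass(frozen=True)
class ConsensusRegion:
    """A multi-sample merged element with per-sample support."""

    interval: GenomicInterval
    element_kind: str
    supporting_samples: tuple[str, ...]
    support_fraction: float


def call_state_domains(
    track: SegmentationTrack,
    rule: ElementRule,
    locus: GenomicInterval | None = None,
) -> list[DomainCall]:
    """Call elements from a chromatin-state track.

    Segments with state in the rule's state set are extracted (restricted to
    ``locus`` if given), gap-merged, and size-filtered.
    """
    if rule.source != "states":
        raise ValueError(f"rule {rule.rule_id} is not state-based")
    unknown = rule.state_set - set(track.state_alphabet)
    if unknown and track.segments:
        warnings.warn(
            f"states {sorted(unknown)} absent from track {track.sample_id}",
            stacklevel=2,
        )
    ivs = track.filter_states(rule.state_set)
    if locus is not None:
        ivs = [clipped for iv in ivs if (clipped := iv.clip(locus)) is not None]
    calls = []
    for merged in merge_with_gap(ivs, rule.merge_gap):
        if rule.passes_size(merged.length):
            n_comp = sum(1 for iv in ivs if iv.overlaps(merged))
            calls.append(
                DomainCall(
                    interval=merged,
                    element_kind=rule.element_kind,
                    sample_id=track.sample_id,
                    rule_id=rule.rule_id,
                    component_segments=n_comp,
                )
            )
    return calls


def call_mark_domains(
    peaks_by_mark: Mapping[str, PeakTrack], rule: ElementRule
) -> list[DomainCall]:
    """Call elements from histone-mark peaks.

    Single-mark rules (broad domains from H3K4me3) merge that mark's peaks.
    Multi-mark rules (super-enhancers from H3K4me1 + H3K27ac) take the
    base-level intersection of the per-mark merged footprints, re-merge, and
    size-filter — both marks jointly define the element.
    """
    if rule.source != "marks":
        raise ValueError(f"rule {rule.rule_id} is not mark-based")
    for mark in sorted(rule.mark_set):
        if mark not in peaks_by_mark:
            raise ValueError(f"missing required mark {mark!r}")
    sample_ids = {peaks_by_mark[m].sample_id for m in rule.mark_set}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else "+".join(sorted(sample_ids))
    per_mark = [
        merge_with_gap(peaks_by_mark[m].peaks, rule.merge_gap)
        for m in sorted(rule.mark_set)
    ]
    if len(per_mark) == 1:
        footprint = per_mark[0]
    else:
        n = len(per_mark)
        footprint = [iv for iv, sup in intersect_support(per_mark) if sup == n]
    calls = []
    for merged in merge_with_gap(footprint, rule.merge_gap):
        if rule.passes_size(merged.length):
            calls.append(
                DomainCall(
                    interval=merged,
                    element_kind=rule.element_kind,
                    sample_id=sample_id,
                    rule_id=rule.rule_id,
                    component_segments=sum(1 for iv in footprint if iv.overlaps(merged)),
                )
            )
    return calls


def build_consensus(
    calls_by_sample: Mapping[str, Sequence[DomainCall]],
    element_kind: str,
    min_support: float = 0.5,
    merge_gap: int = 1000,
    rule: ElementRule | None = None,
) -> list[ConsensusRegion]:
    """Merge per-sample calls into consensus regions.

    Bases supported by at least ``ceil(min_support * n_samples)`` samples are
    kept, gap-merged, and size-filtered by ``rule`` (default: the genome-wide
    state rule for ``element_kind``).  Majority support (0.5) is the default
    because strict intersection would erase developmentally dynamic elements.
    """
    if not calls_by_sample:
        raise ValueError("at least one sample is required")
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if rule is None:
        defaults = {"BD": "bd_genomewide", "SE": "se_genomewide",
                    "promoter": "promoter", "polycomb": "polycomb"}
        rule = STATE_RULES[defaults[element_kind]]
    samples = sorted(calls_by_sample)
    per_sample = {
        s: union_intervals(
            [c.interval for c in calls_by_sample[s] if c.element_kind == element_kind]
        )
        for s in samples
    }
    n = len(samples)
    need = math.ceil(min_support * n)
    supported = [
        iv for iv, sup in intersect_support([per_sample[s] for s in samples]) if sup >= need
    ]
    regions = []
    for merged in merge_with_gap(supported, merge_gap):
        if not rule.passes_size(merged.length):
            continue
        supporting = tuple(
            s for s in samples if any(iv.overlaps(merged) for iv in per_sample[s])
        )
        regions.append(
            ConsensusRegion(
                interval=merged,
                element_kind=element_kind,
                supporting_samples=supporting,
                support_fraction=len(supporting) / n,
            )
        )
    return regions


def annotate_locus_elements(
    consensus: Sequence[ConsensusRegion],
    locus_template: Mapping[str, GenomicInterval],
) -> pd.DataFrame:
    """Label consensus regions by the template element with maximal overlap.

    Ties break toward the template element whose start is nearest; regions
    with no template overlap are labelled ``novel``.
    """
    rows = []
    for region in consensus:
        best_label, best_key = "novel", None
        for name in sorted(locus_template):
            tmpl = locus_template[name]
            ov = region.interval.overlap_length(tmpl)
            if ov <= 0:
                continue
            key = (-ov, abs(region.interval.start - tmpl.start), name)
            if best_key is None or key < best_key:
                best_key, best_label = key, name
        rows.append(
            {
                "chrom": region.interval.chrom,
                "start": region.interval.start,
                "end": region.interval.end,
                "length": region.interval.length,
                "element_kind": region.element_kind,
                "label": best_label,
                "support_fraction": region.support_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "element_kind", "label", "support_fraction",
        ],
    )
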