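"""Element calling and consensus building against hand-worked and per-base
oracles."""

import math

import numpy as np
import pytest

from epitrans import (
    DomainCall,
    GenomicInterval,
    PeakTrack,
    SegmentationTrack,
    StateSegment,
    annotate_locus_elements,
    build_consensus,
    call_mark_domains,
    call_state_domains,
)
from epitrans.calling import MARK_RULES, STATE_RULES, ConsensusRegion
from conftest import CHROM, oracle_merge, oracle_support, random_intervals


def gi(start, end, chrom=CHROM):
    return GenomicInterval(chrom, start, end)


def track_of(ivs_states, sample="s1"):
    return SegmentationTrack.from_segments(
        sample, [StateSegment(iv, st) for iv, st in ivs_states]
    )


def tile(chrom, start, end, states, chunk=1800, gap=400):
    """Tile [start, end) with chunks of alternating states and sub-1-kb gaps."""
    out, pos, k = [], start, 0
    while pos < end:
        e = min(pos + chunk, end)
        out.append((GenomicInterval(chrom, pos, e), states[k % len(states)]))
        pos, k = e + gap, k + 1
    out[-1] = (GenomicInterval(chrom, out[-1][0].start, end), out[-1][1])
    return out


class TestStateDomainCalling:
    def test_dh_broad_domain_from_tiled_printed_coordinates(self):
        # states 10/11 tiling the published D_H region with sub-1-kb gaps
        track = track_of(tile("chr14", 106_346_800, 106_387_800, (10, 11)))
        calls = call_state_domains(track, STATE_RULES["bd_locus"])
        assert len(calls) == 1
        assert calls[0].interval == GenomicInterval("chr14", 106_346_800, 106_387_800)
        assert calls[0].interval.length == 41_000
        assert calls[0].component_segments > 1

    def test_exact_threshold_size_not_called(self):
        # strict ">": a 2500-bp state-9 run is not a locus super-enhancer
        track = track_of([(gi(0, 2500), 9)])
        assert call_state_domains(track, STATE_RULES["se_locus"]) == []
        track2 = track_of([(gi(0, 2501), 9)])
        assert len(call_state_domains(track2, STATE_RULES["se_locus"])) == 1

    def test_polycomb_run_called(self):
        track = track_of([(gi(1000, 1600), 7), (gi(5000, 5200), 11)])
        calls = call_state_domains(track, STATE_RULES["polycomb"])
        assert [c.interval for c in calls] == [gi(1000, 1600)]
        assert calls[0].element_kind == "polycomb"

    def test_locus_restriction_clips_segments(self):
        track = track_of(tile(CHROM, 0, 40_000, (10, 11)))
        locus = gi(10_000, 30_000)
        calls = call_state_domains(track, STATE_RULES["bd_locus"], locus=locus)
        assert len(calls) == 1
        assert calls[0].interval == locus

    def test_unknown_state_warns_not_errors(self):
        track = track_of([(gi(0, 3000), 9)])
        with pytest.warns(UserWarning, match="absent"):
            calls = call_state_domains(track, STATE_RULES["bd_genomewide"])
        assert calls == []

    def test_wrong_rule_source_rejected(self):
        track = track_of([(gi(0, 3000), 9)])
        with pytest.raises(ValueError, match="state-based"):
            call_state_domains(track, MARK_RULES["bd_marks"])


class TestMarkDomainCalling:
    def test_broad_domain_size_rule(self):
        wide = {"H3K4me3": PeakTrack("s", "H3K4me3", [gi(0, 41_000)])}
        narrow = {"H3K4me3": PeakTrack("s", "H3K4me3", [gi(0, 1800)])}
        assert len(call_mark_domains(wide, MARK_RULES["bd_marks"])) == 1
        assert call_mark_domains(narrow, MARK_RULES["bd_marks"]) == []

    def test_super_enhancer_from_joint_mark_intersection(self):
        # joint footprint [2000, 9000) = 7000 bp > 5000
        peaks = {
            "H3K4me1": PeakTrack("s", "H3K4me1", [gi(0, 10_000)]),
            "H3K27ac": PeakTrack("s", "H3K27ac", [gi(2000, 9000)]),
        }
        calls = call_mark_domains(peaks, MARK_RULES["se_marks"])
        assert [c.interval for c in calls] == [gi(2000, 9000)]

    def test_single_mark_makes_no_super_enhancer(self):
        peaks = {
            "H3K4me1": PeakTrack("s", "H3K4me1", [gi(0, 10_000)]),
            "H3K27ac": PeakTrack("s", "H3K27ac", [gi(50_000, 51_000)]),
        }
        assert call_mark_domains(peaks, MARK_RULES["se_marks"]) == []

    def test_missing_mark_named_in_error(self):
        peaks = {"H3K4me1": PeakTrack("s", "H3K4me1", [gi(0, 10_000)])}
        with pytest.raises(ValueError, match="H3K27ac"):
            call_mark_domains(peaks, MARK_RULES["se_marks"])


def _calls(sample, ivs, kind="BD"):
    return [
        DomainCall(interval=iv, element_kind=kind, sample_id=sample, rule_id="r")
        for iv in ivs
    ]


class TestConsensus:
    def test_identical_calls_full_support(self):
        by_sample = {s: _calls(s, [gi(0, 5000)]) for s in ("a", "b", "c")}
        regions = build_consensus(by_sample, "BD", min_support=0.5)
        assert len(regions) == 1
        assert regions[0].interval == gi(0, 5000)
        assert regions[0].support_fraction == 1.0
        assert regions[0].supporting_samples == ("a", "b", "c")

    def test_minority_call_dropped(self):
        by_sample = {"a": _calls("a", [gi(0, 5000)]), "b": [], "c": []}
        assert build_consensus(by_sample, "BD", min_support=0.5) == []

    def test_invalid_support_rejected(self):
        with pytest.raises(ValueError):
            build_consensus({"a": []}, "BD", min_support=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_staggered_calls_match_per_base_majority_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = 20_000
        sets = {
            f"s{k}": [
                gi(s, min(length, s + 2100 + int(rng.integers(0, 3000))))
                for s in rng.integers(0, length - 2500, size=rng.integers(1, 4))
            ]
            for k in range(4)
        }
        by_sample = {s: _calls(s, ivs) for s, ivs in sets.items()}
        regions = build_consensus(by_sample, "BD", min_support=0.5, merge_gap=1000)
        support = oracle_support(list(sets.values()), length)
        majority = oracle_merge(
            [gi(int(lo), int(hi)) for lo, hi in _runs(support >= 2)], 1000, length
        )
        expected = [iv for iv in majority if iv.length > 2000]
        assert [r.interval for r in regions] == expected

    @pytest.mark.parametrize("mode,need", [("union", 1), ("intersection", 4)])
    def test_support_extremes_match_union_and_intersection(self, mode, need):
        rng = np.random.default_rng(99)
        length = 10_000
        sets = {
            f"s{k}": random_intervals(rng, 3, length, max_len=4000) for k in range(4)
        }
        by_sample = {s: _calls(s, ivs) for s, ivs in sets.items()}
        min_support = 1e-9 if mode == "union" else 1.0
        regions = build_consensus(by_sample, "BD", min_support=min_support, merge_gap=500)
        support = oracle_support(list(sets.values()), length)
        runs = [gi(int(lo), int(hi)) for lo, hi in _runs(support >= need)]
        expected = [iv for iv in oracle_merge(runs, 500, length) if iv.length > 2000]
        assert [r.interval for r in regions] == expected

    def test_monotone_in_merge_gap(self):
        rng = np.random.default_rng(5)
        ivs_states = [
            (iv, 10 if k % 2 else 11)
            for k, iv in enumerate(random_intervals(rng, 12, 50_000, max_len=3000))
        ]
        track = SegmentationTrack.from_segments(
            "s", [StateSegment(iv, st) for iv, st in _dedup(ivs_states)]
        )
        totals = []
        for gap in (200, 600, 1000, 2000):
            rule = STATE_RULES["bd_genomewide"]
            rule = type(rule)(
                rule_id="g", element_kind="BD", source="states",
                state_set=frozenset({10, 11}), min_size=2000, merge_gap=gap,
            )
            totals.append(sum(c.interval.length for c in call_state_domains(track, rule)))
        assert totals == sorted(totals)


def _runs(mask):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return idx.reshape(-1, 2)


def _dedup(ivs_states):
    """Drop overlapping intervals so the track constructor accepts them."""
    out, prev_end = [], -1
    for iv, st in sorted(ivs_states, key=lambda t: t[0]):
        if iv.start >= prev_end:
            out.append((iv, st))
            prev_end = iv.end
    return out


class TestLocusAnnotation:
    TEMPLATE = {
        "Edelta": GenomicInterval("chr14", 106_281_800, 106_289_800),
        "Emu": GenomicInterval("chr14", 106_299_800, 106_326_200),
    }

    def _region(self, start, end):
        return ConsensusRegion(
            interval=GenomicInterval("chr14", start, end),
            element_kind="SE",
            supporting_samples=("a",),
            support_fraction=1.0,
        )

    def test_exact_match_labelled(self):
        df = annotate_locus_elements([self._region(106_281_800, 106_289_800)], self.TEMPLATE)
        assert df.label.tolist() == ["Edelta"]

    def test_no_overlap_is_novel(self):
        df = annotate_locus_elements([self._region(1000, 9000)], self.TEMPLATE)
        assert df.label.tolist() == ["novel"]

    def test_straddling_region_assigned_to_larger_overlap(self):
        # overlaps Edelta by 4 kb and Emu by 20 kb
        df = annotate_locus_elements([self._region(106_285_800, 106_319_800)], self.TEMPLATE)
        assert df.label.tolist() == ["Emu"]

    def test_tie_breaks_to_nearer_start(self):
        template = {
            "left": GenomicInterval(CHROM, 0, 1000),
            "right": GenomicInterval(CHROM, 2000, 3000),
        }
        # overlaps each template element by exactly 500 bp; starts nearer "left"
        df = annotate_locus_elements([self._r(CHROM, 500, 2500)], template)
        assert df.label.tolist() == ["left"]

    def _r(self, chrom, start, end):
        return ConsensusRegion(
            interval=GenomicInterval(chrom, start, end),
            element_kind="SE",
            supporting_samples=("a",),
            support_fraction=1.0,
        )
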