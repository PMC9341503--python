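"""Derivative-chromosome coordinate maps and relocation detection."""

import numpy as np
import pytest

from epitrans import (
    DetectionThresholds,
    GeneModel,
    GenomicInterval,
    RearrangementEvent,
    bidirectional_effect_scan,
    build_derivative_map,
    detect_epigenomic_translocation,
)
from epitrans.calling import DomainCall

SIZES = {"chr14": 10_000, "chr11": 8_000}


def cut_paste(orientation="forward"):
    return RearrangementEvent(
        event_id="e1",
        event_type="cut_paste_insertion",
        donor=GenomicInterval("chr14", 1000, 2000),
        acceptor_site=("chr11", 500),
        orientation=orientation,
    )


def reciprocal():
    return RearrangementEvent(
        event_id="e2",
        event_type="reciprocal_translocation",
        breakpoints=(("chr14", 7000), ("chr11", 300)),
    )


class TestEventValidation:
    def test_cut_paste_requires_donor_and_acceptor(self):
        with pytest.raises(ValueError):
            RearrangementEvent(event_id="x", event_type="cut_paste_insertion")

    def test_reciprocal_requires_two_breakpoints(self):
        with pytest.raises(ValueError):
            RearrangementEvent(event_id="x", event_type="reciprocal_translocation")

    def test_breakpoint_beyond_chromosome_rejected(self):
        ev = RearrangementEvent(
            event_id="x",
            event_type="reciprocal_translocation",
            breakpoints=(("chr14", 99_999), ("chr11", 300)),
        )
        with pytest.raises(ValueError, match="beyond"):
            build_derivative_map(ev, SIZES)


class TestDerivativeMap:
    def test_forward_cut_paste_offset(self):
        dmap = build_derivative_map(cut_paste(), SIZES)
        # donor base 1500 lands at acceptor position 500 + (1500 - 1000)
        assert dmap.map_position("chr14", 1500) == ("der(chr11)", 1000)

    def test_inverted_cut_paste_is_a_permutation(self):
        ev = RearrangementEvent(
            event_id="inv",
            event_type="cut_paste_insertion",
            donor=GenomicInterval("chr14", 1000, 1010),
            acceptor_site=("chr11", 500),
            orientation="inverted",
        )
        dmap = build_derivative_map(ev, SIZES)
        images = [dmap.map_position("chr14", x)[1] for x in range(1000, 1010)]
        assert sorted(images) == list(range(500, 510))
        assert images == list(range(509, 499, -1))

    def test_reciprocal_breakpoint_arithmetic(self):
        dmap = build_derivative_map(reciprocal(), SIZES)
        # chr11:400 is 100 bp past breakpoint b2, so lands 100 bp past b1
        assert dmap.map_position("chr11", 400) == ("der(chr14)", 7100)
        assert dmap.map_position("chr14", 6999) == ("der(chr14)", 6999)
        assert dmap.map_position("chr14", 7000) == ("der(chr11)", 300)

    @pytest.mark.parametrize("make_event", [cut_paste, reciprocal])
    def test_bijective_over_all_bases(self, make_event):
        sizes = {"chr14": 2000, "chr11": 1500}
        ev = make_event()
        if ev.event_type == "cut_paste_insertion":
            ev = RearrangementEvent(
                event_id=ev.event_id, event_type=ev.event_type,
                donor=GenomicInterval("chr14", 300, 700),
                acceptor_site=("chr11", 200), orientation="forward",
            )
        else:
            ev = RearrangementEvent(
                event_id=ev.event_id, event_type=ev.event_type,
                breakpoints=(("chr14", 1200), ("chr11", 400)),
            )
        dmap = build_derivative_map(ev, sizes)
        images = set()
        n = 0
        for chrom, size in sizes.items():
            for pos in range(size):
                dest = dmap.map_position(chrom, pos)
                assert dest is not None, f"{chrom}:{pos} unmapped"
                assert dest not in images, f"collision at {dest}"
                images.add(dest)
                n += 1
        assert n == sum(sizes.values())

    def test_sequence_insertion_is_identity(self):
        ev = RearrangementEvent(
            event_id="ins", event_type="sequence_insertion", acceptor_site=("chr11", 500)
        )
        dmap = build_derivative_map(ev, SIZES)
        assert dmap.map_position("chr11", 1234) == ("chr11", 1234)


class TestMapInterval:
    def test_interior_interval_shifts_rigidly(self):
        dmap = build_derivative_map(cut_paste(), SIZES)
        pieces = dmap.map_interval(GenomicInterval("chr14", 1200, 1400))
        assert len(pieces) == 1
        assert pieces[0].mapped == GenomicInterval("der(chr11)", 700, 900)

    def test_breakpoint_straddle_splits_in_two(self):
        dmap = build_derivative_map(reciprocal(), SIZES)
        pieces = dmap.map_interval(GenomicInterval("chr14", 6900, 7100))
        assert len(pieces) == 2
        assert pieces[0].mapped.chrom == "der(chr14)"
        assert pieces[1].mapped.chrom == "der(chr11)"

    def test_acceptor_tail_shifted_by_donor_length(self):
        dmap = build_derivative_map(cut_paste(), SIZES)
        pieces = dmap.map_interval(GenomicInterval("chr11", 600, 900))
        assert pieces[0].mapped == GenomicInterval("der(chr11)", 1600, 1900)

    @pytest.mark.parametrize("orientation", ["forward", "inverted"])
    def test_matches_per_base_mapping_oracle(self, orientation):
        dmap = build_derivative_map(cut_paste(orientation), SIZES)
        query = GenomicInterval("chr14", 800, 2300)
        pieces = dmap.map_interval(query)
        mapped_bases = set()
        for piece in pieces:
            if piece.mapped is None:
                continue
            expected = {
                dmap.map_position(query.chrom, p)
                for p in range(piece.source.start, piece.source.end)
            }
            got = {
                (piece.mapped.chrom, p)
                for p in range(piece.mapped.start, piece.mapped.end)
            }
            assert got == expected
            assert not (mapped_bases & got)
            mapped_bases |= got
        total_src = sum(p.source.length for p in pieces)
        total_mapped = sum(p.mapped.length for p in pieces if p.mapped is not None)
        assert total_src == query.length
        assert total_mapped == len(mapped_bases)

    def test_length_conservation_and_no_overlap(self):
        dmap = build_derivative_map(reciprocal(), SIZES)
        pieces = dmap.map_interval(GenomicInterval("chr11", 0, 8000))
        assert sum(p.mapped.length for p in pieces if p.mapped) == 8000


def bd(sample, chrom, start, end):
    return DomainCall(
        interval=GenomicInterval(chrom, start, end),
        element_kind="BD",
        sample_id=sample,
        rule_id="r",
    )


DONOR = GenomicInterval("chr14", 1_000_000, 1_041_000)
WT_BD = [DONOR]
GENE = GeneModel("onco", GenomicInterval("chr11", 500_000, 513_400, "+"), "+")


class TestDetector:
    def test_relocated_when_donor_lost_and_acceptor_gained(self):
        calls = [bd("m", "chr11", 500_000, 513_000)]
        reports = detect_epigenomic_translocation(calls, WT_BD, DONOR, [GENE], sample_id="m")
        r = reports[0]
        assert r.verdict == "relocated"
        assert r.donor_bd_coverage == 0.0
        assert r.acceptor_body_bd_coverage > 0.9

    def test_healthy_pattern_not_relocated(self):
        calls = [bd("h", "chr14", 1_000_000, 1_041_000)]
        r = detect_epigenomic_translocation(calls, WT_BD, DONOR, [GENE], sample_id="h")[0]
        assert r.verdict == "not_relocated"
        assert r.donor_bd_coverage == pytest.approx(1.0)
        assert r.acceptor_body_bd_coverage == 0.0

    def test_retained_and_gained_is_partial(self):
        calls = [
            bd("p", "chr14", 1_000_000, 1_041_000),
            bd("p", "chr11", 500_000, 513_000),
        ]
        r = detect_epigenomic_translocation(calls, WT_BD, DONOR, [GENE], sample_id="p")[0]
        assert r.verdict == "partial"

    def test_verdict_invariant_to_call_order(self):
        calls = [
            bd("p", "chr11", 500_000, 513_000),
            bd("p", "chr14", 1_000_000, 1_041_000),
        ]
        fwd = detect_epigenomic_translocation(calls, WT_BD, DONOR, [GENE], sample_id="p")
        rev = detect_epigenomic_translocation(calls[::-1], WT_BD, DONOR, [GENE], sample_id="p")
        assert fwd[0].verdict == rev[0].verdict == "partial"

    def test_missing_acceptor_gene_rejected(self):
        with pytest.raises(ValueError, match="acceptor"):
            detect_epigenomic_translocation([], WT_BD, DONOR, [], sample_id="x")

    def test_missing_wildtype_domain_rejected(self):
        with pytest.raises(ValueError, match="wild-type"):
            detect_epigenomic_translocation(
                [], [GenomicInterval("chr14", 0, 1000)], DONOR, [GENE], sample_id="x"
            )

    def test_thresholds_are_configurable(self):
        # 30% donor residue: lost under a permissive threshold, kept by default
        calls = [
            bd("m", "chr14", 1_000_000, 1_012_300),
            bd("m", "chr11", 500_000, 513_000),
        ]
        default = detect_epigenomic_translocation(calls, WT_BD, DONOR, [GENE], sample_id="m")[0]
        loose = detect_epigenomic_translocation(
            calls, WT_BD, DONOR, [GENE],
            thresholds=DetectionThresholds(donor_loss=0.40), sample_id="m",
        )[0]
        assert default.verdict == "partial"
        assert loose.verdict == "relocated"


class TestBidirectionalScan:
    NEIGHBORS = [
        GENE,
        GeneModel("adjacent", GenomicInterval("chr11", 100_000, 103_200, "+"), "+"),
        GeneModel("far", GenomicInterval("chr11", 3_000_000, 3_010_000, "+"), "+"),
    ]

    def test_both_flanking_genes_flagged_when_covered(self):
        calls = [
            bd("m", "chr11", 500_000, 513_000),
            bd("m", "chr11", 100_000, 103_200),
        ]
        table = bidirectional_effect_scan(calls, ("chr11", 488_000), self.NEIGHBORS)
        flagged = set(table[table.flagged].gene_id)
        assert flagged == {"onco", "adjacent"}
        assert "far" not in set(table.gene_id)  # outside the 500-kb flank

    def test_gene_without_gain_not_flagged(self):
        # reciprocal-style outcome: only the acceptor gene gains a domain
        calls = [bd("m", "chr11", 500_000, 513_000)]
        table = bidirectional_effect_scan(calls, ("chr11", 488_000), self.NEIGHBORS)
        assert set(table[table.flagged].gene_id) == {"onco"}

    def test_empty_neighbourhood_returns_empty_table(self):
        table = bidirectional_effect_scan([], ("chr11", 488_000), [self.NEIGHBORS[2]])
        assert table.empty
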