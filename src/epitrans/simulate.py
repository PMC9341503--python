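"""Synthetic mini-cohorts with the statistical structure the analysis assumes.

The generator emulates the inputs the pipeline consumes — chromatin-state
segmentations, histone-mark/DNase peak tracks, genome sequence, gene models,
expression tables and rearrangement events — for a cohort of healthy
B-cell-like samples and translocated malignant-like samples.  Two locus
templates are provided:

``toy``
    two 5-Mb chromosomes ("chr14L", "chr11L") at 200-bp resolution carrying a
    scaled immunoglobulin-heavy-like locus (four super-enhancers, a 41-kb
    broad domain over a D-segment-like region, a promoter), a CCND1-like
    acceptor gene with an upstream Polycomb block and a MYEOV-like neighbour,
    planted broad-domain genes with proximal super-enhancers (positive
    control for the co-occurrence analysis), narrow-promoter control genes,
    and RGYW motif clusters in materialised sequence.

``igh_printed``
    the same structure laid out at the published IGH/CCND1 coordinates
    (Eα2 106,025,200–106,056,800; Eα1 106,144,200–106,179,400;
    Eδ 106,281,800–106,289,800; Eμ 106,299,800–106,326,200; D_H broad domain
    106,346,800–106,387,800 on chromosome 14), intervals only — no sequence
    is materialised at this scale.

Healthy samples carry every template element, chunked into sub-intervals
separated by sub-1-kb gaps (so gap-merging is always exercised).  Malignant
samples are healthy samples transformed by :func:`inject_translocation`.
Noise: Gaussian boundary jitter rounded to the track resolution, Bernoulli
per-segment state flips to a low-signal state, and Bernoulli peak dropout.
Regenerating with the same spec and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .calling import (
    STATE_RULES,
    DomainCall,
    build_consensus,
    call_state_domains,
)
from .cooccurrence import (
    Anchor,
    AnchorSet,
    ProximityProfile,
    proximity_profile,
)
from .intervals import (
    GeneModel,
    GenomicInterval,
    PeakTrack,
    SegmentationTrack,
    StateSegment,
    coverage_fraction,
    subtract_intervals,
    union_intervals,
)
from .motifs import count_rgyw
from .rearrangement import (
    DetectionThresholds,
    RearrangementEvent,
    detect_epigenomic_translocation,
)

#: state a flipped (noise-corrupted) segment is relabelled to
FLIP_STATE = 1

STATES_BY_KIND = {
    "BD": (10, 11),
    "SE": (9,),
    "promoter": (11, 10),
    "polycomb": (7,),
}

SCENARIOS = ("u266_like", "z138_like", "none")


@dataclass(frozen=True)
class NoiseModel:
    """Noise applied to synthetic tracks.

    Defaults: one resolution unit of boundary jitter, 2% state flips and 2%
    peak dropout — enough to exercise robustness without overwhelming 2-kb
    elements.
    """

    boundary_jitter_sd: float = 200.0
    state_flip_rate: float = 0.02
    peak_dropout_rate: float = 0.02

    def __post_init__(self) -> None:
        for r in (self.state_flip_rate, self.peak_dropout_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")


NO_NOISE = NoiseModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    The default cohort mirrors the consensus-building setting: 15 healthy
    B-cell-like samples plus two malignant samples, one carrying a
    cut-and-paste insertion of the Eα1-like super-enhancer ~12 kb upstream of
    the CCND1-like gene ("u266_like") and one a reciprocal translocation
    juxtaposing the gene to the intact super-enhancer cluster ("z138_like").
    """

    n_healthy: int = 15
    n_malignant: int = 2
    scenarios: tuple[str, ...] = ("u266_like", "z138_like")
    template: str = "toy"
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    include_fasta: bool = True

    def __post_init__(self) -> None:
        if self.n_healthy < 1:
            raise ValueError("need at least one healthy sample")
        if self.n_malignant < 0:
            raise ValueError("n_malignant must be >= 0")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        if self.n_malignant > 0 and not self.scenarios:
            raise ValueError("scenarios required when n_malignant > 0")

    def scenario_for(self, j: int) -> str:
        return self.scenarios[j % len(self.scenarios)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


# ---------------------------------------------------------------------------
# Locus templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateElement:
    name: str
    interval: GenomicInterval
    kind: str


@dataclass(frozen=True)
class LocusTemplate:
    name: str
    chrom_sizes: Mapping[str, int]
    resolution: int
    elements: tuple[TemplateElement, ...]
    genes: tuple[GeneModel, ...]
    bd_genes: tuple[str, ...]
    control_genes: tuple[str, ...]
    donor_locus: GenomicInterval
    donor_se: str
    acceptor_gene: str
    neighbor_gene: str
    insertion_site: tuple[str, int]
    reciprocal_breakpoints: tuple[tuple[str, int], tuple[str, int]]
    motif_clusters: tuple[tuple[str, int, int], ...] = ()
    motif_region: GenomicInterval | None = None
    has_sequence: bool = False

    def element(self, name: str) -> TemplateElement:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _gene(gene_id: str, chrom: str, start: int, end: int, strand: str = "+") -> GeneModel:
    return GeneModel(gene_id=gene_id, body=GenomicInterval(chrom, start, end, strand), strand=strand)


def _build_template(
    name: str,
    chrom_a: str,
    chrom_b: str,
    size_a: int,
    size_b: int,
    igh_offset: int,
    bd_gene_start: int,
    ctrl_gene_start: int,
    ccnd1_start: int,
    myeov_start: int,
    promoter_start: int,
    breakpoint_a: int,
    breakpoint_b: int,
    motif_clusters: tuple,
    motif_region: GenomicInterval | None,
    has_sequence: bool,
) -> LocusTemplate:
    """Shared layout: the published IGH geometry shifted by ``igh_offset``."""

    def igh(lo: int, hi: int) -> GenomicInterval:
        return GenomicInterval(chrom_a, lo + igh_offset, hi + igh_offset)

    elements = [
        TemplateElement("Ealpha2", igh(106_025_200, 106_056_800), "SE"),
        TemplateElement("Ealpha1", igh(106_144_200, 106_179_400), "SE"),
        TemplateElement("Edelta", igh(106_281_800, 106_289_800), "SE"),
        TemplateElement("Emu", igh(106_299_800, 106_326_200), "SE"),
        TemplateElement("DH_BD", igh(106_346_800, 106_387_800), "BD"),
        TemplateElement(
            "igh_promoter", GenomicInterval(chrom_a, promoter_start, promoter_start + 4000), "promoter"
        ),
    ]
    genes: list[GeneModel] = []
    bd_gene_names, ctrl_gene_names = [], []
    se_gaps = (20_000, 50_000, 80_000, 30_000)
    for k in range(4):
        gstart = bd_gene_start + k * 600_000
        gid = f"bdg{k + 1}"
        genes.append(_gene(gid, chrom_a, gstart, gstart + 20_000))
        bd_gene_names.append(gid)
        elements.append(
            TemplateElement(f"{gid}_bd", GenomicInterval(chrom_a, gstart, gstart + 20_000), "BD")
        )
        se_start = gstart + 20_000 + se_gaps[k]
        elements.append(
            TemplateElement(f"{gid}_se", GenomicInterval(chrom_a, se_start, se_start + 6_000), "SE")
        )
    for k in range(4):
        gstart = ctrl_gene_start + k * 600_000
        gid = f"ctl{k + 1}"
        genes.append(_gene(gid, chrom_b, gstart, gstart + 10_000))
        ctrl_gene_names.append(gid)
        elements.append(
            TemplateElement(
                f"{gid}_promoter", GenomicInterval(chrom_b, gstart - 400, gstart + 400), "promoter"
            )
        )
    genes.append(_gene("CCND1L", chrom_b, ccnd1_start, ccnd1_start + 13_400))
    genes.append(_gene("MYEOVL", chrom_b, myeov_start, myeov_start + 3_200))
    elements.append(
        TemplateElement(
            "ccnd1_promoter", GenomicInterval(chrom_b, ccnd1_start, ccnd1_start + 1000), "promoter"
        )
    )
    elements.append(
        TemplateElement(
            "ccnd1_polycomb", GenomicInterval(chrom_b, ccnd1_start - 6000, ccnd1_start), "polycomb"
        )
    )
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return LocusTemplate(
        name=name,
        chrom_sizes={chrom_a: size_a, chrom_b: size_b},
        resolution=200,
        elements=tuple(elements),
        genes=tuple(sorted(genes, key=lambda g: (g.body.chrom, g.body.start))),
        bd_genes=tuple(bd_gene_names),
        control_genes=tuple(ctrl_gene_names),
        donor_locus=igh(106_346_800, 106_387_800),
        donor_se="Ealpha1",
        acceptor_gene="CCND1L",
        neighbor_gene="MYEOVL",
        insertion_site=(chrom_b, ccnd1_start - 12_000),
        reciprocal_breakpoints=((chrom_a, breakpoint_a), (chrom_b, breakpoint_b)),
        motif_clusters=motif_clusters,
        motif_region=motif_region,
        has_sequence=has_sequence,
    )


def toy_template() -> LocusTemplate:
    return _build_template(
        name="toy",
        chrom_a="chr14L",
        chrom_b="chr11L",
        size_a=5_000_000,
        size_b=5_000_000,
        igh_offset=-105_000_000,
        bd_gene_start=2_000_000,
        ctrl_gene_start=500_000,
        ccnd1_start=3_000_000,
        myeov_start=2_560_000,
        promoter_start=1_400_000,
        breakpoint_a=1_340_000,
        breakpoint_b=2_990_000,
        motif_clusters=(("chr14L", 950_000, 260), ("chr14L", 1_200_000, 300)),
        motif_region=GenomicInterval("chr14L", 900_000, 1_300_000),
        has_sequence=True,
    )


def igh_printed_template() -> LocusTemplate:
    return _build_template(
        name="igh_printed",
        chrom_a="chr14",
        chrom_b="chr11",
        size_a=110_000_000,
        size_b=70_000_000,
        igh_offset=0,
        bd_gene_start=100_000_000,
        ctrl_gene_start=60_000_000,
        ccnd1_start=69_455_800,
        myeov_start=69_061_600,
        promoter_start=106_400_000,
        breakpoint_a=106_330_000,
        breakpoint_b=69_440_000,
        motif_clusters=(),
        motif_region=None,
        has_sequence=False,
    )


_TEMPLATES = {"toy": toy_template, "igh_printed": igh_printed_template}


def get_template(name: str) -> LocusTemplate:
    try:
        return _TEMPLATES[name]()
    except KeyError:
        raise ValueError(f"unknown template {name!r}; expected one of {sorted(_TEMPLATES)}")


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------


def _chunk_layout(iv: GenomicInterval, rng, res: int) -> list[list[int]]:
    """Split an element into 1–3-kb chunks separated by sub-1-kb gaps,
    covering exactly [start, end)."""
    chunks: list[list[int]] = []
    pos = iv.start
    while pos < iv.end:
        clen = int(rng.integers(5, 16)) * res
        end = min(pos + clen, iv.end)
        chunks.append([pos, end])
        gap = int(rng.integers(1, 5)) * res
        pos = end + gap
    chunks[-1][1] = iv.end
    return chunks


def _simulate_track(
    template: LocusTemplate,
    sample_id: str,
    rng,
    noise: NoiseModel,
    disease_status: str = "healthy",
    cell_type: str = "B_cell_like",
) -> SegmentationTrack:
    res = template.resolution
    segments: list[StateSegment] = []
    prev_end: dict[str, int] = {}
    for elem in template.elements:
        states = STATES_BY_KIND[elem.kind]
        chrom = elem.interval.chrom
        for s, e in _chunk_layout(elem.interval, rng, res):
            state = states[int(rng.integers(0, len(states)))]
            js = int(np.clip(round(rng.normal(0, noise.boundary_jitter_sd) / res), -3, 3)) * res
            je = int(np.clip(round(rng.normal(0, noise.boundary_jitter_sd) / res), -3, 3)) * res
            u = rng.random()  # flip draw, consumed at every rate for coupling
            s2, e2 = max(0, s + js), e + je
            s2 = max(s2, prev_end.get(chrom, 0))
            if e2 <= s2:
                continue
            if u < noise.state_flip_rate:
                state = FLIP_STATE
            segments.append(StateSegment(GenomicInterval(chrom, s2, e2), state))
            prev_end[chrom] = e2
    return SegmentationTrack.from_segments(
        sample_id,
        segments,
        cell_type=cell_type,
        disease_status=disease_status,
        resolution=res,
    )


def _simulate_peaks(
    template: LocusTemplate, sample_id: str, rng, noise: NoiseModel
) -> dict[str, PeakTrack]:
    res = template.resolution
    raw: dict[str, list[GenomicInterval]] = {
        m: [] for m in ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "DNase")
    }
    for elem in template.elements:
        ivs = [
            GenomicInterval(elem.interval.chrom, s, e)
            for s, e in _chunk_layout(elem.interval, rng, res)
        ]
        if elem.kind == "BD":
            raw["H3K4me3"] += ivs
            raw["H3K27ac"] += ivs
        elif elem.kind == "SE":
            raw["H3K4me1"] += ivs
            raw["H3K27ac"] += ivs
        elif elem.kind == "promoter":
            raw["H3K4me3"] += ivs
        elif elem.kind == "polycomb":
            raw["H3K27me3"] += ivs
        if elem.kind in ("BD", "SE", "promoter"):
            raw["DNase"].append(elem.interval)
    tracks = {}
    for mark in sorted(raw):
        kept = [iv for iv in raw[mark] if rng.random() >= noise.peak_dropout_rate]
        tracks[mark] = PeakTrack(sample_id=sample_id, mark=mark, peaks=kept)
    return tracks


# ---------------------------------------------------------------------------
# Rearrangement injection
# ---------------------------------------------------------------------------


def make_event(template: LocusTemplate, scenario: str, event_id: str) -> RearrangementEvent | None:
    if scenario == "none":
        return None
    if scenario == "u266_like":
        return RearrangementEvent(
            event_id=event_id,
            event_type="cut_paste_insertion",
            donor=template.element(template.donor_se).interval,
            acceptor_site=template.insertion_site,
            orientation="forward",
        )
    if scenario == "z138_like":
        return RearrangementEvent(
            event_id=event_id,
            event_type="reciprocal_translocation",
            breakpoints=template.reciprocal_breakpoints,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def _tile(iv: GenomicInterval, states: Sequence[int], chunk: int = 2000, gap: int = 200) -> list[StateSegment]:
    """Deterministically tile a region with alternating-state chunks
    (sub-1-kb gaps, ~90% coverage)."""
    out = []
    pos, k = iv.start, 0
    while pos < iv.end:
        end = min(pos + chunk, iv.end)
        out.append(StateSegment(GenomicInterval(iv.chrom, pos, end), states[k % len(states)]))
        pos = end + gap
        k += 1
    return out


def _clear_region(segments: list[StateSegment], region: GenomicInterval) -> list[StateSegment]:
    out = []
    for seg in segments:
        for piece in subtract_intervals([seg.interval], region):
            out.append(StateSegment(piece, seg.state))
    return out


def inject_translocation(
    track: SegmentationTrack,
    event: RearrangementEvent | None,
    bd_relocation: bool = True,
    *,
    donor_bd: GenomicInterval,
    acceptor_gene: GeneModel,
    neighbor_gene: GeneModel | None = None,
    bd_states: Sequence[int] = (10, 11),
    se_state: int = 9,
    residual_fraction: float = 0.05,
    inserted_se_length: int = 6000,
) -> SegmentationTrack:
    """Transform a healthy track into its rearranged counterpart.

    Super-enhancer states move according to the event: a cut-and-paste event
    removes state-9 segments inside the donor segment and paints an equally
    long state-9 footprint landing at the acceptor site (on the gene-distal
    side, so the inserted element ends at the site); a reciprocal
    translocation leaves the super-enhancers in place (the acceptor gene is
    juxtaposed to them on the derivative); a sequence insertion activates a
    template super-enhancer of ``inserted_se_length`` at the site.

    With ``bd_relocation`` the donor broad-domain states are removed down to
    a residual fraction (< 10% of the footprint) and broad-domain states are
    written over the acceptor gene body (and the neighbour gene's body for
    cut-and-paste events, modelling the bidirectional effect of the landed
    super-enhancer).  With ``bd_relocation=False`` only the super-enhancer
    moves (negative control).
    """
    if event is None:
        return track
    segments = list(track.segments)
    if event.event_type == "cut_paste_insertion":
        donor = event.donor
        segments = [
            seg
            for seg in segments
            if not (seg.state == se_state and seg.interval.overlaps(donor))
        ] + [
            StateSegment(piece, seg.state)
            for seg in track.segments
            if seg.state == se_state and seg.interval.overlaps(donor)
            for piece in subtract_intervals([seg.interval], donor)
        ]
        chrom, p = event.acceptor_site
        landing = GenomicInterval(chrom, max(0, p - donor.length), p)
        segments = _clear_region(segments, landing)
        segments += _tile(landing, [se_state])
    elif event.event_type == "sequence_insertion":
        chrom, p = event.acceptor_site
        landing = GenomicInterval(chrom, max(0, p - inserted_se_length), p)
        segments = _clear_region(segments, landing)
        segments += _tile(landing, [se_state])
    # reciprocal translocation: SE states stay at the donor locus
    if bd_relocation:
        kept, budget = [], residual_fraction * donor_bd.length
        cum = 0.0
        new_segments = []
        for seg in segments:
            if seg.state in bd_states and seg.interval.overlaps(donor_bd):
                inside = seg.interval.overlap_length(donor_bd)
                if cum + inside <= budget:
                    cum += inside
                    new_segments.append(seg)
                else:
                    for piece in subtract_intervals([seg.interval], donor_bd):
                        new_segments.append(StateSegment(piece, seg.state))
            else:
                new_segments.append(seg)
        segments = new_segments
        targets = [acceptor_gene.body]
        if neighbor_gene is not None and event.event_type == "cut_paste_insertion":
            targets.append(neighbor_gene.body)
        for body in targets:
            body_plain = GenomicInterval(body.chrom, body.start, body.end)
            segments = _clear_region(segments, body_plain)
            segments += _tile(body_plain, list(bd_states))
    return SegmentationTrack.from_segments(
        track.sample_id,
        segments,
        cell_type=track.cell_type,
        disease_status="malignant",
        resolution=track.resolution,
    )


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _engineered_window(count: int, window: int = 2500) -> str:
    """A window containing exactly ``count`` RGYW matches: spaced AGCA blocks
    on a match-free C background."""
    if count * 4 > window:
        raise ValueError(f"target {count} unreachable in a {window}-bp window")
    seq = "AGCA" * count + "C" * (window - 4 * count)
    assert count_rgyw(seq) == count
    return seq


def generate_sequence_with_clusters(
    length: int,
    cluster_spec: Sequence[tuple[int, int]],
    seed_or_rng,
    window: int = 2500,
) -> str:
    """Uniform-random sequence with motif-cluster windows spliced in.

    Each ``(position, target_count)`` plants a ``window``-bp block containing
    exactly ``target_count`` RGYW matches (verified before emission).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    arr = _BASES[rng.integers(0, 4, size=length)]
    seq = arr.tobytes().decode()
    for pos, count in cluster_spec:
        if pos < 0 or pos + window > length:
            raise ValueError(f"cluster window at {pos} outside sequence of length {length}")
        block = _engineered_window(count, window)
        seq = seq[:pos] + block + seq[pos + window :]
    return seq


def _simulate_genome(template: LocusTemplate, rng) -> dict[str, str]:
    sequences = {}
    for chrom in sorted(template.chrom_sizes):
        clusters = [(pos, count) for c, pos, count in template.motif_clusters if c == chrom]
        sequences[chrom] = generate_sequence_with_clusters(
            template.chrom_sizes[chrom], clusters, rng
        )
    return sequences


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    spec: CohortSpec | None
    template: LocusTemplate
    tracks: list[SegmentationTrack]
    peaks: dict[str, dict[str, PeakTrack]]
    genes: tuple[GeneModel, ...]
    events: dict[str, RearrangementEvent | None]
    expression: pd.DataFrame
    fasta: dict[str, str] | None
    manifest: dict

    @property
    def healthy_tracks(self) -> list[SegmentationTrack]:
        return [t for t in self.tracks if t.disease_status == "healthy"]

    @property
    def malignant_tracks(self) -> list[SegmentationTrack]:
        return [t for t in self.tracks if t.disease_status == "malignant"]

    def track(self, sample_id: str) -> SegmentationTrack:
        for t in self.tracks:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort from a spec (deterministic in seed)."""
    template = get_template(spec.template)
    tracks: list[SegmentationTrack] = []
    peaks: dict[str, dict[str, PeakTrack]] = {}
    events: dict[str, RearrangementEvent | None] = {}
    relocated: dict[str, list[str]] = {}

    for i in range(spec.n_healthy):
        sid = f"H{i + 1:02d}"
        rng = np.random.default_rng([spec.seed, 1, i])
        tracks.append(_simulate_track(template, sid, rng, spec.noise))
        peaks[sid] = _simulate_peaks(template, sid, np.random.default_rng([spec.seed, 2, i]), spec.noise)
        events[sid] = None
        relocated[sid] = []

    acceptor = template.gene(template.acceptor_gene)
    neighbor = template.gene(template.neighbor_gene)
    for j in range(spec.n_malignant):
        sid = f"M{j + 1:02d}"
        rng = np.random.default_rng([spec.seed, 3, j])
        base = _simulate_track(template, sid, rng, spec.noise, cell_type="malignant_B_like")
        scenario = spec.scenario_for(j)
        event = make_event(template, scenario, event_id=f"{sid}_{scenario}")
        if event is None:
            track = SegmentationTrack.from_segments(
                sid,
                base.segments,
                cell_type=base.cell_type,
                disease_status="malignant",
                resolution=base.resolution,
            )
            relocated[sid] = []
        else:
            track = inject_translocation(
                base,
                event,
                bd_relocation=True,
                donor_bd=template.donor_locus,
                acceptor_gene=acceptor,
                neighbor_gene=neighbor,
            )
            relocated[sid] = [acceptor.gene_id]
            if event.event_type == "cut_paste_insertion":
                relocated[sid].append(neighbor.gene_id)
        tracks.append(track)
        pk = _simulate_peaks(template, sid, np.random.default_rng([spec.seed, 4, j]), spec.noise)
        pk = _transform_peaks(pk, event, template, acceptor, neighbor)
        peaks[sid] = pk
        events[sid] = event

    expr_rng = np.random.default_rng([spec.seed, 5])
    expression = _simulate_expression(template, [t.sample_id for t in tracks], relocated, expr_rng)

    fasta = None
    if spec.include_fasta and template.has_sequence:
        fasta = _simulate_genome(template, np.random.default_rng([spec.seed, 6]))

    manifest = {
        "seed": spec.seed,
        "template": template.name,
        "spec": spec.to_dict(),
        "spec_sha256": spec.sha256(),
        "samples": [
            {
                "sample_id": t.sample_id,
                "disease_status": t.disease_status,
                "cell_type": t.cell_type,
                "scenario": (events[t.sample_id].event_type if events[t.sample_id] else "none"),
            }
            for t in tracks
        ],
    }
    return SyntheticCohort(
        spec=spec,
        template=template,
        tracks=tracks,
        peaks=peaks,
        genes=template.genes,
        events=events,
        expression=expression,
        fasta=fasta,
        manifest=manifest,
    )


def _transform_peaks(
    pk: dict[str, PeakTrack],
    event: RearrangementEvent | None,
    template: LocusTemplate,
    acceptor: GeneModel,
    neighbor: GeneModel,
) -> dict[str, PeakTrack]:
    """Mirror the injected epigenomic changes in the mark/DNase channels."""
    if event is None:
        return pk
    donor_bd = template.donor_locus
    body = GenomicInterval(acceptor.body.chrom, acceptor.body.start, acceptor.body.end)
    out = {}
    for mark, track in pk.items():
        ivs = list(track.peaks)
        if mark in ("H3K4me3", "DNase"):
            ivs = subtract_intervals(ivs, donor_bd)
            ivs.append(body)
            if event.event_type == "cut_paste_insertion":
                ivs.append(GenomicInterval(neighbor.body.chrom, neighbor.body.start, neighbor.body.end))
        if mark in ("H3K4me1", "H3K27ac") and event.event_type == "cut_paste_insertion":
            donor = event.donor
            chrom, p = event.acceptor_site
            ivs = subtract_intervals(ivs, donor)
            ivs.append(GenomicInterval(chrom, max(0, p - donor.length), p))
        out[mark] = PeakTrack(sample_id=track.sample_id, mark=mark, peaks=ivs)
    return out


def _simulate_expression(
    template: LocusTemplate,
    samples: Sequence[str],
    relocated: Mapping[str, Sequence[str]],
    rng,
    low_log2: float = 2.0,
    high_log2: float = 6.0,
    sd_log2: float = 0.5,
) -> pd.DataFrame:
    """FPKM-like expression: log-normal regimes with >=4-fold separation
    between relocated acceptor genes and everything else."""
    gene_ids = sorted(g.gene_id for g in template.genes)
    values = {}
    for sid in samples:
        row = []
        hot = set(relocated.get(sid, []))
        for gid in gene_ids:
            loc = high_log2 if gid in hot else low_log2
            row.append(float(2.0 ** rng.normal(loc, sd_log2)))
        values[sid] = row
    return pd.DataFrame.from_dict(values, orient="index", columns=gene_ids).sort_index()


# ---------------------------------------------------------------------------
# Cohort persistence
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    outdir = Path(outdir)
    (outdir / "segmentation").mkdir(parents=True, exist_ok=True)
    for track in cohort.tracks:
        eio.write_segmentation(
            outdir / "segmentation" / f"{track.sample_id}.bed",
            track,
            header=f"sample={track.sample_id} status={track.disease_status}",
        )
    for sid in sorted(cohort.peaks):
        for mark in sorted(cohort.peaks[sid]):
            eio.write_bed(
                outdir / "peaks" / f"{sid}.{mark}.bed",
                [(iv, mark) for iv in cohort.peaks[sid][mark].peaks],
                header=f"sample={sid} mark={mark}",
            )
    eio.write_bed(
        outdir / "genes.bed",
        [(g.body, g.gene_id) for g in cohort.genes],
        header="gene models",
    )
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    ev_rows = []
    for sid in sorted(cohort.events):
        e = cohort.events[sid]
        if e is None:
            ev_rows.append({"sample_id": sid, "event_type": "none"})
            continue
        row = {
            "sample_id": sid,
            "event_id": e.event_id,
            "event_type": e.event_type,
            "orientation": e.orientation,
        }
        if e.donor is not None:
            row["donor"] = {"chrom": e.donor.chrom, "start": e.donor.start, "end": e.donor.end}
        if e.acceptor_site is not None:
            row["acceptor_site"] = {"chrom": e.acceptor_site[0], "pos": e.acceptor_site[1]}
        if e.breakpoints is not None:
            row["breakpoints"] = [
                {"chrom": c, "pos": p} for c, p in e.breakpoints
            ]
        ev_rows.append(row)
    with open(outdir / "events.yaml", "w") as fh:
        yaml.safe_dump(ev_rows, fh, sort_keys=True)
    if cohort.fasta is not None:
        eio.write_fasta(outdir / "genome.fa", cohort.fasta)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")


def _event_from_row(row: dict) -> RearrangementEvent | None:
    if row.get("event_type") == "none":
        return None
    donor = None
    if "donor" in row:
        d = row["donor"]
        donor = GenomicInterval(d["chrom"], d["start"], d["end"])
    acceptor = None
    if "acceptor_site" in row:
        acceptor = (row["acceptor_site"]["chrom"], row["acceptor_site"]["pos"])
    breakpoints = None
    if "breakpoints" in row:
        breakpoints = tuple((b["chrom"], b["pos"]) for b in row["breakpoints"])
    return RearrangementEvent(
        event_id=row["event_id"],
        event_type=row["event_type"],
        donor=donor,
        acceptor_site=acceptor,
        breakpoints=breakpoints,
        orientation=row.get("orientation", "forward"),
    )


def load_cohort(outdir) -> SyntheticCohort:
    """Load a written cohort back (template resolved from the manifest)."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    template = get_template(manifest["template"])
    status = {s["sample_id"]: s for s in manifest["samples"]}
    tracks = []
    for path in sorted((outdir / "segmentation").glob("*.bed")):
        sid = path.stem
        meta = status[sid]
        tracks.append(
            eio.read_segmentation(
                path,
                sample_id=sid,
                cell_type=meta["cell_type"],
                disease_status=meta["disease_status"],
                resolution=template.resolution,
            )
        )
    peaks: dict[str, dict[str, PeakTrack]] = {}
    for path in sorted((outdir / "peaks").glob("*.bed")):
        sid, mark = path.stem.split(".", 1)
        peaks.setdefault(sid, {})[mark] = eio.read_peaks(path, sid, mark)
    genes = tuple(eio.read_genes(outdir / "genes.bed"))
    with open(outdir / "events.yaml") as fh:
        ev_rows = yaml.safe_load(fh) or []
    events = {row["sample_id"]: _event_from_row(row) for row in ev_rows}
    expression = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    fasta = None
    fa_path = outdir / "genome.fa"
    if fa_path.exists():
        seqs = {}
        name, buf = None, []
        with open(fa_path) as fh:
            for line in fh:
                if line.startswith(">"):
                    if name is not None:
                        seqs[name] = "".join(buf)
                    name, buf = line[1:].strip(), []
                else:
                    buf.append(line.strip())
        if name is not None:
            seqs[name] = "".join(buf)
        fasta = seqs
    return SyntheticCohort(
        spec=None,
        template=template,
        tracks=tracks,
        peaks=peaks,
        genes=genes,
        events=events,
        expression=expression,
        fasta=fasta,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Evaluation helpers (planted-truth recovery, calibration generator)
# ---------------------------------------------------------------------------


def recovered(element: TemplateElement, calls: Sequence[DomainCall], min_cover: float = 0.5) -> bool:
    ivs = [c.interval for c in calls if c.element_kind == element.kind]
    return coverage_fraction(element.interval, ivs) >= min_cover


def _plantable(template: LocusTemplate) -> list[TemplateElement]:
    """Template elements large enough for their kind's genome-wide rule."""
    defaults = {"BD": "bd_genomewide", "SE": "se_genomewide",
                "promoter": "promoter", "polycomb": "polycomb"}
    out = []
    for e in template.elements:
        rule = STATE_RULES[defaults[e.kind]]
        if rule.passes_size(e.interval.length):
            out.append(e)
    return out


def evaluate_recovery(
    cohort: SyntheticCohort,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> dict:
    """Recall of planted elements in healthy samples and verdict accuracy of
    the relocation detector across all samples."""
    template = cohort.template
    plantable = _plantable(template)
    rules = {
        "BD": STATE_RULES["bd_genomewide"],
        "SE": STATE_RULES["se_genomewide"],
        "promoter": STATE_RULES["promoter"],
        "polycomb": STATE_RULES["polycomb"],
    }
    hits = {k: 0 for k in rules}
    totals = {k: 0 for k in rules}
    healthy_bd_calls: dict[str, list[DomainCall]] = {}
    for track in cohort.healthy_tracks:
        calls_by_kind = {
            kind: call_state_domains(track, rule) for kind, rule in rules.items()
        }
        healthy_bd_calls[track.sample_id] = calls_by_kind["BD"]
        for elem in plantable:
            totals[elem.kind] += 1
            if recovered(elem, calls_by_kind[elem.kind]):
                hits[elem.kind] += 1
    recall = {
        k: (hits[k] / totals[k] if totals[k] else float("nan")) for k in rules
    }
    recall["overall"] = (
        sum(hits.values()) / sum(totals.values()) if sum(totals.values()) else float("nan")
    )

    wt_consensus = build_consensus(
        healthy_bd_calls, "BD", min_support=0.5, rule=STATE_RULES["bd_locus"]
    )
    acceptor = template.gene(template.acceptor_gene)
    verdicts: dict[str, str] = {}
    expected: dict[str, str] = {}
    for track in cohort.tracks:
        calls = call_state_domains(track, rules["BD"])
        reports = detect_epigenomic_translocation(
            calls,
            wt_consensus,
            template.donor_locus,
            [acceptor],
            thresholds=thresholds,
            sample_id=track.sample_id,
        )
        verdicts[track.sample_id] = reports[0].verdict
        event = cohort.events.get(track.sample_id)
        expected[track.sample_id] = "not_relocated" if event is None else "relocated"
    correct = sum(verdicts[s] == expected[s] for s in verdicts)
    false_positives = sum(
        1
        for s in verdicts
        if expected[s] == "not_relocated" and verdicts[s] != "not_relocated"
    )
    return {
        "recall": recall,
        "verdicts": verdicts,
        "expected": expected,
        "verdict_accuracy": correct / len(verdicts),
        "false_positive_verdicts": false_positives,
    }


def simulate_proximity_profiles(
    n_anchors: int = 60,
    n_ses: int = 15,
    chrom_length: int = 10_000_000,
    enrichment: float = 0.0,
    planted_max_gap: int = 80_000,
    se_length: int = 6_000,
    anchor_length: int = 1_000,
    rng=None,
    seed: int | None = None,
) -> tuple[ProximityProfile, ProximityProfile]:
    """Anchor/super-enhancer placement generator for test calibration.

    Mirroring the cohort template geometry, broad-domain anchors and control
    anchors occupy two equally sized chromosomes with identical background
    super-enhancer density, and both anchor sets are drawn uniformly with
    matched lengths — under ``enrichment=0`` the two arms are exchangeable,
    so the null hypothesis of the headline proximity test holds exactly.
    With ``enrichment > 0`` that fraction of broad-domain anchors receives a
    super-enhancer planted within ``planted_max_gap``; the control arm keeps
    the background density.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    def _uniform_anchors(kind: str, chrom: str) -> AnchorSet:
        starts = rng.integers(0, chrom_length - anchor_length, size=n_anchors)
        return AnchorSet(
            kind=kind,
            anchors=[Anchor(GenomicInterval(chrom, int(s), int(s) + anchor_length)) for s in starts],
        )

    bd_anchors = _uniform_anchors("broad_domain", "chrA")
    ctrl_anchors = _uniform_anchors("control_promoter", "chrB")
    ses = []
    for chrom in ("chrA", "chrB"):
        se_starts = rng.integers(0, chrom_length - se_length, size=n_ses)
        ses += [GenomicInterval(chrom, int(s), int(s) + se_length) for s in se_starts]
    for a in bd_anchors.anchors:
        if rng.random() < enrichment:
            gap = int(rng.integers(0, planted_max_gap))
            start = min(a.interval.end + gap, chrom_length - se_length)
            ses.append(GenomicInterval("chrA", start, start + se_length))
    return (
        proximity_profile(bd_anchors, ses),
        proximity_profile(ctrl_anchors, ses),
    )
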