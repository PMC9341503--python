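# Methods

## Scope and model

`epitrans` re-implements, as a reusable and tested pipeline, a chromatin-state
analysis of super-enhancer hijacking in haematological malignancies. The
underlying biological model is *epigenomic translocation*: in healthy B cells
an H3K4me3 broad domain (BD) accompanies the immunoglobulin heavy-chain (IGH)
super-enhancers at their wild-type locus; when a rearrangement juxtaposes an
IGH super-enhancer with a proto-oncogene such as *CCND1*, the broad domain
disappears from the donor locus and a cancer-specific broad domain appears
over the oncogene body, together with increased accessibility and expression.

The pipeline has five analysis stages plus a generator:

1. **Element calling** (`calling`). Chromatin-state segmentations (ChromHMM
   style, 200-bp resolution) are filtered to the state subset that defines
   each element — state 9 (active canonical enhancer) for super-enhancers,
   state 7 (Polycomb-repressed) for Polycomb blocks, states 10+11 (active
   non-canonical H3K4me3 enhancer + active promoter) for promoters and broad
   domains. Runs are merged, skipping gaps strictly below 1 kb, and kept if
   they exceed the element's size threshold. A parallel mark-based caller
   builds broad domains from merged H3K4me3 peaks and super-enhancers from
   the base-level intersection of merged H3K4me1 and H3K27ac footprints (the
   two marks jointly define the element).
2. **Consensus** (`calling.build_consensus`). Per-sample calls are reduced to
   a per-base support partition; bases supported by at least
   `ceil(min_support · n)` samples are merged with the same gap rule and
   re-filtered by size. Majority support (`min_support = 0.5`) is the
   default: strict intersection would erase developmentally dynamic elements
   (the Eμ enhancer shrinks after the germinal-centre stage), while union
   would inflate boundaries from single noisy samples.
3. **Proximity analysis** (`cooccurrence`). Anchors are either consensus
   broad domains or 1-kb control promoter windows centred on the TSS of
   genes with a narrow H3K4me3 peak (genes carrying a broad domain at any of
   their TSSs are excluded). Super-enhancers overlapping a broad domain or a
   broad-domain-bearing gene body are excluded. Each anchor's nearest
   same-chromosome super-enhancer edge distance is binned in half-open
   100-kb bins up to 5 Mb. The headline statistic is the 2×2 contrast
   "within 100 kb yes/no × anchor kind", tested with Fisher's exact test
   (two-sided); per-bin contrasts are Benjamini–Hochberg corrected. A
   broad domain is cell-type exclusive iff every other cell type's
   active-state (9/10/11) coverage of it is < 10%.
4. **Motif scanning** (`motifs`). AID hotspot motifs (RGYW; R=A/G, Y=C/T,
   W=A/T) are counted as overlapping 4-mers in 2.5-kb windows tiled across a
   region; windows with strictly more than 200 matches qualify and adjacent
   qualifying windows merge into clusters. Under uniform bases the expected
   count is 2497/32 ≈ 78 per window, so random background essentially never
   qualifies.
5. **Rearrangement modelling and detection** (`rearrangement`).
   Rearrangements are piecewise injective coordinate maps onto derivative
   chromosomes (cut-and-paste insertion, reciprocal translocation, and
   sub-resolution sequence insertions modelled as in-place activation).
   The detector computes `donor_bd_coverage` — the fraction of the
   wild-type consensus broad-domain footprint still covered by a sample's
   broad-domain calls — and `acceptor_body_bd_coverage` over each candidate
   oncogene body. Verdict: *relocated* iff donor coverage < 0.10 **and**
   acceptor coverage ≥ 0.50; *partial* if gained without loss; otherwise
   *not_relocated*. A bidirectional scan reports gene-body coverage for all
   genes within 500 kb of an insertion site, since a landed super-enhancer
   can seed broad domains on both sides.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| merge gap | < 1000 | bp | strict gap-skipping rule used for all element merging |
| BD size, genome-wide | > 2000 | bp | broad domains exceed typical 1–2-kb promoter peaks |
| BD size, locus scan | ≥ 15000 | bp | minimum size for targeted locus scans (inclusive) |
| SE size, genome-wide | > 5000 | bp | joint H3K4me1/H3K27ac footprint |
| SE / promoter size, locus | > 2500 | bp | locus-restricted calls |
| consensus support | 0.5 | fraction | majority; see above |
| proximity bins | 100 000 × 50 | bp | distances analysed up to 5 Mb |
| control promoter width | 1000 | bp | TSS-centred window, [TSS−500, TSS+500) |
| exclusivity threshold | < 0.10 | fraction | low active-background coverage |
| significance level | 0.05 | — | two-sided |
| motif window / threshold | 2500 / > 200 | bp / count | tiled windows (step = window) |
| donor loss threshold | < 0.10 | fraction | mirrors the 10% background criterion |
| acceptor gain threshold | ≥ 0.50 | fraction | "most of the gene body" |
| neighbour flank | 500 000 | bp | bidirectional-effect search radius |

All thresholds are strict (">") except the 15-kb locus broad-domain minimum
and the acceptor gain, which are inclusive. Where a published description is
ambiguous the package fixes one deterministic reading: coordinates are
0-based end-exclusive (so printed lengths equal `end − start` exactly, e.g.
the 41-kb broad domain), distance bins are half-open, the motif scan tiles
non-overlapping windows on the forward strand by default (a both-strand mode
adds the reverse-complement WRCY pattern), and annotation ties break toward
the template element with the nearer start.

## Synthetic data

The generator emulates the cohort structure the analysis assumes, at desk
scale. The `toy` template uses two 5-Mb chromosomes — large enough to
exercise the 5-Mb binning edge cases — carrying the published IGH geometry
shifted to small coordinates; `igh_printed` lays the same structure out at
the published GRCh37 coordinates (intervals only; no 110-Mb sequence is
materialised). Healthy samples tile every template element with 1–3-kb
chunks separated by sub-1-kb gaps, so the gap-merging rule is always
exercised and, at zero noise, every element is reconstructed exactly.
Malignant samples are healthy samples transformed by `inject_translocation`:
the donor super-enhancer's state-9 segments move to the insertion site (for
cut-and-paste; reciprocal events leave them in place), donor broad-domain
states are removed down to a residual below 10% of the footprint (emulating
the small residual signal attributable to the remaining locus enhancers),
and broad-domain states are tiled over ≥ 90% of the acceptor (and, for
cut-and-paste, neighbour) gene body. The inserted super-enhancer footprint
is painted on the gene-distal side of the insertion point so it never
collides with the gene body it activates.

Noise defaults: boundary jitter SD of one resolution unit (200 bp), 2%
per-segment state flips to a low-signal state, 2% peak dropout. Flip draws
are consumed at every rate from a layout-independent stream, so recall is
pathwise non-increasing in the flip rate — the property asserted over a
{0, 0.05, 0.1, 0.2} × 20-seed grid. Expression is log-normal with log2
means 2 (baseline) and 6 (relocated acceptor genes), i.e. ≥ 4-fold
separation by construction.

The calibration generator (`simulate_proximity_profiles`) places
broad-domain and control anchors on two equally sized chromosomes with
identical background super-enhancer density and matched anchor lengths, so
under zero enrichment the two arms are exchangeable and the headline test's
null holds exactly; enrichment plants super-enhancers within 80 kb of a
fraction of broad-domain anchors only. Anchor lengths are matched
deliberately: with unmatched lengths the edge-distance distributions differ
under the null and the test would conflate anchor size with proximity.

What the generator does **not** emulate: read-level signal and peak-calling
noise, assembly gaps and repeats, copy-number changes, inter-sample
covariance of boundaries, or realistic genome-wide element densities.
Passing tests therefore demonstrate correctness of the calling, consensus,
mapping and testing logic under the stated noise model — not performance on
real ChIP-seq data.

## Numerical choices and degenerate inputs

* Interval sorting is by (chromosome lexical, start, end) everywhere;
  all stages are deterministic given a seed.
* `intersect_support` conserves base×support mass exactly (checked against
  per-base oracles); adjacent runs of equal support are coalesced into
  maximal runs.
* Cross-chromosome distances are `+inf` sentinels, not errors, so
  nearest-feature searches are total; anchors on super-enhancer-free
  chromosomes land in the beyond-5-Mb tail.
* Degenerate 2×2 tables (a zero margin) report p = 1.0 with a warning;
  empty anchor sets are an error.
* Fisher's exact test is delegated to `scipy.stats.fisher_exact` and checked
  in the test suite against exhaustive enumeration over all tables with the
  observed margins (≤ 60).
* Derivative maps are validated as bijections over all mapped bases on toy
  chromosomes; interval mapping splits queries at map boundaries and
  conserves mapped length.

## Known limitations

* Consensus support semantics across cohorts ("intersected and merged") is
  under-determined in the source description; majority support is one
  defensible reading and is configurable.
* The detector's verdict is a two-threshold rule on coverages; it does not
  model allele-specific coexistence of H3K4me3 and H3K27me3 domains
  (observed over *MYC*/*FGFR3* in some samples).
* Rank-based super-enhancer calling from signal intensity (ROSE-style) and
  inflection-point broad-domain selection are intentionally out of scope;
  the callers here operate on segmentations and peak sets, which are inputs.
* Breakpoint discovery, alignment, peak calling, expression quantification
  and genome-browser figure replication are inputs or non-goals, not part of
  the package.
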