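# Methods

This note records the models, conventions and numerical choices behind
`trivasc`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not
establish about real data.

## Coordinate and data conventions

All coordinates are micrometres in a right-handed frame with z
increasing from the superficial (vitreal) side toward the deep (scleral)
side, matching confocal stack acquisition; z = 0 is the innermost traced
point. Tracing tools disagree on native units and z direction, so the
SWC reader takes an explicit `unit_scale` (µm per coordinate unit) and
callers are responsible for flipping z if their stack was acquired
scleral-first. Files are comma-delimited UTF-8 with decimal points.

A *path* is one exported centerline; the tracing convention assumed
throughout is that each vessel segment — the stretch between two branch
points or endpoints — was traced as its own path. The SWC reader
enforces the same convention on import by splitting at every structure
point of degree ≠ 2.

## Network assembly

Path endpoints within `merge_tol_um` of one another are fused into a
single node by single-linkage clustering (union–find over all endpoint
pairs within tolerance); the node sits at the centroid of its members.
The default tolerance is **1.0 µm** — below capillary diameter, so
distinct vessels are never fused, but generous enough for manual traces
of a shared junction that rarely coincide exactly. Interior path points
are never fused: mid-course crossings of independently traced vessels
are (correctly) not junctions.

Tortuosity is arclength / chord per segment. A closed or nearly closed
segment has no meaningful ratio; segments with chord ≤ 1 µm are flagged
undefined, excluded from layer means, and logged to the network QC list
rather than capped — capping would bias layer means by an arbitrary
ceiling, exclusion is conservative and auditable.

## Depth partition

The five compartments S, SI, I, ID, D are contiguous z intervals
covering the traced range. In explicit mode the caller supplies the four
interior cuts. In automatic mode the arclength-weighted kernel density
of depth is estimated (Gaussian KDE, **3 µm** bandwidth — narrower than
any plexus, wider than trace jitter), the three most prominent modes at
least 2 × slab half-width apart become the plexus centers, and slabs of
half-width `slab_halfwidth_um` (**10 µm**, roughly half a plexus
thickness) around them define the S/I/D membership regions; the gaps
between consecutive slabs are SI and ID, and S/D extend to the stack
extremes. The evaluation grid is padded by 4 bandwidths so modes at the
stack faces still register as peaks. Anything other than exactly three
well-separated modes raises an error directing the user to explicit
cuts — guessing a partition from a degenerate profile would silently
corrupt every downstream metric.

Each segment is assigned the compartment holding the largest share of
its arclength, computed by apportioning every polyline leg according to
its z-extent overlap with each compartment. Exact ties go to the
shallower compartment (a fixed, documented bias beats a
platform-dependent one). This majority rule is robust to boundary
jitter and covers both readings of what a "gap layer" vessel is — one
lying between plexuses, or one connecting them.

## Pericytes

Each soma snaps to the layer of the segment owning the nearest polyline
vertex within `snap_tol_um` (**10 µm**, about one soma diameter);
distance ties resolve toward the shallower layer, mirroring the segment
rule. A soma with no vessel within tolerance falls back to the
compartment of its own depth, and is rejected with a QC entry only if it
also lies outside the partitioned range. Coverage is layer arclength
divided by layer soma count — the mean micrometres of vessel per
pericyte — and is reported missing rather than zero or infinite when a
layer has no somata.

Snapping to polyline *vertices* rather than interpolated points is a
deliberate simplification: traces are densely sampled (micron-scale
steps), so the vertex approximation errs by less than the soma radius.

## Axial classification

Candidate axial segments carry at least `interior_frac` (**50%**) of
their arclength inside the SI/ID gaps. Candidates sharing a node whose
depth falls outside every plexus slab are chained; a node inside a slab
terminates the chain (the vessel has "arrived" at a plexus). A chain's
contact set is the set of slabs containing any of its polyline vertices;
{S,I} → SI-connecting, {I,D} → ID-connecting, {S,I,D} → SID,
{S,D} → SD, anything else is left unclassified and counted for QC.
Independently, every branch node of degree ≥ 3 with depth inside a gap
increments inter-plexus branching — reported alongside, not subtracted
from, the four connection classes.

Contact is decided by sampled vertices, not by the continuous curve: a
vessel that dives from superficial to deep without a sampled point in
the intermediate slab is an SD bridge. This matches how a human
classifier reads a trace and is what makes the SD class non-empty at
all — any continuous curve from S to D crosses the I slab's z range.

Two properties bound what this heuristic guarantees. Midpoint
subdivision of a single-gap chain (SI, ID, or a gap bifurcation) changes
no counts: a new collinear degree-2 node in a gap neither terminates a
chain nor adds contact. But the ≥ 50% candidate rule is *not* invariant
under arbitrary subdivision of multi-gap chains: splitting an SID chain
leaves one half that absorbs the full 20 µm intermediate-slab crossing
and drops below majority-gap, dissolving the chain. The classification
is therefore defined on traces that follow the one-path-per-segment
convention, where connectors arrive whole.

## Group statistics

*Aggregation.* Z-stacks from the same retina in the same eccentricity
band are averaged first; whole-animal values are the mean of those band
means. The two-stage mean, not the pooled mean, is the estimator — a
retina imaged five times in one band must not count five times.

*Welch's t.* t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite
df; the summary-statistics route is the primary entry point (printed
tables are sufficient inputs) and the raw route simply summarises and
delegates, so the two agree exactly by construction. Zero variance in
both groups is rejected (df undefined).

*Two-way ANOVA.* Type III sums of squares with sum-to-zero contrasts —
the convention of the commercial software whose analyses this package
mirrors, and the only defensible choice for unbalanced glycemia × layer
designs. Raw mode fits via OLS (statsmodels); summary mode reconstructs
SS_within = Σ(nᵢⱼ−1)sᵢⱼ² and obtains each effect's SS as the increase in
weighted residual SS of the cell-mean regression when that effect's
contrast columns are dropped from the otherwise-full model. When the
summaries come from the raw data the two modes agree to floating
precision. Empty cells are errors; nothing is imputed. Cells with zero
SD are rejected in summary mode.

*Tukey–Kramer.* q = |mᵢ − mⱼ| / √(MS_within/2 · (1/nᵢ + 1/nⱼ)) with p
from the studentized range, k = all cells of the fitted family, df =
error df. For two balanced cells this collapses to the pooled-variance
t-test (q = t√2), which is the cheap correctness check.

*Runs test.* Residual signs (ordered by x, zeros dropped) are reduced to
a run count. Exact enumeration of the conditional runs distribution is
used for n ≤ 20; above that a continuity-corrected normal approximation.
The default p is two-sided (twice the smaller tail, capped at 1);
`alternative="too_few"` gives the one-tailed clustering p that
curve-fitting software reports when checking linearity. The
approximation is accurate to ±0.03 per tail once each sign occurs ≥ 6
times (≥ 7 for the doubled two-sided p); with heavy sign imbalance it is
known to fail, which is why exact enumeration is the small-n default
rather than an option.

*Severity.* An animal's glycemic exposure is summarised as lifetime mean
BG and the number of weeks strictly above 400 mg/dL (the hyperglycemia
threshold for this model); a reading of exactly 400 does not count.

Out of scope by design: repeated-measures/mixed-effects ANOVA with
sphericity correction and three-way ANOVAs (they require the matched
longitudinal raw data); eccentricity analyses can be run as plain
two-way ANOVAs but then ignore the within-retina matching and should be
labelled as approximations. No multiple-testing correction is applied
across metrics, matching the analysis convention the package mirrors.

## Synthetic generator

The generator emulates the study conditions end to end: 300 × 300 µm
ROIs over a 95 µm stack; plexus planes at 5 / 47.5 / 90 µm; per-plexus
density targets ≈ 15.8 / 21.2 / 30.7 mm/mm² with segment lengths ≈ 63 /
55 / 50 µm and tortuosity targets 1.11 / 1.19 / 1.17; pericyte coverage
targets per compartment (106–230 µm/pericyte); axial connector counts
4 SI / 7 ID / 6 SID / 1 SD / 1 branch point per field (≈ 44–78 per
mm²); cohorts of 13 euglycemic vs 14 hyperglycemic animals aged 7–61
weeks across four eccentricity bands; weekly blood glucose N(152.9,
10.0) mg/dL for euglycemic animals and, from onset at week 4, N(491.6,
62.58) capped at the 600 mg/dL meter ceiling for hyperglycemic ones.

Each plexus is a jittered square lattice (node jitter 4 µm) whose edges
are consumed in random order until the target total length is best
approximated — the residual mismatch is at most half an edge, a few
percent. Every edge becomes a sinusoidally displaced polyline (25
points, one full period) whose amplitude is solved by root-finding so
the *discretized* arclength/chord ratio equals the tortuosity target
exactly; the ledger then records exactly what the pipeline should
measure. Connectors are placed at anchor sites kept ≥ 25 µm apart and
≥ 3 µm from lattice nodes so endpoint fusion can never accidentally
merge them; their vertex layouts guarantee the intended contact sets
(the SD connector's sampled vertices skip the intermediate slab by
construction). Pericytes sit exactly on interior polyline vertices of
their layer, spaced to hit the coverage target after rounding.

The ground-truth ledger is filled during construction with plain inline
summations — including an independent reimplementation of the
majority-layer rule — and never by calling the analysis modules, so it
can serve as an oracle for parameter-recovery tests.

What passing recovery tests shows: the pipeline measures what was built,
exactly, including layer assignment, density bookkeeping, pericyte
snapping and axial classification. What it does not show: robustness to
the features real traces have and the generator lacks — z jitter within
a plexus (a config knob, default 0), curved or incomplete vessels,
tracing errors, unequal ROI coverage, somata displaced off the vessel
wall, or class-ambiguous connectors. Those need real annotated data.

## Registration

Frame alignment is zero-normalized cross-correlation of each frame
against a template patch over all valid integer offsets
(`skimage.feature.match_template`); the peak gives the shift, frames
with peak NCC below `min_corr` (**0.5**) are dropped and logged, and the
matched patches of the kept frames are averaged into a template-sized
image. Registration is integer-pixel by design — the method is template
matching, nothing finer — and NCC's invariance to positive affine
intensity changes is what makes it robust to illumination drift. The
manual contrast adjustment of an interactive workflow is replaced by a
deterministic percentile stretch (1st/99th by default, mapped linearly
to [0, 1] and clipped). The axial step of a defocus series is region
thickness / number of steps (95 µm in 13 steps ≈ 7.31 µm). The manual
template choice and qualitative frame-quality judgement of the original
workflow are inherently subjective; the explicit threshold here is a
reproducible stand-in, not a reconstruction.

## Numerical details

- Tie tolerance in layer assignment: 1e-9 relative to total arclength.
- Candidate threshold comparison uses a 1e-12 relative slack so a
  segment with exactly half its length in the gaps is a candidate.
- The Welch, F, studentized-range and normal p-values come from scipy's
  distribution functions; the runs-test pmf is evaluated in exact
  integer arithmetic before the final division.
- Generator determinism: one `numpy.random.Generator` drives an ROI;
  cohort generation consumes a single stream sequentially, so a fixed
  seed reproduces byte-identical exports on a given platform (floating
  point differences across BLAS builds may perturb the last digits of
  coordinates, not any count).
- Problem sizes in the validation suite — 500 oracle networks, one ROI
  per animal in the recovery cohort, 10⁴ null simulations — were chosen
  as the smallest sizes at which the checked quantities are stable to
  well within their tolerances.

## Known limitations

- Mid-path intersections are never fused into junctions; only traced
  endpoints define nodes. Networks traced with long multi-segment paths
  must be re-split (the SWC reader does this automatically).
- Nominal field area (0.09 mm²) is the default normaliser; vessels
  crossing the field border are counted in full as traced. Effective
  traced area can be passed explicitly when that convention is wanted.
- The axial candidate rule is a heuristic with a documented
  non-invariance under subdivision of multi-gap chains (above).
- The runs-test normal approximation degrades under heavy sign
  imbalance; exact enumeration covers n ≤ 20 but large-n, imbalanced
  residual sets get the approximation with no exact fallback.
- Tortuosity is the arc/chord ratio only; no curvature-integral or
  inflection-count variants, and no diameter, flow or perfusion
  estimation.
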