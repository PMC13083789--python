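# Methods

## Scope and data model

`isletsort` operates on event-level flow-cytometry data: one row per cell,
one column per channel, linear-scale fluorescence intensities (arbitrary
units, strictly positive).  The `EventTable` carries optional ground-truth
class labels — available by construction for simulated events, or supplied
externally when an orthogonal staining panel classified real events — a
stage-6 day, and a stable integer `event_id` assigned at creation.  Event
identity survives gating, which makes pre/post subset checks and
enrichment accounting exact rather than approximate.

Seven mutually exclusive classes partition an SC-islet preparation:
`beta` (INS+NKX6.1+), `alpha_poly` (GCG+ alpha plus GCG+INS+ polyhormonal
cells lacking NKX6.1, treated as one off-target class), `delta` (SST+),
`ec_like` (serotonin+ enterochromaffin-like), `ductal` (CFTR/SOX9+),
`progenitor` (NKX6.1+NEUROG3+), and `other`.

## Synthetic SC-islet generator

Each event draws a class from a multinomial and then, independently per
channel, a log-normal intensity: `log10 I ~ Normal(location + drift(day),
scale)`.  Flow intensities are positive and right-skewed and are routinely
displayed on log axes, which makes the log-normal the natural minimal
model; all parameters live on the log10 scale.

Default mixture weights: beta 0.25, alpha/polyhormonal 0.25, delta 0.05,
EC-like 0.05, ductal 0.10, progenitor 0.15, other 0.15.  The beta weight
sits mid-way in the 20–30% band that current differentiation protocols
typically yield; the remaining weights are calibration choices that
qualitatively match pre-sort composition panels (alpha/polyhormonal
comparable to beta, minor delta/EC fractions, ductal-like cells present)
and are not measured values.

Channel calibration (log10 location / scale):

| channel | high classes | high loc | low loc | scale |
|---|---|---|---|---|
| CD133 | beta (day 7), ductal | 2.60 | 2.15 (alpha/delta/EC), 1.90 (prog/other) | 0.25 |
| CD49a | beta, alpha_poly, delta, ec_like | 2.60 | 1.00 | 0.15 |
| identity markers (INS, NKX6.1, GCG, NEUROG3, SST, SEROTONIN, CFTR) | owning class(es) | 2.4–2.8 | 1.00 | 0.20 |

No public dataset quantifies the alpha-beta CD133 effect size, so the
day-7 separation (0.45 log10 units ≈ 1.8 within-class SDs) is a documented
design choice: large enough that a top-20% CD133 gate on the endocrine
subset is beta-dominated, small enough that the populations genuinely
overlap and the sort is imperfect — closed-form prediction puts dual-gate
purity near 93%, CD133-only near 62%, against the 25% unsorted baseline.

**Stage-6 drift.** Newly formed beta cells polarize progressively, so
their CD133 signal rises across stage 6 while the alpha signal does not.
The default drift shifts the beta CD133 location linearly from −0.60
log10 units at day 0 (beta slightly *below* the alpha location, full
overlap) to 0 at day 7.  The implied noise-free RPI sequence over days
0–7 is 1, 1, 1, 1, 1, 0.85, 0.55, 0.30: pinned at the overlap endpoint
early, then falling by steps that dominate quantile sampling noise at the
default 5,000 events/day (quantile standard errors ≈ 0.015 log10 units,
per-day location steps 0.086).  CD133 decline during later in-vitro
maturation is outside the stage-6 window and not modeled.

**Determinism.** `simulate_events` is bit-reproducible given
`(seed, n, day)`; its stream is seeded from `SeedSequence([seed, day])`.
Time courses derive a child seed per day from
`SeedSequence([master, day])`, so adding or removing a day never perturbs
the other days' draws.

**What the generator does not emulate** — doublets, debris, dead cells,
spectral spillover/compensation, instrument noise floors, acquisition-time
drift, and any correlation between channels within a class.  Passing tests
therefore demonstrate the correctness of the *analysis* under the stated
statistical model, not robustness to instrument artifacts; on real data
the positive-split heuristic in particular assumes a genuinely bimodal,
well-separated marker.

## Population summaries and the relative position index

Quantiles project-wide use linear interpolation between order statistics
(the p-quantile of sorted x₁…x_n at rank 1 + p(n−1); numpy's default).
The same convention feeds the alpha 0.95 percentile and the beta
interquartile range.

The RPI rescales the alpha/polyhormonal upper boundary (P95) linearly
across the beta IQR and clamps to [0, 1]:

    RPI = clamp((P95_α − Q1_β) / (Q3_β − Q1_β), 0, 1)

so RPI = 0 exactly when P95_α ≤ Q1_β (separation) and RPI = 1 exactly
when P95_α ≥ Q3_β (overlap).  A degenerate beta IQR (Q3 = Q1) collapses
to those endpoint semantics.  The index is computed on linear intensities;
interior values (not the endpoints) depend on the scale, so the convention
is fixed and recorded here.  The functional form is the committed
interpretation of a graphically specified procedure: it is the unique
linear statistic built from exactly P95 and the IQR that has range [0, 1]
with 0 meaning separation and 1 meaning overlap.

Sort-window selection offers `argmin` (earliest day attaining the minimal
index; ties break to the earlier day, i.e. shorter culture) and
`first_below` (earliest day under a threshold; no qualifying day returns
`None`, a no-window outcome distinct from an error).  Classes come from
ground-truth labels; restricting to the NEUROG3+ endocrine subset before
computing the index is an optional label filter, not a separate algorithm.

## Gate semantics

* `top_fraction` — rank-based: exactly ⌈fraction·n⌉ events survive, ties
  broken by descending intensity then original event order.  A cutoff-based
  gate would inflate the count at tied intensities; rank selection keeps
  the "top 20%" literal.  `top_fraction_threshold` reports the equivalent
  dial-in cutoff (the k-th largest intensity).
* `threshold` — keep `I ≥ cutoff` (`above`) or `I < cutoff` (`below`);
  the two directions partition the table.
* `positive_split` — for bimodal markers such as CD49a: sort log10
  intensities, split at the largest consecutive gap, take each side's mean
  log10 intensity as its cluster center, and threshold at the midpoint of
  the centers (events at or above it are positive).  Deterministic and
  assumption-light; ties in the gap break to the lowest gap, and a manual
  `cutoff` override is available.  Fewer than two distinct values ⇒ every
  event counts as positive.
* `apply_sequential` — gates compose left to right with daughter-gate
  semantics: each `top_fraction` is relative to the survivors at that
  stage, as on a sorter.  An empty intermediate table short-circuits to an
  empty result.  The dual beta-cell sort is
  `[positive_split(CD49a), top_fraction(CD133, 0.20)]`; gate order is
  configurable and order sensitivity is real (conditional fractions), so
  the CD49a-first default is recorded here.  Whether the top-20% should be
  relative to all events or to a pre-gated subset is likewise a
  configuration choice; the single-marker gate defaults to all events.
* Scatter-based singlet/debris gating is out of scope — the simulator
  emits singlets only.

Composition, purity, yield and enrichment are counted on ground-truth
labels.  Empty tables have *undefined* (not zero) compositions, and a
class absent pre-sort has an undefined (not infinite) enrichment fold;
both are surfaced as `None` so downstream code must handle them
explicitly.  JSON/TSV reports serialize fractions in [0, 1].

## Replicate statistics

Sorting experiments compare a handful of biological replicates (n = 3–4
independent differentiations), where asymptotic p-values are unreliable.
Both tests are two-sided and exact at desk scale:

* **Wilcoxon matched-pairs signed-rank** — zero differences dropped (the
  common convention; the choice matters only for degenerate data), ties
  mid-ranked.  Exact for ≤ 25 nonzero pairs via the classical
  shift-convolution DP over doubled (hence integral) ranks — equivalent to
  enumerating all 2ⁿ sign assignments; tie-corrected normal approximation
  (no continuity correction) above.  All-zero differences yield a flagged
  degenerate result with p = 1.
* **Mann–Whitney U** (statistic U₁) — exact for n₁+n₂ ≤ 16 tie-free
  samples via the rank-sum subset-count DP; otherwise a tie-corrected
  normal approximation with continuity correction.

Exact two-sided p-values are twice the smaller tail probability, capped at
1, so they are conservative (attained size ≤ nominal α).  Stars follow the
conventional map: `****` p<0.0001, `***` p<0.001, `**` p<0.01, `*` p<0.05,
else `ns`.

## File formats

CSV is the canonical interchange: header
`event_id,label,timepoint,<channels…>`, floats at 9 significant digits,
deterministic byte-identical output.  FCS support is a read-only subset of
FCS 3.0/3.1: uncompressed list-mode data, float/double or plain integer
types, little- or big-endian; channel names prefer `$PnS` over `$PnN`;
labels are never present in FCS.  FCS 2.0, ASCII or bit-packed data, and
writing FCS are out of scope.  Because the pipeline requires strictly
positive intensities, FCS files containing zero or negative (compensated)
values are rejected rather than clipped.

## Problem sizes

Default analysis sizes — 10,000 events per preparation, 5,000 events per
time-course day, 20 replicate seeds for purity summaries, 2,000 replicates
for test-level checks — were chosen so every distributional check has
3-sigma headroom against its expected sampling noise while the full suite
stays interactive.

## Known limitations

* Channels are conditionally independent given class; no spillover,
  compensation or within-class correlation structure.
* The positive-split heuristic assumes clear bimodality; on smeared real
  data a manual cutoff should be supplied.
* The RPI's interior values depend on the (linear) intensity scale
  convention; comparisons across instruments require a shared scale.
* Ground-truth labels stand in for the hormone/TF staining panels used to
  score real sorts; label noise is not modeled.
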