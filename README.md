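# isletsort

Simulation and analysis of marker-based cell sorting for stem-cell-derived
islets (SC-islets).

Differentiating human pluripotent stem cells into pancreatic islets
typically yields only 20–30% insulin-producing beta cells, alongside
glucagon-positive alpha/polyhormonal cells, delta and enterochromaffin-like
cells, ductal-like cells and residual progenitors.  A practical enrichment
strategy sorts on two commercially available surface markers: **CD133**
(PROM1), which is high on newly formed (polarized) beta cells and on
ductal-like cells but low on alpha/polyhormonal cells, and **CD49a**
(ITGA1), a pan-endocrine marker absent from ductal epithelium.  Gating
CD49a-positive cells first and then keeping the brightest 20% on CD133
enriches beta cells past 70% purity while excluding both alpha cells and
ductal contaminants.

`isletsort` implements the quantitative machinery behind that strategy as
a tested pipeline on event-level cytometry data:

* **`isletsort.simulate`** — a synthetic SC-islet event generator:
  seven-class mixtures with per-class log-normal channel intensities and a
  stage-6 time drift, so the whole pipeline is testable without any
  instrument data.
* **`isletsort.population`** — quantile population summaries and the
  **relative position index (RPI)**, the separation statistic that decides
  *when* to sort.  With `P95_α` the alpha/polyhormonal population's 0.95
  percentile and `[Q1_β, Q3_β]` the beta interquartile range on CD133,

  ```
  RPI = clamp( (P95_α − Q1_β) / (Q3_β − Q1_β), 0, 1 )
  ```

  RPI ≈ 1 means the populations overlap; RPI ≈ 0 means the alpha upper
  boundary sits below the beta bulk and sorting will be clean.
* **`isletsort.timing`** — RPI time courses over stage-6 days 0–7 and
  sort-window selection (`argmin` or `first_below`).
* **`isletsort.gating`** — gate simulation: exact rank-based top-fraction
  gates, fixed thresholds, automatic positive/negative splits for bimodal
  markers, sequential (daughter-gate) composition, and purity / yield /
  enrichment accounting with ground-truth labels.
* **`isletsort.stats`** — exact Wilcoxon signed-rank and Mann–Whitney
  tests (enumeration at replicate-scale n) with conventional star
  annotations.
* **`isletsort.io`** — CSV event tables (canonical), a read-only FCS
  3.0/3.1 list-mode subset, and JSON/TSV gating reports.

## Worked example

```python
import isletsort as ist

cfg = ist.default_sc_islet_config(seed=1)

# When to sort: RPI across stage-6 days 0..7
course = ist.compute_timecourse(
    ist.simulate_timecourse(cfg, 5000, range(8)), "CD133")
print([round(v, 3) for v in course.values])
print("sort on day", ist.select_sort_window(course, "argmin"))

# What sorting achieves at day 7
table = ist.simulate_events(cfg, 10000, 7)
dual = ist.apply_sequential(table, ist.dual_sort_gates())
print("pre-sort beta fraction ", ist.composition(table).fraction(ist.CellClass.BETA))
print("post-sort beta fraction", ist.composition(dual).fraction(ist.CellClass.BETA))
```

prints

```
[1.0, 1.0, 1.0, 1.0, 1.0, 0.794, 0.553, 0.332]
sort on day 7
pre-sort beta fraction  0.2471
post-sort beta fraction 0.9304857621440537
```

The index stays pinned at 1 (full overlap) through mid-stage 6, falls
steeply as the beta CD133 distribution pulls away from the alpha one, and
is lowest at day 7 — the chosen sort window.  Sorting there with the dual
CD49a→CD133 gate raises beta purity from ~25% to ~93% while removing
ductal-like events entirely (CD133 alone would carry them along).

The same operations are available from a shell:

```
isletsort simulate --n 10000 --day 7 --seed 1 --out day7.csv
isletsort rpi --events day7.csv --channel CD133
isletsort gate --events day7.csv --gates gates.json --report report.json
```

## Documentation

`docs/methods.md` describes the simulator's calibration, the RPI
definition and its conventions, gate semantics, the exact-test algorithms,
and known limitations.
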