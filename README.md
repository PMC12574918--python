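# tigermove

Movement-network analysis of passive acoustic telemetry for large
coastal sharks, built around a two-island tiger shark (*Galeocerdo
cuvier*) receiver study: 32 moored receivers in two arrays (18 around
New Providence, 14 around Great Exuma, The Bahamas) listening for
surgically implanted coded transmitters in sharks spanning 91–300 cm
fork length (FL).

It is written for movement ecologists who want the full chain from raw
detection exports to life-stage-resolved space-use statistics as
tested, reusable code:

1. **Detection QC** — removes false detections: records closer to the
   previous retained detection of the same tag at the same station than
   the tag's minimum transmission delay (Rule A), and isolated records
   with no other detection of that tag within ±24 h (Rule B).
2. **Residency** — reduces detections to *detection days* and computes
   the residency index `RI = detection days / monitoring period`
   (first-to-last detection, inclusive), station-residency runs
   (consecutive detection days at one station), occupancy, and monthly
   summaries.
3. **Growth-corrected life staging** — integrates a piecewise
   size-class growth schedule (4–40 cm FL/yr) to estimate FL at first
   detection, because sharks tagged up to 415 days before first
   detection may have changed life stage (YOY < 110 cm FL, juvenile
   < 180, sub-adult ≥ 180, adult > 255 ♂ / > 265 ♀) in the interim.
4. **Movement networks** — per-individual directed graphs with
   receivers as nodes and consecutive-detection station changes as
   weighted edges, built over each shark's *active stations* (receivers
   deployed during its monitoring window). Node metrics: connectivity
   (degree), betweenness (raw shortest-path counting), occupancy,
   station residency. Motility is summarised per shark per array as

   - node density = visited stations / active stations,
   - edge density = distinct ordered station pairs traversed / n(n−1),

   and observed metrics are screened against Erdős–Rényi G(n, m) nulls
   with a one-sample Wilcoxon signed-rank test (exact for n ≤ 12).
5. **Motility models** — nine candidate additive models of edge density
   vs `s(FL)` (penalized cubic regression splines, optionally by sex)
   plus sex/island factors, compared by AIC, ΔAIC and Akaike weights
   `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`; the default selection rule takes
   the highest deviance explained among models within ΔAIC < 2.
6. **Synthetic telemetry** — a continuous-time Markov movement
   simulator over stations plus an off-array state, with a sex-specific
   motility effect (linear in FL for males, unimodal with a 237.5 cm
   peak for females) driving both move rate and home-range extent,
   imperfect detection, and injected false detections — so the whole
   chain runs with known ground truth and parameter recovery can be
   asserted.

## Worked example

```python
import tigermove as tm

# simulate a cohort at the study conditions and run the full pipeline
bundle = tm.run_cohort(tm.SimConfig(seed=1))

ri = bundle["residency"]["residency_index"]
print(f"mean RI {ri.mean():.2f} -> {tm.percent_time_outside(ri.mean()):.0f}% "
      "of monitored time outside the arrays")
print(bundle["model_table"].head(3).round(2).to_string(index=False))
print("selected:", bundle["selected_model"]["model_id"])
```

prints (seed 1):

```
mean RI 0.28 -> 72% of monitored time outside the arrays
                         model_id     aic  delta_aic  akaike_weight  edf  deviance_explained_pct
ED ~ s(FL, by=Sex) + Sex + Island -101.04       0.00           0.24 5.70                   32.85
        ED ~ s(FL) + Sex + Island -100.86       0.18           0.22 4.69                   29.04
                 ED ~ s(FL) + Sex  -99.93       1.11           0.14 3.45                   22.73
selected: ED ~ s(FL, by=Sex) + Sex + Island
```

A mean residency index of 0.28 means the simulated sharks were detected
on 28% of the days between their first and last detection; the model
table ranks the nine edge-density candidates by AIC, and the default
rule selects the sex-specific smooth — the data were simulated with a
genuinely sex-specific motility effect, so that is the right answer.

The growth correction alone:

```python
tm.estimate_fl_at(176.0, "2019-07-01", "2021-06-01")   # -> 211.1 cm
tm.classify_life_stage(211.1, "F")                     # -> 'sub-adult'
```

a 176 cm juvenile grows to ~211 cm in ~23 months, crossing the 180 cm
juvenile/sub-adult boundary en route.

There is also a CLI:

```bash
tigermove simulate --seed 1 --outdir out/sim
tigermove qc --detections out/sim/detections.csv --tags out/sim/tags.csv --outdir out/qc
tigermove all --seed 1 --outdir out/full
```

## Layout

- `src/tigermove/io.py` — CSV dialects (native + VUE-style headers), QC filter
- `src/tigermove/residency.py` — detection days, RI, runs, occupancy
- `src/tigermove/growth.py` — growth schedule, staging (`data/growth_schedule.csv`)
- `src/tigermove/network.py` — networks, metrics, null models, GraphML export
- `src/tigermove/models.py` — penalized-spline motility models, AIC selection
- `src/tigermove/simulate.py` — synthetic telemetry generator
- `src/tigermove/reference.py` — synthetic reference cohort (stand-in attribute table)
- `src/tigermove/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter defaults, limitations
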