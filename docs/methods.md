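# Methods

This note documents the models and procedures implemented in
`tigermove`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data tests do and do not
demonstrate about real telemetry data.

## Detection quality control

A coded transmitter cannot be heard twice at one receiver within less
than its minimum transmission delay, so such records are physically
impossible and are removed (Rule A). Rule A compares each record
against the previous **retained** record of that tag at that station,
scanning forward in time: comparing against the previous raw record
would let a burst of spurious detections shield its own members.
Rule A is restricted to same-station pairs by default (a tag can be
legitimately heard at two stations in quick succession where detection
ranges overlap); `same_station_only=False` switches to array-wide
comparison.

Rule B removes isolated records: a detection with no other detection of
the same tag anywhere in the array within ±`isolation_window_h`. The
window defaults to 24 h, matching the day scale on which residency is
defined; it is a parameter because the isolation notion has no single
field-standard width. Because the window is symmetric, any record's
witness is itself witnessed, so the filter is idempotent — a property
the tests assert.

## Residency statistics

All downstream statistics are built on **detection days** — unique
(shark, station, calendar date) triples in a configurable timezone
(default UTC). The residency index is

RI = (number of detection days) / (monitoring period in days),

with the monitoring period counted inclusively, (last − first) + 1, so
a single-day record gives RI = 1 rather than a division by zero.

Station-residency runs count consecutive detection days at one station;
a run ends when the shark is detected at another station or is absent
over 24 h — interpreted at day resolution as a gap of at least one full
calendar day — and re-detected. Days with detections at several
stations are ordered by earliest ping (ties by station id): the
earlier-visited station's run continues through that day and then
closes. Run lengths conserve detection days per (shark, station), which
the tests assert.

Occupancy is the group mean of total detection days per station. The
group mean includes members with zero days (default) — optionally only
members whose monitoring window overlapped one of the station's
deployments, consistent with the active-station rule below; a
detected-sharks-only mean is available because both conventions appear
in practice.

## Growth correction and life staging

Fork length at an arbitrary date is estimated by integrating a
piecewise size-class growth schedule in daily steps, switching rates
when a class boundary is crossed; daily stepping bounds the
discretisation error by one day's growth (≤ 0.11 cm at the fastest
class) and makes the estimate exactly additive in time. The default
schedule (cm FL/yr over cm FL classes; `data/growth_schedule.csv`):

| class (cm FL) | rate (cm/yr) |
|---|---|
| 50–110 | 40 |
| 110–180 | 21 |
| 180–265 | 18 |
| 265–400 | 6 |

Rates decelerate with size, stay within the 4–40 cm/yr band reported
for the species, and the sub-adult class rate is pinned by the worked
example of a 176 cm juvenile reaching ≈211 cm over ≈23 months. Users
can substitute any schedule (CSV/YAML) satisfying the same invariants.

Life stages: YOY < 110 cm FL, juvenile < 180, sub-adult ≥ 180, adult
> 255 cm (males) / > 265 cm (females). The boundary value 180 cm is
assigned to sub-adult (the published band definitions leave it
unassigned). With sex unknown and FL inside the (255, 265] band the
classifier returns `indeterminate` rather than guessing. Because growth
is non-negative, stage is monotone through time.

`restage_cohort` recomputes FL and stage at first and last detection
and reports every stage change between tagging and first detection —
the correction that matters in multi-year studies where elapsed time to
first detection can exceed a year.

### Synthetic reference cohort

The per-shark attribute table behind the published summary counts is
not deposited, so `tigermove.reference` constructs a **synthetic**
39-shark stand-in that satisfies the published constraints
simultaneously: sex ratio 30 F : 9 M; FL at first detection spanning
91–300 cm (140–253 cm for males) with a non-significant pooled t-test
between sexes on 37 df; elapsed tagging-to-first-detection times
spanning 0–415 days with mean 50; final stage counts 1 YOY /
6 juvenile / 22 sub-adult / 10 adult; and exactly five sharks tagged as
sub-adults that cross the female maturity threshold by first detection.
Tagging lengths are back-solved from target first-detection lengths by
bisection under the growth schedule, so the cohort stays internally
consistent if the schedule is replaced. It is a consistency witness,
not a reconstruction of the real animals.

## Movement networks

Receivers are nodes; a movement is a pair of consecutive retained
detections of one shark at two different stations, giving directed
weighted edges. Repeat detections at one station are not movements (no
self-loops). Each shark's network is restricted to its **active
stations** — receivers with a deployment interval overlapping the
shark's monitoring window by ≥ 1 day — so density denominators reflect
the stations the shark could actually have been heard on.

- Node density = |visited| / |active|.
- Edge density = |distinct ordered pairs traversed| / n(n−1).

Edges are directed by default ("every combination of movements" read as
ordered pairs); an undirected convention (denominator n(n−1)/2) is a
flag, since published density conventions are often unstated. Edge
density counts distinct pairs; movement counts are kept as weights.
Transitions spanning the two arrays are tallied separately as
inter-array connectivity and are not edges of either array network —
the arrays are analysed as separate networks, because cross-array
animals in this system visit only single stations in the second array.

Betweenness is raw (unnormalised) shortest-path counting on the
unweighted directed graph with fractional credit for tied shortest
paths (Brandes' algorithm via networkx); a brute-force all-shortest-path
enumeration oracle verifies it on every random digraph with ≤ 8 nodes
in the tests. Connectivity counts distinct neighbours linked by at
least one edge in either direction.

A note on an invariant that does *not* hold: node density can only
shrink when detections are removed, but edge density is not monotone
under arbitrary thinning — removing an intermediate detection splices
its neighbours into a new consecutive pair. Edge density is monotone
under truncation of the stream; the tests assert exactly the true
properties.

### Random-network screen

Observed per-node metrics are compared against Erdős–Rényi G(n, m)
directed graphs matching the observed node and edge counts, via a
one-sample Wilcoxon signed-rank test of the per-node values against the
null grand mean (node labels in G(n, m) are exchangeable). The exact
two-sided tail is computed by convolving the signed-rank-sum
distribution for n ≤ 12; above that a normal approximation with
continuity and tie corrections is used; all-zero differences return
p = 1 flagged degenerate.

This screen should be read descriptively: per-node metrics within one
graph are dependent and betweenness is right-skewed, so the test is not
exactly calibrated even when the observed graph is itself a G(n, m)
draw. The signed-rank implementation itself is calibrated (uniform p
under iid symmetric differences) and exact against full 2^n sign
enumeration — both tested. The G(n, m) null with fixed node and edge
counts is one of several defensible randomisations; it is pluggable.

## Motility models

Nine candidate models of edge density are fitted: smooths of FL
(shared or by-sex) with optional sex and island factors, and the two
factor-only models. Smooths are cubic B-splines with k = 5 basis
functions, a sum-to-zero centring constraint, and a second-difference
(P-spline) penalty; the smoothing parameter is selected per model by
GCV over a 25-point log grid, and AIC is computed with the effective
degrees of freedom (trace of the hat matrix) plus one for the scale.
Penalisation matters here: with ~40 records an unpenalised k = 5 spline
wiggles, and a by-sex smooth would pay a fixed 2(k−1) AIC charge even
when the sexes' curves barely differ — with GCV shrinkage its
effective-df cost adapts, which is what makes the published-style
selection dynamics (several models within ΔAIC < 2, sex-specific model
best on deviance) reproducible.

The response is Gaussian on the (0, 1) densities, mirroring common
practice for these models; densities near the boundary make a beta
family a reasonable alternative but one that changes AIC scale, so it
is out of scope here. Records entering the models are one per shark
(each shark's primary array, i.e. most detection days, with island set
accordingly).

Selection: ΔAIC and Akaike weights from the AIC column; default rule
picks the highest deviance explained among models within ΔAIC < 2
(ties to lower AIC), the trade-off of interpretability against support
used in this literature; a pure-AIC rule is available.

Smooth shape is classified from the fitted curve on a 201-point FL
grid: *linear* (no interior extremum), *unimodal* (exactly one interior
maximum exceeding both endpoints by > 1 SE), else *other*;
monotonicity is judged with a 1%-of-range tolerance to ignore
numerically flat stretches, and the interior argmax is always reported
for peak-recovery checks. Smooth F statistics are Wald-type on the
penalized coefficients and should be read as approximate.

The sex comparison of body size is a pooled-variance two-sample t-test
(df = n₁ + n₂ − 2; the pooled form is what reproduces 37 df for a
30 + 9 cohort).

## Synthetic telemetry generator

The generator emulates the study conditions: two arrays of 18 + 14
stations with habitat mix 9 coral reef / 6 deep wall / 3 sand /
14 seagrass, depths 2–207 m, staggered deployments; a cohort of 40
sharks (77% female) with truncated-normal FL distributions (females
218 ± 49 cm on 91–300, males 209 ± 45 cm on 140–253).

Movement is a continuous-time Markov chain over stations plus an
explicit off-array state. While at a station a shark initiates a
station-to-station move at rate r₀ + (r₁−r₀)·m (defaults
0.03–0.16 h⁻¹) or leaves the array at 0.25 h⁻¹; away spells are
exponential with mean 72 h (per-shark lognormal heterogeneity,
σ = 0.35), tripled during June–September to mimic seasonal emigration.
The **motility effect** m ∈ [0.1, 1] is the generative analogue of the
fitted relationship: linear in FL for males, a Gaussian bump peaking at
237.5 cm (σ = 35 cm) for females; it scales both the move rate and a
home-range radius (4–22 km) that weights destination and return
choices together with proximity to the current station. FL grows daily
under the growth schedule, so motility and life stage change
mid-track. These defaults were calibrated once so the emergent
summaries sit in the observed ranges for this system (mean RI ≈ 0.26,
edge density ≈ 0–0.3, node density broad with mean ≈ 0.5–0.7).

Detections: every visit lasts at least one maximum transmission delay,
pings occur at uniform delays in 120–300 s, are dropped outside the
station's deployment window, and survive with probability 0.6. False
detections are injected at 0.05 per tag-day in the two classes the QC
filter targets — impossible short-interval duplicates (guaranteed
removable, so Rule-A recall is measurable and equals 1) and isolated
singletons. The default study window is 18 months (2018-02-01 to
2019-07-31), a problem size that keeps a full cohort simulation under
ten seconds while leaving hundreds of visits per shark.

What the generator does **not** emulate: distance-dependent detection
probability (detection is binary in-residence; no range model is
published for this array), depth use, temperature or tide effects,
inter-animal interactions, and tag loss or mortality. Passing recovery
tests therefore show the estimators recover the parameters of *this*
movement model at realistic data sizes — not that real tiger shark data
meet its assumptions.

## Parameter recovery, numerical choices, determinism

At the study conditions (40 sharks, 32 stations, five seeds) the test
suite asserts: the sex-specific smooth is selected by the default rule
in a majority of seeds; the fitted male trend is monotone increasing in
a majority; and the fitted female peak lands within ±15 cm of the
237.5 cm truth (majority of seeds, and in median). With ~9 males per
cohort these are small-sample fits; majorities rather than unanimity
are the honest bar.

All randomness flows from explicit `numpy` generators seeded per phase
from the run seed; same seed ⇒ byte-identical outputs (tested end to
end). Ties are broken deterministically everywhere (timestamps, then
ids). Degenerate inputs are defined rather than fatal: single active
station ⇒ edge density 0 with a flag; single detection day ⇒ RI = 1;
all-zero null differences ⇒ p = 1 flagged.

## Known limitations

- The Gaussian response for bounded densities can predict slightly
  outside (0, 1) at the extremes of the FL range.
- Smooth F/p values are approximate under penalisation (as are their
  published counterparts, whose basis and family are unreported).
- The inclusive monitoring-period convention makes RI of very short
  records coarse (1 day ⇒ RI = 1).
- Group occupancy depends on the zero-member convention; both
  conventions are computed, the group mean is the default.
- The G(n, m) null preserves only node and edge counts, not spatial
  structure; stations are geographically embedded, so rejections are
  expected and should not be over-interpreted.
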