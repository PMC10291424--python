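# Methods

This note records the models, conventions and numerical choices behind
`copial`, and what the synthetic-data tests do and do not establish about
real archaeological data.

## Niche classification and occupancy

A cell-year is in the maize direct-precipitation farming niche when
precipitation (water-year, cm) and Fahrenheit growing degree days both
*strictly* exceed their thresholds (defaults 30 cm, 1800 FGDD). We read
"exceeding" literally, so boundary cells are out of niche;
`NicheParams(inclusive_thresholds=True)` switches to ≥ for sensitivity
checks. The classification is a conjunction and is monotone
nondecreasing in each input.

Occupancy in year *t* counts any occupation span intersecting
[*t* − lookback, *t*] (default lookback 3 years). Spans are closed
calendar-year intervals attached to exactly one cell; a span's length is
end − start + 1, so a single-year occupation has length 1.

Room to walk is the difference of two proportions:
occupied-in-niche / occupied − in-niche / total. In a year with no
occupied cells the first proportion is 0/0; we report it (and room to
walk) as undefined rather than zero — absence of settlement is not
evidence that settlement avoided the niche. Undefined values propagate
through the trailing smoother, which averages only the defined values in
its window. The unoccupied-niche measure is reported as a fraction of
all cells, (n_in_niche − n_occupied_in_niche) / n_total; both counts are
also in the output, so an absolute-count variant is a column subtraction
away. Occupied cells lacking climate records raise a coverage error
instead of silently distorting denominators.

The smoothing window is one-sided and trailing, default 11 years
*including* the current year (t−10 … t). A "preceding 11 years" reading
that excludes the current year is available via
`window_includes_current=False`; the two differ by a one-year shift and
we default to the window that ends at the reported year. Windows are
truncated at the series start rather than padded.

## Gini estimation

The default estimator is the uncorrected population Gini
G = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ), computed from the sorted sample in
O(n log n); the pairwise O(n²) form exists in the test suite as an
independent oracle, and the two agree to 1e−12. The n/(n−1) correction
is a flag, off by default: comparability of a *series* of Ginis across
periods matters more than the small bias at the period sample sizes we
target, and the uncorrected form is the one with exact replication
invariance. Houses (not settlements) are the unit of observation;
nonpositive areas are rejected at ingest.

Uncertainty is a percentile bootstrap over houses (default B = 500–1000,
α = 0.05), clipped to [0,1] and widened if needed to bracket the point
estimate. Periods with fewer than `min_n` houses (default 5) are
reported with an undefined Gini and a recorded reason, keeping one row
per period for downstream joins.

## Growth, churn, persistence

Annualized growth between period midpoints is geometric:
r = 100·((P₂/P₁)^(1/Δt) − 1) %/yr, matching the percent-per-year
convention; the composition over consecutive intervals is the
Δt-weighted geometric mean. Zero-population endpoints make a rate
undefined — a colonization or abandonment, flagged as such, excluded
from churn counts but listed in the output. Churn counts subregions with
|r| ≥ threshold (default 0.7 %/yr), boundary inclusive.

Persistence assigns each occupation span to the period containing its
start year (proportional allocation across periods was rejected as
harder to test and to explain), and reports the mean span length and
count per period. An optional hamlet/village split classes settlements
by their total house count (default village ≥ 3 houses); when the split
is on, the village class is the persistence covariate used downstream.

## The demographic simulator

State is a vector of annual cohorts n₀…n₈₀. Each year:

1. E = yield · min(arable_area, c·L) / D, with labour L = Σ lₐnₐ and
   baseline demand D = Σ ρₐnₐ (adult-equivalent units).
2. Multipliers φ_f, φ_s = 1 for E ≥ 1; for E < 1,
   φ = ((E − E₀)/(1 − E₀))₊^γ with floors E_f0 = 0.25 (fertility) and
   E_s0 = 0 (survival).
3. Births Σ fₐφ_f nₐ enter age 0; survivors sₐφ_s nₐ shift up one age;
   the terminal class dies (an absorbing option exists). Deaths and
   survivors account exactly for every cohort, and CBR − CDR equals the
   year's relative growth identically.

The functional forms of the E-response are this package's own
concretization — continuous, nondecreasing power ramps with floors — not
a reconstruction of any published elasticity schedule. The curvature
default γ = 0.08 deserves comment: because φ_s multiplies survival at
*every* age in the same year, the food feedback at γ = 1 is essentially
deadbeat — growth stops within a year of E crossing 1 and the transition
degenerates to a point. A shallow ramp lowers the loop gain so the
tightening spreads over decades, which is the regime of interest: the
reference run's Copial Phase lasts 357 years and its Malthusian
Transition Interval 56 years, with equilibrium E ≈ 0.85.

The reference parameterization is *derived*, not hand-tuned: survival is
a high-infant-mortality curve (s₀ = 0.80, flattening to ≈0.996 in
adulthood, collapsing after 75); fertility is a Gaussian-shaped hump
over ages 15–44 scaled by eigenvalue bisection so intrinsic growth is
exactly 1.3 %/yr; arable_area is sized so land-limited supply balances
baseline demand (at the abundance stable age structure) at N = 10⁴; and
the labour coefficient gives labour twice the land it needs at that
point, keeping the approach land-limited. Founding populations start at
100 people in stable-age proportions. The model is deterministic; no
climate forcing enters the simulator — interannual variability lives in
the niche module's world.

Phase detection: copial_end is the first year with E < 1;
malthusian_start the first later year opening `malthusian_k` (default
10) consecutive years with |ΔN/N| < eps_growth (default 1e−4). The
sustained-run requirement keeps transient echoes of the age structure
from declaring equilibrium early.

The juvenility-index estimator CBR = a + b·P is a configurable linear
map; the shipped defaults (a = 10, b = 120 per 1000 person-years) are
illustrative external constants spanning a plausible 20–60 CBR range and
should be replaced with the user's preferred skeletal-calibration
regression.

## Synthetic worlds

The generator's job is planted structure, not realism:

- **Climate.** Log-precipitation is a stationary AR(1) (coefficient =
  the configured lag-1 autocorrelation) mixing a landscape-wide and a
  per-cell component, so fields are spatially and temporally correlated
  and strictly positive; with zero variance every cell-year equals the
  mean exactly. FGDD is a deterministic across-cell gradient plus
  zero-truncated normal noise. Defaults (35 cm mean, CV 0.25, AR1 0.3,
  FGDD 2000 with −1.5/cell gradient and SD 120) put the landscape partly
  in and partly out of niche in a typical year.
- **Settlement.** Foundings are uniform in time (or pinned per period);
  with probability `niche_preference` (default 0.9) a founding cell is
  drawn from the cells in niche that year. Span lengths are geometric
  (mean 25 years by default, sub-generational), truncated at the horizon
  so occupancy never outruns climate coverage.
- **Houses.** Floor areas are lognormal around 15 m² with σ =
  √2·Φ⁻¹((G+1)/2), inverting G = 2Φ(σ/√2) − 1, so each period's
  *population* Gini equals the planted value exactly. Lognormality is a
  harness choice that makes the planted Gini exact — it is not a claim
  about archaeological house-size distributions.
- **Populations.** Each subregion compounds a percent-per-year schedule
  between period midpoints from a common initial size, plus optional
  per-(subregion, period) migration pulses; with a flat schedule the
  series is exactly constant.

One seed fans out into four fixed substreams (landscape, occupation,
houses, populations), so a stage can be regenerated independently and
identical (config, seed) reproduces every table exactly.

What passing these tests shows: the pipeline recovers structure it was
promised, under clean sampling assumptions. What it does not show: that
real settlement data meet those assumptions — real house-size
distributions need not be lognormal, occupation dating is censored and
uncertain rather than exactly spanned, population estimates carry
aggregation error, and climate reconstruction error is absent entirely.

## Association testing

Covariates join on the period grid — one row per period, always; niche
statistics are averaged over the years inside each period; missing cells
stay missing. Inference is Spearman rank correlation with a two-sided
permutation p-value, (1 + #{|ρ*| ≥ |ρ|}) / (n_perm + 1) over label
shuffles, requiring at least 4 complete periods. With ~14 periods,
unknown marginals and no independence guarantees, a rank statistic with
permutation calibration is about as much inference as the data support;
the type-I rate at the 0.05 level is verified to sit in [0.02, 0.08]
over 500 null datasets.

## Problem sizes in the test and acceptance suites

The statistical studies run at sizes chosen to make their conclusions
stable while keeping the default suite fast: Gini recovery uses 200
seeds at n = 500 (±0.02 band; the sampling SD at the planted G = 0.3 is
≈0.010); sign recovery uses 200 planted worlds of 30 cells × 850 years
with 150 houses per period; the permutation calibration uses 500 null
tables of 14 periods; oracle equivalences run at n ≤ 300 (Gini) and
≤ 10⁴ cell-years (niche counting). The demographic reference run is
1500 annual steps.

## Known limitations

- A settlement occupies exactly one cell; multi-cell settlements and
  within-settlement household histories are out of scope.
- The simulator has no stochasticity, no climate forcing, and no
  technological or institutional change; its Malthusian Phase is an
  absorbing equilibrium by construction.
- Churn inherits whatever population measure it is given; comparing
  churn built from one population series against covariates built from
  another deserves caution, and the run manifest records provenance for
  exactly that reason.
- The period grid is treated as data: statistics are only as fine as the
  periodization supplied.
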