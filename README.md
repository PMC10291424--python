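# copial

Wealth inequality, mobility constraints and food-limited population
dynamics for agrarian settlement records.

`copial` is a tested analysis pipeline for archaeologists and human
population ecologists studying how wealth differences emerge in
smallholder farming societies as the landscape fills up. It was built for
upland dry-farming settlement records of the US-Southwest type — annual
cell-level climate reconstructions, tree-ring-dated occupation spans,
house floor areas by archaeological period, and subregional population
series — but every input is a plain CSV and every stage also runs on
synthetic data with known planted structure.

## What it computes

**Farming niche and room to walk.** A landscape cell-year is in the maize
direct-precipitation farming niche when water-year precipitation exceeds
30 cm and Fahrenheit growing degree days exceed 1800. Crossing the niche
classification with occupancy (a cell is occupied in year *t* if a
settlement span intersects [*t*−3, *t*]) gives the annual series

```
room_to_walk(t) = n_occupied_in_niche / n_occupied  −  n_in_niche / n_cells
```

— high when plenty of unoccupied farmable land remains, with the second
term stripping most climate variability out of the first. The series is
reported raw and smoothed with a trailing 11-year moving average, along
with the unoccupied-niche fraction (n_in_niche − n_occupied_in_niche) / n_cells.

**Wealth inequality.** Per period, the Gini coefficient of house floor
areas, G = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ), with percentile-bootstrap intervals. An
optional n/(n−1) small-sample correction is available; the uncorrected
population Gini is the default.

**Mobility.** Annualized subregional growth between consecutive period
midpoints, r = 100·((P₂/P₁)^(1/Δt) − 1) %/yr; *churn* counts the
subregions with |r| ≥ 0.7 %/yr in each period (growth that size more
plausibly reflects migration than natural increase; with six subregions
the count is bounded 0–6). *Persistence* is the mean occupation-span
length per period.

**Food-limited demography.** A deterministic annual-cohort simulator: the
food ratio E = yield · min(arable, c·L) / D compares production (limited
by land or by labour L = Σ lₐnₐ) with baseline demand D = Σ ρₐnₐ. While
E ≥ 1 the population grows at the dominant eigenvalue of its Leslie
matrix; below 1, fertility and survival are scaled by continuous ramps
with floors. Trajectories divide into a long Copial Phase (E > 1), a
short Malthusian Transition Interval, and a Malthusian Phase in which
birth and death rates converge. The reference run yields a 357-year
Copial Phase and a 56-year transition.

**Association.** All covariates are joined on the period grid and tested
with Spearman rank correlation plus a permutation p-value — deliberately
modest inference for ~14 periods of unknown marginals.

## Worked example

Plant a world in which inequality, settlement persistence and landscape
packing all rise together over fourteen 50-year periods (AD 600–1299):

```yaml
# planted.yaml
synthetic:
  n_cells: 30
  years: [600, 1449]
  houses_per_period: 150
  planted_gini_by_period: {P01: 0.15, P02: 0.18, P03: 0.21, P04: 0.24, P05: 0.28,
                           P06: 0.31, P07: 0.34, P08: 0.37, P09: 0.40, P10: 0.43,
                           P11: 0.46, P12: 0.49, P13: 0.52, P14: 0.55}
  occupation_duration_by_period: {P01: 8, P02: 14, P03: 19, P04: 25, P05: 30,
                                  P06: 36, P07: 41, P08: 47, P09: 52, P10: 58,
                                  P11: 63, P12: 69, P13: 74, P14: 80}
  foundings_by_period: {P01: 2, P02: 3, P03: 4, P04: 5, P05: 6, P06: 7, P07: 8,
                        P08: 9, P09: 10, P10: 11, P11: 12, P12: 13, P13: 14, P14: 15}
  seed: 42
gini_bootstrap_B: 500
n_perm: 999
```

```bash
copial all --config planted.yaml --out demo --seed 42
```

prints

```
gini ~ mean_persistence_yr: rho=+0.736 (n=14, p=0.007)
gini ~ mean_unoccupied_niche_frac: rho=-0.886 (n=14, p=0.001)
gini ~ mean_room_to_walk: rho=-0.248 (n=14, p=0.414)
gini ~ churn: rho=+0.371 (n=13, p=0.230)
phases: copial 357 yr, transition 56 yr (complete)
```

Periods of high house-size Gini are periods of persistent settlement
(ρ = +0.74) and of a small unoccupied farming niche (ρ = −0.89) — the
planted directional structure, recovered from the generated house,
occupation and climate tables. The demographic reference run reports its
multi-century growth phase and decades-scale food-limited transition.
`demo/` holds every stage table (`niche_series.csv`, `gini_series.csv`,
`churn.csv`, `persistence.csv`, `trajectory.csv`, `association_table.csv`,
…) plus a manifest with the full configuration; rerunning with the same
seed reproduces each file byte for byte.

Each stage is also available as a subcommand (`copial simulate | niche |
gini | churn | persistence | demog-run | associate`) over the documented
CSV schemas, and as plain library functions (`copial.gini`,
`copial.niche_series`, `copial.churn`, `copial.run`, …).

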