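"""Food- and space-limited age-structured population dynamics.

A deterministic annual-cohort simulator for a natural-fertility agrarian
population colonizing a finite arable landscape. The state is a vector of
cohort counts n_a (ages 0..A_max); each year the *food ratio*

    E = yield_per_area * min(arable_area, labor_area_coeff * L) / D

compares the food the population can produce — limited either by land or by
its own labour L = sum(l_a * n_a) — with the baseline demand
D = sum(rho_a * n_a) of the whole population in adult-equivalent units.
While E >= 1 the population grows at its intrinsic rate (the dominant
eigenvalue of the baseline Leslie matrix). Once E falls below 1, fertility
and survival are scaled down by continuous, nondecreasing response ramps

    phi(E) = clip((E - E0) / (1 - E0), 0, 1) ** gamma      (E < 1)

with separate floors E_f0 (fertility) and E_s0 (survival). This produces
the characteristic three-phase trajectory: a long *Copial Phase* of
unconstrained growth while food is abundant, a short, sharp *Malthusian
Transition Interval* once E crosses 1, and a final *Malthusian Phase* in
which birth and death rates converge and growth ceases at an equilibrium
E below 1.

The default parameterization (the *reference run*) is built by
calibration, not hand-tuned constants: the fertility schedule is scaled so
the intrinsic growth rate is 1.3 %/yr, and land supply is sized so the
land-limited balance settles near N = 10^4, which yields a multi-century
Copial Phase followed by a transition lasting only decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

TRAJECTORY_COLUMNS = ["year", "N", "E", "CBR", "CDR", "L", "D"]

#: Default juvenility-index -> crude-birth-rate coefficients (per 1000
#: person-years). These are illustrative external constants mapping
#: P in [0.1, 0.4] onto CBR ~22-58; substitute the fitted regression of
#: your preferred palaeodemographic calibration study.
JUVENILITY_CBR_COEFS = (10.0, 120.0)


# ---------------------------------------------------------------------------
# Schedules and parameters


@dataclass(frozen=True)
class VitalSchedules:
    """Age-specific schedules on annual ages 0..A_max.

    fertility
        Births per person-year under abundance (both sexes pooled, so
        roughly half the per-woman rate); zero outside reproductive ages.
    survival
        Annual probability of surviving from age a to a+1 under abundance.
    labor
        Worker-equivalents contributed by one person of age a.
    consumption
        Adult-equivalent baseline food demand of one person of age a.
    """

    fertility: np.ndarray
    survival: np.ndarray
    labor: np.ndarray
    consumption: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.fertility, self.survival, self.labor, self.consumption]
        if len({a.shape for a in arrays}) != 1 or self.fertility.ndim != 1:
            raise ConfigurationError("all schedules must share one 1-D age axis")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise ConfigurationError("survival must lie in [0, 1]")
        if np.any(self.fertility < 0) or np.any(self.labor < 0) or np.any(self.consumption < 0):
            raise ConfigurationError("fertility, labor and consumption must be nonnegative")

    @property
    def n_ages(self) -> int:
        return self.fertility.size

    def leslie_matrix(self, phi_f: float = 1.0, phi_s: float = 1.0) -> np.ndarray:
        """Projection matrix: first row fertility*phi_f, subdiagonal survival*phi_s."""
        A = self.n_ages
        M = np.zeros((A, A))
        M[0, :] = self.fertility * phi_f
        M[np.arange(1, A), np.arange(A - 1)] = self.survival[:-1] * phi_s
        return M


def default_schedules(intrinsic_growth_pct: float = 1.3, a_max: int = 80) -> VitalSchedules:
    """Plausible pre-industrial schedules scaled to a target intrinsic rate.

    Survival follows a high-infant-mortality curve flattening through
    adulthood and collapsing in old age; fertility is a Gaussian-shaped
    hump over ages 15-44 whose level is solved (by bisection on the Leslie
    dominant eigenvalue) so the abundance-regime growth rate equals
    ``intrinsic_growth_pct`` percent per year.
    """
    ages = np.arange(a_max + 1)
    s = np.full(a_max + 1, 0.995)
    s[0] = 0.80
    s[1:5] = [0.95, 0.96, 0.97, 0.98]
    s[15:50] = 0.996
    s[50:65] = 0.99
    s[65:75] = 0.97
    s[75:] = 0.90
    s[a_max] = 0.0  # terminal age class dies with certainty

    shape = np.where(
        (ages >= 15) & (ages <= 44), np.exp(-0.5 * ((ages - 27) / 7.0) ** 2), 0.0
    )

    labor = np.zeros(a_max + 1)
    labor[7:15] = 0.5
    labor[15:60] = 1.0
    labor[60:70] = 0.5
    labor[70:] = 0.25

    rho = np.ones(a_max + 1)
    rho[:5] = 0.4
    rho[5:10] = 0.6
    rho[10:15] = 0.8
    rho[60:] = 0.9

    target = 1.0 + intrinsic_growth_pct / 100.0

    def lam(scale: float) -> float:
        sched = VitalSchedules(shape * scale, s, labor, rho)
        return _dominant_eigenvalue(sched.leslie_matrix())

    lo, hi = 1e-4, 2.0
    while lam(hi) < target:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if lam(mid) < target:
            lo = mid
        else:
            hi = mid
    return VitalSchedules(shape * (0.5 * (lo + hi)), s, labor, rho)


def _dominant_eigenvalue(M: np.ndarray) -> float:
    vals = np.linalg.eigvals(M)
    return float(np.max(vals.real[np.isclose(vals.imag, 0.0, atol=1e-9)]))


@dataclass(frozen=True)
class DemoParams:
    """Production, response and numerical parameters of the simulator.

    arable_area is in land units, yield_per_area in adult-equivalent food
    units per land unit per year (demand weights rho_a are in the same
    food units), labor_area_coeff in land units workable per
    worker-equivalent. E_f0/E_s0 are the food-ratio floors at which
    fertility/survival reach zero; gamma is the curvature of the response
    ramps; eps_growth is the relative annual growth below which the
    population counts as stationary, and malthusian_k how many consecutive
    stationary years declare the Malthusian Phase.

    The default gamma is deliberately small (0.08). Because the survival
    multiplier acts on every cohort in the same year, a unit exponent
    makes the food feedback near-deadbeat: growth stops within a year of
    E crossing 1 and the Malthusian Transition Interval degenerates to a
    point. A shallow ramp spreads the tightening over decades, giving the
    characteristic multi-century Copial Phase followed by a transition of
    five to six decades.
    """

    schedules: VitalSchedules
    arable_area: float
    yield_per_area: float = 1.0
    labor_area_coeff: float = 1.0
    fertility_floor: float = 0.25
    survival_floor: float = 0.0
    response_exponent: float = 0.08
    eps_growth: float = 1e-4
    malthusian_k: int = 10
    terminal_absorbing: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.fertility_floor < 1:
            raise ConfigurationError("fertility_floor must be in [0, 1)")
        if not 0 <= self.survival_floor < 1:
            raise ConfigurationError("survival_floor must be in [0, 1)")
        if self.arable_area <= 0 or self.yield_per_area <= 0:
            raise ConfigurationError("arable_area and yield_per_area must be positive")
        if self.labor_area_coeff <= 0:
            raise ConfigurationError("labor_area_coeff must be positive")
        if self.response_exponent <= 0:
            raise ConfigurationError("response_exponent must be positive")


@dataclass(frozen=True)
class DemoState:
    """One year of the simulation: cohort vector plus derived aggregates.

    CBR and CDR are the crude birth/death rates of the projection step that
    produced this state (denominator: previous year's population), so
    CBR - CDR equals the year's relative growth exactly; NaN on a freshly
    initialized state.
    """

    year: int
    cohorts: np.ndarray
    cbr: float = math.nan  # rates of the step that *produced* this state,
    cdr: float = math.nan  # per person-year of the previous population

    @property
    def total(self) -> float:
        return float(self.cohorts.sum())

    def labor(self, params: DemoParams) -> float:
        return float(np.dot(params.schedules.labor, self.cohorts))

    def demand(self, params: DemoParams) -> float:
        return float(np.dot(params.schedules.consumption, self.cohorts))


@dataclass(frozen=True)
class PhaseReport:
    """Phase chronology of one trajectory (years; NaN where not reached)."""

    start_year: int
    copial_end_year: float
    malthusian_start_year: float
    copial_duration: float
    mti_duration: float
    status: str  # "complete", "no-food-limit", "no-equilibrium", or "extinct"


@dataclass(frozen=True)
class Trajectory:
    states: tuple[DemoState, ...]
    params: DemoParams
    status: str = "ok"  # "ok" or "extinct"

    def frame(self) -> pd.DataFrame:
        rows = []
        for st in self.states:
            rows.append(
                {
                    "year": st.year,
                    "N": st.total,
                    "E": food_ratio(st, self.params),
                    "CBR": st.cbr,
                    "CDR": st.cdr,
                    "L": st.labor(self.params),
                    "D": st.demand(self.params),
                }
            )
        return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


# ---------------------------------------------------------------------------
# Core relations


def food_ratio(state: DemoState, params: DemoParams) -> float:
    """E = yield * min(arable land, land workable by current labour) / demand.

    Returns NaN for an extinct population (zero demand), which callers
    treat as a halt condition, not an exception.
    """
    D = state.demand(params)
    if D <= 0:
        return math.nan
    worked = min(params.arable_area, params.labor_area_coeff * state.labor(params))
    return params.yield_per_area * worked / D


def vital_response(E: float, params: DemoParams) -> tuple[float, float]:
    """Fertility and survival multipliers (phi_f, phi_s) in [0, 1].

    Both equal 1 for E >= 1 (abundance changes nothing); below 1 they ramp
    down as ((E - floor)/(1 - floor))**gamma, hitting zero at their floors.
    Continuous and nondecreasing in E.
    """
    if math.isnan(E) or E < 0:
        raise DomainError(f"food ratio must be nonnegative, got {E}")
    if E >= 1.0:
        return 1.0, 1.0

    def ramp(floor: float) -> float:
        frac = (E - floor) / (1.0 - floor)
        return max(0.0, frac) ** params.response_exponent

    return ramp(params.fertility_floor), ramp(params.survival_floor)


def project_year(state: DemoState, params: DemoParams) -> DemoState:
    """Advance one year: births enter age 0, survivors shift up one age.

    The food ratio of the *current* state sets this year's vital-rate
    multipliers. Deaths + survivors account exactly for every cohort
    (people reaching past the terminal age die by default, or pile up in
    the terminal class if terminal_absorbing). The returned state carries
    the step's CBR and CDR.
    """
    E = food_ratio(state, params)
    if math.isnan(E):
        raise DomainError("cannot project an extinct population")
    phi_f, phi_s = vital_response(E, params)
    sched = params.schedules
    n = state.cohorts
    births = float(np.dot(sched.fertility * phi_f, n))
    survivors = sched.survival * phi_s * n
    new = np.zeros_like(n)
    new[0] = births
    new[1:] = survivors[:-1]
    if params.terminal_absorbing:
        new[-1] += survivors[-1]
    kept = float(survivors[:-1].sum()) + (
        float(survivors[-1]) if params.terminal_absorbing else 0.0
    )
    N = state.total
    deaths = N - kept
    return DemoState(state.year + 1, new, cbr=births / N, cdr=deaths / N)


def default_params(
    intrinsic_growth_pct: float = 1.3,
    equilibrium_N: float = 1e4,
    labor_slack: float = 2.0,
    **overrides,
) -> DemoParams:
    """The reference parameterization, built by calibration.

    The fertility schedule is scaled for the target intrinsic growth rate;
    arable_area is then sized so baseline demand (at the abundance-regime
    stable age structure) balances supply at E = 1 when N is about
    ``equilibrium_N``, and labor_area_coeff is set so labour could work
    ``labor_slack`` times the arable land at that point — the approach to
    equilibrium is land-limited, not labour-limited.
    """
    sched = default_schedules(intrinsic_growth_pct)
    M = sched.leslie_matrix()
    vals, vecs = np.linalg.eig(M)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    v = v / v.sum()  # stable age distribution under abundance
    rho_bar = float(np.dot(sched.consumption, v))
    l_bar = float(np.dot(sched.labor, v))
    arable = rho_bar * equilibrium_N  # E=1 exactly at N=equilibrium_N (land-limited)
    labor_coeff = labor_slack * arable / (l_bar * equilibrium_N)
    base = DemoParams(
        schedules=sched,
        arable_area=arable,
        yield_per_area=1.0,
        labor_area_coeff=labor_coeff,
    )
    return replace(base, **overrides) if overrides else base


def initial_state(
    params: DemoParams, founding_population: float = 100.0, year: int = 0
) -> DemoState:
    """Founding population at the abundance-regime stable age structure."""
    M = params.schedules.leslie_matrix()
    vals, vecs = np.linalg.eig(M)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    v = v / v.sum()
    return DemoState(year, founding_population * v)


def run(params: DemoParams, init: DemoState | None = None, years: int = 1500) -> Trajectory:
    """Simulate ``years`` annual steps; deterministic.

    Returns the trajectory of years+1 states (fewer if the population goes
    extinct, in which case status is "extinct" rather than an exception).
    """
    if years < 1:
        raise DomainError("years must be >= 1")
    state = init if init is not None else initial_state(params)
    states: list[DemoState] = [state]
    status = "ok"
    for _ in range(years):
        if state.total <= 0 or math.isnan(food_ratio(state, params)):
            status = "extinct"
            break
        state = project_year(state, params)
        states.append(state)
    return Trajectory(tuple(states), params, status)


def detect_phases(trajectory: Trajectory, params: DemoParams | None = None) -> PhaseReport:
    """Locate the Copial / Malthusian-Transition / Malthusian phase boundaries.

    copial_end is the first year with E < 1; malthusian_start the first
    later year opening ``malthusian_k`` consecutive years of relative
    growth below eps_growth in magnitude. Durations: copial_duration =
    copial_end - start, mti_duration = malthusian_start - copial_end.
    """
    params = params or trajectory.params
    df = trajectory.frame()
    if len(df) == 0:
        raise DomainError("empty trajectory")
    start = int(df["year"].iloc[0])
    if trajectory.status == "extinct":
        below = df.loc[df["E"] < 1.0, "year"]
        ce = float(below.iloc[0]) if len(below) else math.nan
        return PhaseReport(start, ce, math.nan, ce - start if not math.isnan(ce) else math.nan,
                           math.nan, "extinct")
    below = df.loc[df["E"] < 1.0, "year"]
    if len(below) == 0:
        return PhaseReport(start, math.nan, math.nan, math.nan, math.nan, "no-food-limit")
    copial_end = float(below.iloc[0])

    N = df["N"].to_numpy()
    years = df["year"].to_numpy()
    rel = np.abs(N[1:] / N[:-1] - 1.0)  # growth of step leaving years[:-1]
    quiet = rel < params.eps_growth
    k = params.malthusian_k
    mstart = math.nan
    if quiet.size >= k:
        window = np.convolve(quiet.astype(int), np.ones(k, dtype=int), mode="valid") == k
        for i in np.flatnonzero(window):
            if years[i] > copial_end:
                mstart = float(years[i])
                break
    if math.isnan(mstart):
        return PhaseReport(
            start, copial_end, math.nan, copial_end - start, math.nan, "no-equilibrium"
        )
    return PhaseReport(
        start, copial_end, mstart, copial_end - start, mstart - copial_end, "complete"
    )


def cbr_from_juvenility(
    P: float, coefs: tuple[float, float] = JUVENILITY_CBR_COEFS
) -> float:
    """Crude birth rate (per 1000 person-years) from a juvenility index.

    A configurable linear estimator CBR = intercept + slope * P, where P is
    the juvenile fraction of skeletal deaths, in [0, 1]. Coefficients come
    from an external palaeodemographic regression supplied via config.
    """
    if not 0 <= P <= 1 or not math.isfinite(P):
        raise DomainError(f"juvenility index must be in [0, 1], got {P}")
    intercept, slope = coefs
    return intercept + slope * P
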