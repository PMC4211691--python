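"""Female-only stochastic age-structured population projection.

The projection follows the management assessment for the repatriated
population: parameter uncertainty is expressed as uniform bounds on age at
first reproduction, proportion female, carrying capacity, eggs per female,
survival at ages 1-3, hatching success, and hatchling survival; juvenile
and adult survival come in as point estimates from the mark-recapture
analysis with temporal stochasticity applied yearly on the logit scale.
Total fertility is the product of proportion female, eggs per female,
hatching success, and hatchling survival, with the four components drawn
perfectly correlated (a conservative choice that widens outcome spread).
Recruitment is Poisson; density dependence is a ceiling at carrying
capacity; quasi-extinction is counted when adult females fall to or below
the threshold at any point in the evaluation window.

Three management scenarios are supported: continued repatriation (annual
juvenile releases for a fixed duration), termination of repatriation, and
termination plus a one-time removal of adults at the start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._rand import substream
from .synthetic import gen_release_schedule

__all__ = [
    "VitalRateBounds",
    "ProjectionConfig",
    "Scenario",
    "Trajectory",
    "ScenarioResult",
    "draw_parameter_set",
    "total_fertility",
    "simulate_population",
    "run_scenario",
    "leslie_lambda",
    "euler_lotka_lambda",
    "native_fraction_path",
    "estimate_fertility_product",
]


@dataclass(frozen=True)
class VitalRateBounds:
    """Uniform lower/upper bounds on the uncertain projection inputs."""

    age_first_reproduction: tuple[float, float] = (17, 17)
    proportion_female: tuple[float, float] = (0.3, 0.7)
    carrying_capacity: tuple[float, float] = (424, 3921)
    eggs_per_female: tuple[float, float] = (4, 10)
    survival_age_1_3: tuple[float, float] = (0.6, 0.9)
    hatching_success: tuple[float, float] = (0.15, 0.26)
    hatchling_survival: tuple[float, float] = (0.15, 0.26)

    def midpoints(self) -> dict[str, float]:
        return {k: (lo + hi) / 2 for k, (lo, hi) in self.__dict__.items()}


@dataclass(frozen=True)
class Scenario:
    """Management scenario applied during projection.

    ``kind``: ``"continued_repatriation"`` (releases ``annual_release``
    female juveniles at ``release_age`` for ``duration`` years),
    ``"terminate"`` (no further releases), or
    ``"terminate_plus_removal"`` (no releases and a one-time removal of
    ``removal`` adult females at the start).
    """

    kind: str = "terminate"
    duration: int = 25
    annual_release: int = 40
    release_age: int = 4
    removal: int = 50


@dataclass
class ProjectionConfig:
    bounds: VitalRateBounds = field(default_factory=VitalRateBounds)
    phi_juvenile: float = 0.958
    phi_adult: float = 0.977
    temporal_sd_logit: float = 0.35
    survivors_2007: int = 864          # released tortoises alive in 2007
    initial_females: int | None = None  # explicit override of the default
    # The published projection approximated initial female abundance by the
    # total number of released survivors; set True to scale it by each
    # replicate's proportion-female draw instead.
    scale_initial_by_proportion_female: bool = False
    # The ceiling is applied to the model's population vector (females) at
    # the drawn K; set True to cap at the female share K * proportion female
    # instead.
    ceiling_on_female_share: bool = False
    # How the ceiling removes the excess: "youngest_first" suppresses
    # recruitment at K (competition falls on the youngest stages, the
    # sensitive stage in long-lived tortoises); "uniform" removes at random
    # across all age classes.
    ceiling_policy: str = "youngest_first"
    start_year: int = 2011
    horizon_years: int = 150
    risk_window_years: int = 100
    replicates: int = 100
    quasi_extinction_adults: int = 75
    count_threshold_as_total_adults: bool = False
    juvenile_age_max: int = 8   # juvenile survival applies below this age
    adult_age: int = 18         # reporting/threshold class
    max_age: int = 45           # terminal age class, self-looping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.quasi_extinction_adults < 0:
            raise ValueError("quasi-extinction threshold must be >= 0")
        for lo, hi in self.bounds.__dict__.values():
            if lo > hi:
                raise ValueError("bounds must satisfy low <= high")


@dataclass
class Trajectory:
    """One replicate: female counts by age class per year."""

    years: np.ndarray                 # (Y,)
    ages: np.ndarray                  # (A,) age of each class (1..max_age)
    counts: np.ndarray                # (Y, A)
    carrying_capacity: float
    quasi_extinct_year: int | None    # first year adults <= threshold

    @property
    def total_females(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def females_age_geq(self, age: int) -> np.ndarray:
        return self.counts[:, self.ages >= age].sum(axis=1)


def draw_parameter_set(config: ProjectionConfig,
                       rng: np.random.Generator) -> dict[str, float]:
    """One uniform draw from the bounds.

    The four fertility components (proportion female, eggs per female,
    hatching success, hatchling survival) share a single uniform quantile,
    making them perfectly rank-correlated; other bounded parameters draw
    independent quantiles.  Degenerate bounds return the bound.
    """
    b = config.bounds
    u_fert = rng.random()
    u_k = rng.random()
    u_s = rng.random()
    u_age = rng.random()

    def lerp(bounds, u):
        lo, hi = bounds
        return lo + u * (hi - lo)

    return {
        "age_first_reproduction": round(lerp(b.age_first_reproduction, u_age)),
        "proportion_female": lerp(b.proportion_female, u_fert),
        "carrying_capacity": lerp(b.carrying_capacity, u_k),
        "eggs_per_female": lerp(b.eggs_per_female, u_fert),
        "survival_age_1_3": lerp(b.survival_age_1_3, u_s),
        "hatching_success": lerp(b.hatching_success, u_fert),
        "hatchling_survival": lerp(b.hatchling_survival, u_fert),
        "phi_juvenile": config.phi_juvenile,
        "phi_adult": config.phi_adult,
    }


def total_fertility(rates: Mapping[str, float]) -> float:
    """Expected female yearlings per breeding female per year: the product
    of proportion female, eggs per female, hatching success, and hatchling
    survival."""
    return (rates["proportion_female"] * rates["eggs_per_female"]
            * rates["hatching_success"] * rates["hatchling_survival"])


def _survival_by_age(rates: Mapping[str, float], ages: np.ndarray,
                     juvenile_age_max: int) -> np.ndarray:
    s = np.where(ages <= 3, rates["survival_age_1_3"],
                 np.where(ages < juvenile_age_max, rates["phi_juvenile"],
                          rates["phi_adult"]))
    return s.astype(float)


def _initial_age_structure(config: ProjectionConfig, n_females: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Spread the initial females over age classes using the historical
    release schedule: a cohort released in year y at age ~4 is aged
    4 + (start_year - y), capped at the terminal class."""
    sched = gen_release_schedule(seed=0)
    by_year = sched.groupby("year")["count"].sum()
    ages = np.clip(4 + (config.start_year - by_year.index.to_numpy()),
                   1, config.max_age)
    weights = by_year.to_numpy(dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(n_females, weights)
    out = np.zeros(config.max_age, dtype=np.int64)
    for a, c in zip(ages, counts):
        out[a - 1] += c
    return out


def _apply_ceiling(n: np.ndarray, k_female: float, rng: np.random.Generator,
                   policy: str = "youngest_first") -> np.ndarray:
    """Truncate the population at the ceiling.

    ``youngest_first`` removes the excess from the youngest classes upward
    (recruitment is suppressed while the population sits at K);
    ``uniform`` removes individuals at random across age classes
    (multivariate hypergeometric).
    """
    total = int(n.sum())
    cap = int(math.floor(k_female))
    if total <= cap:
        return n
    if policy == "uniform":
        keep = rng.multivariate_hypergeometric(n.astype(np.int64), cap)
        return np.asarray(keep, dtype=np.int64)
    if policy != "youngest_first":
        raise ValueError(f"unknown ceiling policy {policy!r}")
    out = n.copy()
    excess = total - cap
    for a in range(len(out)):
        take = min(excess, int(out[a]))
        out[a] -= take
        excess -= take
        if excess == 0:
            break
    return out


def simulate_population(
    rates: Mapping[str, float],
    config: ProjectionConfig,
    rng: np.random.Generator,
    scenario: Scenario | None = None,
    initial: np.ndarray | None = None,
) -> Trajectory:
    """Simulate one replicate of female abundance by age class.

    Annual step: binomial survival per age class (ages 1-3 at the drawn
    rate; juvenile/adult rates with a shared annual logit-normal deviation
    of SD ``temporal_sd_logit``), Poisson recruitment from breeding females,
    aging with recruits entering age 1, ceiling truncation at the female
    share of carrying capacity, then scenario releases/removals.
    """
    scenario = scenario or Scenario("terminate")
    A = config.max_age
    ages = np.arange(1, A + 1)
    if initial is None:
        if config.initial_females is not None:
            n_f = int(config.initial_females)
        elif config.scale_initial_by_proportion_female:
            n_f = int(round(config.survivors_2007 * rates["proportion_female"]))
        else:
            n_f = int(config.survivors_2007)
        n = _initial_age_structure(config, n_f, rng)
    else:
        n = np.asarray(initial, dtype=np.int64).copy()
        if np.any(n < 0):
            raise ValueError("initial abundance must be non-negative")
        if n.size != A:
            raise ValueError(f"initial age vector must have {A} classes")
    years = np.arange(config.start_year,
                      config.start_year + config.horizon_years + 1)
    counts = np.zeros((len(years), A), dtype=np.int64)
    k_female = rates["carrying_capacity"]
    if config.ceiling_on_female_share:
        k_female *= rates["proportion_female"]
    maturity = int(rates.get("age_first_reproduction", 17))
    fert = total_fertility(rates)
    sd = config.temporal_sd_logit

    if scenario.kind == "terminate_plus_removal":
        n = _remove_adults(n, ages, config.adult_age, scenario.removal, rng)
    counts[0] = n
    qe_year = None
    threshold = config.quasi_extinction_adults
    if config.count_threshold_as_total_adults:
        threshold = threshold / 2.0
    if _adults(n, ages, config.adult_age) <= threshold:
        qe_year = int(years[0])

    for t in range(1, len(years)):
        dev = rng.normal(0.0, sd) if sd > 0 else 0.0
        r = dict(rates)
        r["phi_juvenile"] = _logit_shift(rates["phi_juvenile"], dev)
        r["phi_adult"] = _logit_shift(rates["phi_adult"], dev)
        s = _survival_by_age(r, ages, config.juvenile_age_max)
        survivors = rng.binomial(n, s)
        breeders = int(survivors[ages >= maturity].sum())
        recruits = rng.poisson(breeders * fert) if fert > 0 else 0
        # age by one year; terminal class self-loops
        n = np.zeros(A, dtype=np.int64)
        n[1:] = survivors[:-1]
        n[A - 1] += survivors[A - 1]
        n[0] = recruits
        n = _apply_ceiling(n, k_female, rng, config.ceiling_policy)
        if (scenario.kind == "continued_repatriation"
                and t <= scenario.duration):
            n[scenario.release_age - 1] += scenario.annual_release
        counts[t] = n
        if qe_year is None and _adults(n, ages, config.adult_age) <= threshold:
            qe_year = int(years[t])
    return Trajectory(years=years, ages=ages, counts=counts,
                      carrying_capacity=k_female, quasi_extinct_year=qe_year)


def _adults(n, ages, adult_age) -> int:
    return int(n[ages >= adult_age].sum())


def _remove_adults(n, ages, adult_age, removal, rng) -> np.ndarray:
    adult_mask = ages >= adult_age
    pool = n[adult_mask]
    take = min(int(removal), int(pool.sum()))
    if take > 0:
        kept = rng.multivariate_hypergeometric(pool.astype(np.int64),
                                               int(pool.sum()) - take)
        n = n.copy()
        n[adult_mask] = kept
    return n


def _logit_shift(p: float, dev: float) -> float:
    if p <= 0.0 or p >= 1.0 or dev == 0.0:
        return p
    return 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + dev)))


@dataclass
class ScenarioResult:
    scenario: Scenario
    trajectories: list[Trajectory]
    extirpation_probability: float      # percent of replicates
    year_k_reached_median: float        # inf if never reached (censored)
    summary: pd.DataFrame               # year x (total, adult) percentiles

    @property
    def replicates(self) -> int:
        return len(self.trajectories)


def run_scenario(
    config: ProjectionConfig,
    scenario: Scenario | str | None = None,
) -> ScenarioResult:
    """Run the configured number of replicates under one scenario.

    Extirpation probability is the percentage of replicates whose adult
    females ever fall to or below the quasi-extinction threshold within the
    risk window.  The year carrying capacity is first reached is summarized
    as a replicate median, censored at infinity for replicates that never
    reach it within the horizon.
    """
    if isinstance(scenario, str):
        scenario = Scenario(kind=scenario)
    scenario = scenario or Scenario("terminate")
    if scenario.kind not in {"continued_repatriation", "terminate",
                             "terminate_plus_removal"}:
        raise ValueError(f"unknown scenario kind {scenario.kind!r}")
    trajs = []
    hit = 0
    k_years = []
    window_end = config.start_year + config.risk_window_years
    for rep in range(config.replicates):
        # substream keyed by replicate only: scenarios run under common
        # random numbers, so scenario contrasts are not washed out by
        # between-scenario Monte Carlo noise
        rng = substream(config.seed, "projection", rep)
        rates = draw_parameter_set(config, rng)
        tr = simulate_population(rates, config, rng, scenario)
        trajs.append(tr)
        if tr.quasi_extinct_year is not None and tr.quasi_extinct_year <= window_end:
            hit += 1
        total = tr.total_females
        reached = np.nonzero(total >= math.floor(tr.carrying_capacity))[0]
        k_years.append(float(tr.years[reached[0]]) if reached.size else math.inf)
    rows = []
    years = trajs[0].years
    tot = np.stack([t.total_females for t in trajs])
    ad = np.stack([t.females_age_geq(config.adult_age) for t in trajs])
    for i, y in enumerate(years):
        rows.append({
            "year": int(y),
            "total_mean": tot[:, i].mean(),
            "total_p2.5": np.percentile(tot[:, i], 2.5),
            "total_p97.5": np.percentile(tot[:, i], 97.5),
            "adult_mean": ad[:, i].mean(),
            "adult_p2.5": np.percentile(ad[:, i], 2.5),
            "adult_p97.5": np.percentile(ad[:, i], 97.5),
        })
    return ScenarioResult(
        scenario=scenario,
        trajectories=trajs,
        extirpation_probability=100.0 * hit / config.replicates,
        year_k_reached_median=float(np.median(k_years)),
        summary=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Deterministic growth rate
# ---------------------------------------------------------------------------

def leslie_lambda(rates: Mapping[str, float],
                  juvenile_age_max: int = 8) -> float:
    """Dominant eigenvalue of the female-only Leslie matrix.

    Classes are ages 1..maturity with the final (maturity+) class
    self-looping at adult survival; breeding females produce
    ``total_fertility(rates)`` female yearlings per year (the fertility
    product already carries offspring through hatching and the first year,
    so no extra parental-survival factor applies).
    """
    maturity = int(rates.get("age_first_reproduction", 17))
    if maturity < 1:
        raise ValueError("age at first reproduction must be >= 1")
    A = maturity
    M = np.zeros((A, A))
    for age in range(1, A):
        r = {"survival_age_1_3": rates["survival_age_1_3"],
             "phi_juvenile": rates["phi_juvenile"],
             "phi_adult": rates["phi_adult"]}
        M[age, age - 1] = _survival_by_age(r, np.array([age]),
                                           juvenile_age_max)[0]
    M[A - 1, A - 1] = rates["phi_adult"]
    M[0, A - 1] = total_fertility(rates)
    ev = np.linalg.eigvals(M)
    return float(np.max(ev.real[np.abs(ev.imag) < 1e-9]))


def euler_lotka_lambda(rates: Mapping[str, float],
                       juvenile_age_max: int = 8,
                       tol: float = 1e-12) -> float:
    """Euler-Lotka root for the same life cycle, solved by bisection.

    An age-1 recruit reaches the breeding class after m-1 years with
    survivorship l_m and then persists at adult survival; its offspring
    appear as age-1 recruits one further year on, so the renewal condition
    is ``1 = f * lambda**-m * l_m / (1 - phi_adult/lambda)``.
    """
    maturity = int(rates.get("age_first_reproduction", 17))
    f = total_fertility(rates)
    phi_a = rates["phi_adult"]
    ages = np.arange(1, maturity)
    s = _survival_by_age({"survival_age_1_3": rates["survival_age_1_3"],
                          "phi_juvenile": rates["phi_juvenile"],
                          "phi_adult": phi_a}, ages, juvenile_age_max)
    l_m = float(np.prod(s))  # survivorship from age 1 to age maturity

    def g(lam: float) -> float:
        return f * lam ** -maturity * l_m / (1 - phi_a / lam) - 1.0

    lo = phi_a + 1e-9
    hi = max(2.0, phi_a + 1.0)
    while g(hi) > 0:
        hi *= 2
    if g(lo) < 0:   # fertility too low: lambda -> adult survival limit
        return phi_a
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Approximate-likelihood fertility estimation
# ---------------------------------------------------------------------------

def native_fraction_path(
    g: float,
    config: ProjectionConfig | None = None,
    end_year: int = 2007,
    release_age: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected native-born fraction by year when the hatching-success x
    hatchling-survival product equals ``g``.

    Released females (the female half of the historical schedule) and their
    native-born offspring are propagated in expectation with the point
    survival rates and mid-bound fertility components; the returned path is
    native / (native + released) among living females.  Returns
    ``(fractions, years)``.
    """
    config = config or ProjectionConfig()
    sched = gen_release_schedule(seed=0).groupby("year")["count"].sum()
    y0 = int(sched.index.min())
    years = np.arange(y0, end_year + 1)
    b = config.bounds
    eggs_mid = sum(b.eggs_per_female) / 2
    pf = 0.5
    s13 = sum(b.survival_age_1_3) / 2
    maturity = int(sum(b.age_first_reproduction) / 2)
    A = config.max_age
    released = np.zeros(A)
    native = np.zeros(A)
    fert = pf * eggs_mid * g
    ages = np.arange(1, A + 1)
    s = np.where(ages <= 3, s13,
                 np.where(ages < config.juvenile_age_max,
                          config.phi_juvenile, config.phi_adult))
    out = np.zeros(len(years))
    for i, y in enumerate(years):
        if y in sched.index:
            released[release_age - 1] += pf * sched.loc[y]
        tot = released.sum() + native.sum()
        out[i] = native.sum() / tot if tot > 0 else 0.0
        breeders = released[ages >= maturity].sum() + \
            native[ages >= maturity].sum()
        recruits = breeders * fert
        for vec in (released, native):
            surv = vec * s
            vec[1:] = surv[:-1]
            vec[A - 1] += surv[A - 1]
            vec[0] = 0.0
        native[0] = recruits
    return out, years


def estimate_fertility_product(
    observed_native_fractions: Mapping[int, float],
    config: ProjectionConfig | None = None,
    grid: np.ndarray | None = None,
    acceptance_ratio: float = 2.0,
    release_age: int = 4,
) -> dict[str, object]:
    """Estimate the hatching-success x hatchling-survival product from the
    observed rise in the native-born fraction.

    For each grid value g the released population and its native-born
    offspring are propagated forward in expectation from the historical
    release schedule (fertility = 0.5 x mid-eggs x g), and the simulated
    trajectory of the native-born fraction is scored against the
    observations by sum of squared deviations.  Grid values scoring within
    ``acceptance_ratio`` times the minimum form the accepted interval; each
    endpoint maps to a per-component value via the square root (the two
    components are assumed equal).
    """
    if not observed_native_fractions:
        raise ValueError("no observations supplied")
    config = config or ProjectionConfig()
    if grid is None:
        grid = np.linspace(0.005, 0.12, 47)
    obs_years = sorted(observed_native_fractions)
    bad = [f for f in observed_native_fractions.values() if not 0 <= f <= 1]
    if bad:
        raise ValueError("observed fractions must lie in [0, 1]")

    y_end = max(obs_years)
    scores = np.empty(len(grid))
    for i, g in enumerate(grid):
        path, years = native_fraction_path(float(g), config, y_end,
                                           release_age=release_age)
        y0 = int(years[0])
        idx = [int(y - y0) for y in obs_years]
        scores[i] = sum((path[j] - observed_native_fractions[y]) ** 2
                        for j, y in zip(idx, obs_years))
    best = scores.min()
    accepted = grid[scores <= acceptance_ratio * best]
    return {
        "grid": grid,
        "scores": scores,
        "interval": (float(accepted.min()), float(accepted.max())),
        "per_component": (float(math.sqrt(accepted.min())),
                          float(math.sqrt(accepted.max()))),
        "best": float(grid[int(np.argmin(scores))]),
    }
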