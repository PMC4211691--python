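"""Synthetic-data generators for every stage of the repatriation analysis.

No raw field data from the tortoise monitoring program are published, so the
package ships generators that emulate the statistical structure each
downstream analysis assumes: staged releases at three sites, open-population
capture histories with age-structured survival and a logit-normal annual
capture random effect, negative-binomial plot counts driven by habitat
covariates, step-like movement tracks with optional edge avoidance,
two-regime soil delta-13C depth profiles, and two-period cactus stage
censuses.

All generators are pure functions of ``(config, seed)``: repeated calls with
identical arguments return byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from ._rand import substream

__all__ = [
    "SimulationTruth",
    "SyntheticDataset",
    "DEFAULT_RELEASE_YEARS",
    "DEFAULT_SITE_WEIGHTS",
    "DEFAULT_EXCLUDED_YEARS",
    "gen_release_schedule",
    "gen_capture_histories",
    "gen_survey_plots",
    "gen_movement_tracks",
    "gen_soil_profile",
    "gen_cactus_census",
    "generate_dataset",
]

# Releases ran annually 1975-1994 and sporadically 1997-2007; three release
# sites, with El Caco and Las Tunas in the island centre and Gardner Bay to
# the east.  Site weights follow the relative cohort sizes of the recapture
# database (Caco 780, Tunas 370, Gardner 309).
DEFAULT_RELEASE_YEARS: tuple[int, ...] = tuple(range(1975, 1995)) + (
    1997, 1999, 2001, 2003, 2005, 2007,
)
DEFAULT_SITE_WEIGHTS: dict[str, float] = {
    "caco": 780 / 1459,
    "tunas": 370 / 1459,
    "gardner": 309 / 1459,
}
#: Survey years with no recapture data.
DEFAULT_EXCLUDED_YEARS: frozenset[int] = frozenset({1995, 1996, 1998})

DEFAULT_SURVEY_YEARS: tuple[int, ...] = tuple(range(1975, 2008))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationTruth:
    """True vital rates and detection parameters behind a synthetic
    capture-history table.

    Survival is age-structured: ``survival_release_year`` applies to the
    first interval after release, ``survival_juvenile`` to tortoises younger
    than 8, ``survival_adult`` to tortoises 8 and older.  Capture
    probability has separate means for tortoises younger than 15
    (``capture_mean_young``) and 15+ (``capture_mean_adult``) with an annual
    logit-scale normal deviation of SD ``capture_sd_logit`` shared by both
    classes.
    """

    survival_adult: float = 0.977
    survival_juvenile: float = 0.958
    survival_release_year: float = 0.85
    capture_mean_young: float = 0.38
    capture_mean_adult: float = 0.33
    capture_sd_logit: float = 0.3
    fertility_components: tuple[float, float, float, float] = (0.5, 7.0, 0.205, 0.205)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("survival_adult", "survival_juvenile", "survival_release_year",
                     "capture_mean_young", "capture_mean_adult"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.capture_sd_logit < 0:
            raise ValueError("capture_sd_logit must be non-negative")


@dataclass
class SyntheticDataset:
    """Bundle of all generated input tables, one per consumer module."""

    capture_table: pd.DataFrame
    plot_surveys: pd.DataFrame
    movement_records: pd.DataFrame
    soil_samples: pd.DataFrame
    cactus_census: pd.DataFrame
    release_schedule: pd.DataFrame = field(default=None)

    def write_csvs(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.capture_table.to_csv(out / "captures.csv", index=False)
        self.plot_surveys.to_csv(out / "plots.csv", index=False)
        self.movement_records.to_csv(out / "movements.csv", index=False)
        self.soil_samples.to_csv(out / "soil.csv", index=False)
        self.cactus_census.to_csv(out / "census.csv", index=False)
        if self.release_schedule is not None:
            self.release_schedule.to_csv(out / "releases.csv", index=False)


# ---------------------------------------------------------------------------
# Release schedule
# ---------------------------------------------------------------------------

def gen_release_schedule(
    total: int = 1482,
    release_years: Sequence[int] = DEFAULT_RELEASE_YEARS,
    site_weights: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Allocate ``total`` released tortoises across year x site cells.

    Years are weighted uniformly among the declared release years; counts
    are multinomial, so they sum exactly to ``total`` and release-free years
    receive zero.  Returns a long table (year, site, count).
    """
    if total < 0:
        raise ValueError("total released must be non-negative")
    weights = dict(DEFAULT_SITE_WEIGHTS if site_weights is None else site_weights)
    wsum = sum(weights.values())
    if not math.isclose(wsum, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"site weights must sum to 1 (got {wsum})")
    years = sorted(release_years)
    sites = sorted(weights)
    if total == 0 or not years:
        return pd.DataFrame(columns=["year", "site", "count"]).astype(
            {"year": int, "count": int, "site": object}
        )
    rng = substream(seed, "release_schedule")
    cellp = np.array([[weights[s] / len(years) for s in sites] for _ in years])
    counts = rng.multinomial(total, cellp.ravel()).reshape(len(years), len(sites))
    rows = [
        (y, s, int(counts[i, j]))
        for i, y in enumerate(years)
        for j, s in enumerate(sites)
    ]
    return pd.DataFrame(rows, columns=["year", "site", "count"])


# ---------------------------------------------------------------------------
# Capture histories
# ---------------------------------------------------------------------------

def gen_capture_histories(
    truth: SimulationTruth,
    schedule: pd.DataFrame,
    survey_years: Sequence[int] = DEFAULT_SURVEY_YEARS,
    excluded_years: Iterable[int] = DEFAULT_EXCLUDED_YEARS,
    age_at_release_choices: Sequence[int] = (2, 3, 4, 5),
    female_fraction: float = 0.5,
    native_rate: float = 0.0,
    native_start_year: int = 2000,
) -> pd.DataFrame:
    """Simulate the open-population detection process for every released
    individual.

    Each individual receives a latent alive/dead path: Bernoulli survival at
    the release-year rate over its first interval, then the class rate for
    its age (juvenile < 8, adult otherwise).  Detection in each survey year
    while alive is Bernoulli with probability
    ``logistic(logit(p_class) + eps_year)``; excluded years get no
    detections.  Detection columns are named ``y<year>``; the release event
    itself is carried by ``release_year`` and is not a detection.

    ``native_rate`` > 0 adds a Poisson stream of native-born individuals per
    year from ``native_start_year`` on, flagged ``native_born=1``; they are
    consumed only by the fertility estimator, never by the mark-recapture
    fit.
    """
    survey_years = sorted(survey_years)
    excluded = frozenset(excluded_years)
    y0, y1 = survey_years[0], survey_years[-1]
    bad = [int(y) for y in schedule["year"].unique() if y < y0 or y > y1]
    if bad:
        raise ValueError(f"schedule years outside survey range: {bad}")

    rng = substream(truth.seed, "capture_histories")
    eps = {
        y: (0.0 if truth.capture_sd_logit == 0
            else rng.normal(0.0, truth.capture_sd_logit))
        for y in survey_years
    }

    def p_detect(age: int, year: int) -> float:
        if year in excluded:
            return 0.0
        mean = truth.capture_mean_young if age < 15 else truth.capture_mean_adult
        if mean <= 0.0:
            return 0.0
        if mean >= 1.0:
            return 1.0
        return float(_logistic(math.log(mean / (1 - mean)) + eps[year]))

    rows = []
    counter = 0
    for _, rec in schedule.sort_values(["year", "site"]).iterrows():
        year, site, count = int(rec["year"]), rec["site"], int(rec["count"])
        for _ in range(count):
            counter += 1
            age0 = int(rng.choice(age_at_release_choices))
            sex = "f" if rng.random() < female_fraction else "m"
            det = {y: 0 for y in survey_years}
            alive = True
            age = age0
            for y in range(year, y1):
                # survive interval y -> y+1
                phi = (truth.survival_release_year if y == year
                       else truth.survival_juvenile if age < 8
                       else truth.survival_adult)
                if rng.random() >= phi:
                    alive = False
                    break
                age += 1
                if (y + 1) in det and rng.random() < p_detect(age, y + 1):
                    det[y + 1] = 1
            rows.append({
                "individual_id": f"rep{counter:05d}",
                "release_year": year,
                "release_site": site,
                "age_at_release": age0,
                "sex": sex,
                "native_born": 0,
                **{f"y{y}": det[y] for y in survey_years},
            })

    if native_rate > 0:
        nat = 0
        for y in range(max(native_start_year, y0), y1 + 1):
            for _ in range(rng.poisson(native_rate)):
                nat += 1
                rows.append({
                    "individual_id": f"nat{nat:05d}",
                    "release_year": y,
                    "release_site": "native",
                    "age_at_release": int(rng.choice((1, 2, 3))),
                    "sex": "f" if rng.random() < female_fraction else "m",
                    "native_born": 1,
                    **{f"y{yy}": 0 for yy in survey_years},
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plot surveys
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_RANGES = {
    "distance_km": (0.0, 6.0),
    "cactus_adult_per_ha": (0.0, 5.0),
    "woody_large_per_100m2": (0.0, 20.0),
}

# Five 20-m-radius circular sub-plots per plot.
PLOT_AREA_HA = 5 * math.pi * 20.0 ** 2 / 1e4


def gen_survey_plots(
    coefs: Mapping[str, float],
    n_plots: int = 96,
    dispersion: float = 1.5,
    seed: int = 0,
    covariate_ranges: Mapping[str, tuple[float, float]] | None = None,
    area_ha: float = PLOT_AREA_HA,
) -> pd.DataFrame:
    """Draw plot covariates and negative-binomial tortoise counts.

    ``coefs`` holds ``intercept`` (log density per hectare at zero
    covariates) and slopes ``b_distance``, ``b_cactus``, ``b_woody`` on the
    raw covariate scale.  Counts have mean ``area * exp(linear predictor)``
    and NB dispersion ``k`` (variance ``mu + mu^2/k``).
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    ranges = dict(DEFAULT_COVARIATE_RANGES)
    if covariate_ranges:
        ranges.update(covariate_ranges)
    rng = substream(seed, "survey_plots")
    dist = rng.uniform(*ranges["distance_km"], n_plots)
    cact = rng.uniform(*ranges["cactus_adult_per_ha"], n_plots)
    woody = rng.uniform(*ranges["woody_large_per_100m2"], n_plots)
    eta = (coefs.get("intercept", 0.0)
           + coefs.get("b_distance", 0.0) * dist
           + coefs.get("b_cactus", 0.0) * cact
           + coefs.get("b_woody", 0.0) * woody)
    mu = area_ha * np.exp(eta)
    p = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p)
    return pd.DataFrame({
        "plot_id": [f"plot{i:03d}" for i in range(n_plots)],
        "tortoise_count": counts.astype(int),
        "area_ha": area_ha,
        "distance_km": dist,
        "cactus_adult_per_ha": cact,
        "cactus_subadult_per_ha": rng.uniform(0.0, 2.0, n_plots),
        "cactus_juvenile_per_ha": rng.uniform(0.0, 8.0, n_plots),
        "woody_large_per_100m2": woody,
        "woody_small_per_100m2": rng.uniform(0.0, 150.0, n_plots),
        "droppings_per_ha": rng.uniform(0.0, 20.0, n_plots),
    })


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------

def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(4 * (n - got) + 8, 2))
        for xy in cand:
            if poly.contains(Point(xy)):
                pts[got] = xy
                got += 1
                if got == n:
                    break
    return pts


def gen_movement_tracks(
    n: int,
    step_model: Mapping[str, object] | None = None,
    range_polygon: Polygon | Sequence[Sequence[float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate annual displacement records inside a range polygon.

    ``step_model`` keys: ``mean_step_m`` (mean displacement length, metres),
    ``sd_step_m``, ``mode`` (``"isotropic"`` or ``"edge_biased"``), and for
    the edge-biased mode ``bias`` in [0, 1] controlling how strongly steps
    point toward the range centroid.  Edge-biased steps are truncated so the
    end point stays inside the polygon, emulating tortoises that do not
    cross the range edge.  Elapsed times are 1-3 years.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = {"mean_step_m": 800.0, "sd_step_m": 300.0, "mode": "isotropic",
             "bias": 0.9}
    if step_model:
        model.update(step_model)
    if range_polygon is None:
        range_polygon = Polygon([(0, 0), (5000, 0), (5000, 4000), (0, 4000)])
    elif not isinstance(range_polygon, Polygon):
        verts = list(range_polygon)
        if len(verts) < 3:
            raise ValueError("range polygon needs at least 3 vertices")
        range_polygon = Polygon(verts)
    if range_polygon.area <= 0:
        raise ValueError("range polygon is degenerate")

    rng = substream(seed, "movement_tracks")
    starts = _sample_in_polygon(range_polygon, n, rng)
    cx, cy = range_polygon.centroid.x, range_polygon.centroid.y
    lengths = np.clip(
        rng.normal(model["mean_step_m"], model["sd_step_m"], n), 0.0, None
    )
    if model["mean_step_m"] == 0:
        lengths[:] = 0.0
    ends = np.empty_like(starts)
    for i, (x0, y0) in enumerate(starts):
        if model["mode"] == "edge_biased":
            to_c = math.atan2(cy - y0, cx - x0)
            theta = to_c + (1 - model["bias"]) * rng.uniform(-math.pi, math.pi)
            # stay inside: never overshoot the centroid
            d_c = math.hypot(cx - x0, cy - y0)
            L = min(lengths[i], 0.8 * d_c)
        else:
            theta = rng.uniform(-math.pi, math.pi)
            L = lengths[i]
        ends[i] = (x0 + L * math.cos(theta), y0 + L * math.sin(theta))
    elapsed = rng.uniform(1.0, 3.0, n)
    start_year = rng.integers(2000, 2003, n)
    classes = rng.choice(["adult_female", "adult_male", "juvenile"], n)
    return pd.DataFrame({
        "individual_id": [f"ind{i:04d}" for i in range(n)],
        "x0": starts[:, 0], "y0": starts[:, 1],
        "x1": ends[:, 0], "y1": ends[:, 1],
        "date0": start_year.astype(float),
        "date1": start_year + elapsed,
        "class": classes,
    })


# ---------------------------------------------------------------------------
# Soil profiles
# ---------------------------------------------------------------------------

def gen_soil_profile(
    end_members: Mapping[str, float] | None = None,
    regime_boundary_depth: float = 40.0,
    mixing_path: Mapping[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    pits: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Two-regime delta-13C depth profiles from a woody/herbaceous mixture.

    Each 10-cm depth gets ``delta = f*woody + (1-f)*herbaceous + noise``
    where the woody fraction ``f`` follows the configured path: linear from
    ``surface`` at depth 0 to ``at_boundary`` at the regime boundary, then
    constant ``deep`` below it.  Defaults emulate a recent shift toward
    woody dominance above ~40 cm (about 510 years BP) over a flat older
    regime.
    """
    em = {"woody": -28.0, "herbaceous": -14.5}
    if end_members:
        em.update(end_members)
    path = {"surface": 0.8, "at_boundary": 0.25, "deep": 0.25}
    if mixing_path:
        path.update(mixing_path)
    pits = dict(pits) if pits else {"caco": 110.0, "gardner": 80.0}
    rng = substream(seed, "soil_profile")
    rows = []
    for pit, max_depth in pits.items():
        for depth in np.arange(10.0, max_depth + 1e-9, 10.0):
            if depth <= regime_boundary_depth:
                f = path["surface"] + (path["at_boundary"] - path["surface"]) * (
                    depth / regime_boundary_depth
                )
            else:
                f = path["deep"]
            f = min(1.0, max(0.0, f))
            val = f * em["woody"] + (1 - f) * em["herbaceous"]
            if noise_sd > 0:
                val += rng.normal(0.0, noise_sd)
            rows.append({"pit_id": pit, "depth_cm": float(depth),
                         "delta13c_permil": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cactus census
# ---------------------------------------------------------------------------

def gen_cactus_census(
    stage_probs: Mapping[str, Sequence[float]] | None = None,
    totals: Mapping[str, int] | Sequence[int] = (315, 396),
    stages: Sequence[str] = ("juvenile_subadult", "adult"),
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial stage counts for two census periods.

    Default totals are the macroplot census sizes (315 then 396); default
    stage probabilities are the observed stage fractions of each census.
    """
    if isinstance(totals, Mapping):
        periods = {str(k): int(v) for k, v in totals.items()}
    else:
        periods = {p: int(t) for p, t in zip(("2004", "2014"), totals)}
    if any(t < 0 for t in periods.values()):
        raise ValueError("census totals must be non-negative")
    probs = {"2004": (194 / 315, 121 / 315), "2014": (266 / 396, 130 / 396)}
    if stage_probs:
        probs.update({str(k): tuple(v) for k, v in stage_probs.items()})
    rng = substream(seed, "cactus_census")
    rows = []
    for period, total in periods.items():
        p = np.asarray(probs[period], dtype=float)
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"stage probabilities for {period} must sum to 1")
        if total == 0:
            continue
        counts = rng.multinomial(total, p)
        rows += [{"period": period, "stage": s, "count": int(c)}
                 for s, c in zip(stages, counts)]
    return pd.DataFrame(rows, columns=["period", "stage", "count"])


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: Mapping[str, Mapping] | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate every input table from one nested config and one seed.

    Config sections (all optional): ``releases``, ``captures``, ``plots``,
    ``movement``, ``soil``, ``census`` with keys matching the corresponding
    generator's signature.
    """
    cfg = {k: dict(v) for k, v in (config or {}).items()}
    schedule = gen_release_schedule(seed=seed, **cfg.get("releases", {}))
    cap_cfg = cfg.get("captures", {})
    truth_kwargs = cap_cfg.pop("truth", {})
    truth = SimulationTruth(seed=seed, **truth_kwargs)
    captures = gen_capture_histories(truth, schedule, **cap_cfg)
    plots_cfg = cfg.get("plots", {})
    coefs = plots_cfg.pop("coefs", {"intercept": 0.5, "b_distance": -0.8,
                                    "b_cactus": 0.25, "b_woody": -0.05})
    plots = gen_survey_plots(coefs, seed=seed, **plots_cfg)
    move_cfg = cfg.get("movement", {})
    movements = gen_movement_tracks(move_cfg.pop("n", 150), seed=seed, **move_cfg)
    soil = gen_soil_profile(seed=seed, **cfg.get("soil", {}))
    census = gen_cactus_census(seed=seed, **cfg.get("census", {}))
    return SyntheticDataset(
        capture_table=captures,
        plot_surveys=plots,
        movement_records=movements,
        soil_samples=soil,
        cactus_census=census,
        release_schedule=schedule,
    )
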