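"""Open-population mark-recapture analysis for a population founded by
known releases.

The model is a Cormack-Jolly-Seber variant: apparent survival is
age-structured (a dedicated year-of-release rate for the first interval
after release, then a juvenile rate below age 8 and an adult rate above),
with adult survival varying by 4-year block, juvenile survival by 2-year
block, and year-of-release survival by release year.  Capture probability
has separate means for tortoises younger than 15 and 15+, with inter-annual
variation modeled as a logit-normal random effect shared by both classes.
Priors are uniform: U(0,1) on every probability and U(0,5) on the
logit-scale capture SD.

Instead of tracking each individual's latent alive/dead state, the
likelihood is the classical multinomial over the m-array (counts of first
recaptures by cohort), which marginalizes the latent states exactly;
abundance of released survivors is then recovered by propagating each
release cohort through the posterior survival rates.

Survey years with no recapture effort are handled by fixing capture
probability to zero for those occasions, so intervals bridge across them
with compounded survival.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._mcmc import adaptive_metropolis, gelman_rubin_psrf
from ._rand import substream
from .synthetic import DEFAULT_EXCLUDED_YEARS

__all__ = [
    "CjsConfig",
    "MArray",
    "CjsPosterior",
    "AbundanceEstimate",
    "filter_growth_records",
    "build_m_array",
    "cjs_log_likelihood",
    "fit_cjs_mcmc",
    "fit_all_regions",
    "derive_abundance",
    "gelman_rubin",
]

REGION_OF_SITE = {"tunas": "tunas_caco", "caco": "tunas_caco",
                  "tunas_caco": "tunas_caco", "gardner": "gardner"}


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Growth-record filtering
# ---------------------------------------------------------------------------

def filter_growth_records(
    records: pd.DataFrame,
    max_interval_years: float = 3.0,
    trim_fraction: float = 0.025,
) -> pd.DataFrame:
    """Apply the growth-record screening rules.

    Recapture intervals longer than ``max_interval_years`` are dropped
    first; then the lowest and highest ``trim_fraction`` of the annualized
    growth-rate distribution are removed (guarding against field-recording
    anomalies).  Trimming is a sort-and-slice of the middle
    ``1 - 2*trim_fraction``: with ties at the cut, record order decides
    which duplicates are kept, so ties sit on the retained side.

    ``records`` needs columns ``interval_years`` and ``growth_cm_per_year``.
    """
    if records.empty:
        return records.copy()
    keep = records[records["interval_years"] <= max_interval_years]
    n = len(keep)
    k = int(math.floor(trim_fraction * n))
    if k == 0:
        return keep.copy()
    order = np.argsort(keep["growth_cm_per_year"].to_numpy(), kind="stable")
    retained = np.sort(order[k:n - k])
    return keep.iloc[retained].copy()


# ---------------------------------------------------------------------------
# m-array
# ---------------------------------------------------------------------------

@dataclass
class MArray:
    """Sufficient statistic for the CJS likelihood.

    Each row is a cohort of individuals entering the at-risk pool at the
    same occasion, with the same age and the same newly-released status
    (a detection re-enters the individual as a re-encounter cohort).
    ``m[c, j]`` counts individuals of cohort ``c`` first recaptured at
    occasion ``j``; ``never[c]`` counts those never seen again.
    """

    occasions: np.ndarray          # calendar years, consecutive
    excluded: frozenset[int]       # occasions (years) with no survey effort
    cohort_occ: np.ndarray         # (C,) entry occasion index
    cohort_age: np.ndarray         # (C,) age at entry
    cohort_new: np.ndarray         # (C,) bool, newly released
    m: np.ndarray                  # (C, T) first-recapture counts
    never: np.ndarray              # (C,)

    @property
    def released(self) -> np.ndarray:
        return self.m.sum(axis=1) + self.never

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)


def _detection_years(table: pd.DataFrame) -> list[int]:
    return sorted(int(c[1:]) for c in table.columns
                  if c.startswith("y") and c[1:].isdigit())


def build_m_array(
    table: pd.DataFrame,
    stratum: str | None = None,
    excluded_years: Sequence[int] | frozenset[int] = DEFAULT_EXCLUDED_YEARS,
    include_native: bool = False,
) -> MArray:
    """Tabulate the m-array from a capture table.

    ``stratum`` restricts to a release region (``"tunas_caco"`` pools the
    two central sites, ``"gardner"`` is separate); ``None`` keeps all.
    Native-born individuals are excluded unless ``include_native``.
    Detections before release, or in excluded survey years, are rejected.
    """
    years = _detection_years(table)
    if not years:
        raise ValueError("no detection columns (expected y<year>)")
    occasions = np.arange(years[0], years[-1] + 1)
    occ_index = {int(y): i for i, y in enumerate(occasions)}
    excluded = frozenset(int(y) for y in excluded_years)
    T = len(occasions)

    df = table
    if not include_native and "native_born" in df.columns:
        df = df[df["native_born"] == 0]
    if stratum is not None:
        region = df["release_site"].map(REGION_OF_SITE)
        df = df[region == stratum]

    det_cols = [f"y{y}" for y in years]
    det = df[det_cols].to_numpy(dtype=int)
    rel_year = df["release_year"].to_numpy(dtype=int)
    rel_age = df["age_at_release"].to_numpy(dtype=int)
    ids = df["individual_id"].to_numpy()

    cohorts: dict[tuple[int, int, bool], int] = {}
    rows_occ, rows_age, rows_new, m_rows, never_rows = [], [], [], [], []

    def row_for(occ: int, age: int, new: bool) -> int:
        key = (occ, age, new)
        if key not in cohorts:
            cohorts[key] = len(rows_occ)
            rows_occ.append(occ)
            rows_age.append(age)
            rows_new.append(new)
            m_rows.append(np.zeros(T, dtype=int))
            never_rows.append(0)
        return cohorts[key]

    for i in range(len(df)):
        r_occ = occ_index.get(rel_year[i])
        if r_occ is None:
            raise ValueError(f"release year outside survey range for {ids[i]}")
        hits = [occ_index[years[j]] for j in np.nonzero(det[i])[0]]
        for h in hits:
            if h < r_occ or (h == r_occ):
                if occasions[h] < rel_year[i]:
                    raise ValueError(
                        f"detection before release for individual {ids[i]}")
            if int(occasions[h]) in excluded:
                raise ValueError(
                    f"detection in excluded year {occasions[h]} for {ids[i]}")
        hits = [h for h in hits if h > r_occ]
        entry_occ, entry_age, new = r_occ, rel_age[i], True
        for h in hits:
            c = row_for(entry_occ, entry_age, new)
            m_rows[c][h] += 1
            entry_age = entry_age + (h - entry_occ)
            entry_occ, new = h, False
        c = row_for(entry_occ, entry_age, new)
        never_rows[c] += 1

    return MArray(
        occasions=occasions,
        excluded=excluded,
        cohort_occ=np.asarray(rows_occ, dtype=int),
        cohort_age=np.asarray(rows_age, dtype=int),
        cohort_new=np.asarray(rows_new, dtype=bool),
        m=np.asarray(m_rows, dtype=int).reshape(len(rows_occ), T),
        never=np.asarray(never_rows, dtype=int),
    )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class CjsConfig:
    """Model structure and sampler settings.

    Defaults mirror the published analysis: 4-year adult survival blocks,
    2-year juvenile blocks and per-release-year first-interval survival,
    all anchored at the first survey year; age thresholds of 8 (survival)
    and 15 (capture); 5,000 burn-in iterations plus 10,000 kept iterations
    thinned by 10, on 3 chains.
    """

    adult_block_years: int = 4
    juvenile_block_years: int = 2
    juvenile_age_max: int = 8
    capture_age_adult: int = 15
    excluded_years: frozenset[int] = DEFAULT_EXCLUDED_YEARS
    chains: int = 3
    burn_in: int = 5000
    iterations: int = 10000
    thin: int = 10
    seed: int = 0
    sigma_p_max: float = 5.0


class CjsStructure:
    """Precomputed index maps from m-array rows to model parameters.

    Rows whose probability vectors are identical (same entry occasion,
    same capped age, same release status) are merged; ages are capped at
    the capture adult threshold since survival and capture classes are
    constant beyond it.
    """

    def __init__(self, marray: MArray, config: CjsConfig):
        self.config = config
        T = marray.n_occasions
        cap = max(config.juvenile_age_max, config.capture_age_adult)

        merged: dict[tuple[int, int, bool], int] = {}
        occ, age, new, m_rows, nev = [], [], [], [], []
        for c in range(len(marray.cohort_occ)):
            key = (int(marray.cohort_occ[c]),
                   int(min(marray.cohort_age[c], cap)),
                   bool(marray.cohort_new[c]))
            if key not in merged:
                merged[key] = len(occ)
                occ.append(key[0]); age.append(key[1]); new.append(key[2])
                m_rows.append(np.zeros(T, dtype=int)); nev.append(0)
            r = merged[key]
            m_rows[r] += marray.m[c]
            nev[r] += int(marray.never[c])
        self.occ = np.asarray(occ)
        self.age = np.asarray(age)
        self.new = np.asarray(new)
        self.m = np.asarray(m_rows).reshape(len(occ), T)
        self.never = np.asarray(nev)
        self.T = T
        self.occasions = marray.occasions
        C = len(occ)

        n_int = T - 1
        jw, aw = config.juvenile_block_years, config.adult_block_years
        self.n_jb = max(1, n_int // jw)
        self.n_ab = max(1, n_int // aw)
        self.release_occs = sorted({int(o) for o, isnew in zip(self.occ, self.new)
                                    if isnew})
        self.r_index = {o: i for i, o in enumerate(self.release_occs)}
        n_R = len(self.release_occs)
        self.n_R = n_R
        self.n_surv = n_R + self.n_jb + self.n_ab

        sidx = np.full((C, n_int), -1, dtype=int)
        for c in range(C):
            for k in range(self.occ[c], n_int):
                a = self.age[c] + (k - self.occ[c])
                if self.new[c] and k == self.occ[c]:
                    sidx[c, k] = self.r_index[int(self.occ[c])]
                elif a < config.juvenile_age_max:
                    sidx[c, k] = n_R + min(k // jw, self.n_jb - 1)
                else:
                    sidx[c, k] = n_R + self.n_jb + min(k // aw, self.n_ab - 1)
        self.sidx = sidx
        self.svalid = sidx >= 0

        cls = np.zeros((C, T), dtype=int)
        cvalid = np.zeros((C, T), dtype=bool)
        for c in range(C):
            for j in range(self.occ[c] + 1, T):
                a = self.age[c] + (j - self.occ[c])
                cls[c, j] = 0 if a < config.capture_age_adult else 1
                cvalid[c, j] = True
        self.cls = cls
        self.cvalid = cvalid
        self.excluded_mask = np.array(
            [int(y) in marray.excluded for y in marray.occasions])
        # occasions where a recapture could occur and effort existed
        self.active_occ = np.array(
            [j for j in range(1, T) if not self.excluded_mask[j]], dtype=int)

        self._surv_cache: tuple | None = None
        self._cap_cache: tuple | None = None

        # exposure weights: individuals entering each survival parameter's
        # intervals, used for the class-level weighted survival summary
        w = np.zeros(self.n_surv)
        rel = self.m.sum(axis=1) + self.never
        for c in range(C):
            for k in range(self.occ[c], n_int):
                w[sidx[c, k]] += rel[c]
        self.exposure = w

    # -- core multinomial log-likelihood -----------------------------------
    # The survival-dependent and capture-dependent halves of the cell
    # log-probabilities are cached separately: blocked Metropolis proposals
    # change only one of them at a time.

    def _surv_term(self, surv: np.ndarray) -> np.ndarray:
        if self._surv_cache is not None and np.array_equal(surv, self._surv_cache[0]):
            return self._surv_cache[1]
        C = self.m.shape[0]
        with np.errstate(divide="ignore"):
            log_phi = np.where(self.svalid,
                               np.log(surv)[np.clip(self.sidx, 0, None)], 0.0)
        cum_phi = np.cumsum(log_phi, axis=1)            # (C, T-1), sums k <= col
        term = np.concatenate([np.zeros((C, 1)), cum_phi], axis=1)
        self._surv_cache = (surv.copy(), term)
        return term

    def _capture_term(self, p_occ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._cap_cache is not None and np.array_equal(p_occ, self._cap_cache[0]):
            return self._cap_cache[1], self._cap_cache[2]
        C, T = self.m.shape
        with np.errstate(divide="ignore"):
            log_1mp_occ = np.log1p(-np.clip(p_occ, 0.0, 1.0 - 1e-15))
            log_p_occ = np.log(np.clip(p_occ, 1e-300, 1.0))
        j = np.arange(T)[None, :]
        l1mp = np.where(self.cvalid, log_1mp_occ[self.cls, j], 0.0)
        cum_1mp = np.cumsum(l1mp, axis=1)               # (C, T), sums m <= col
        prev = np.concatenate([np.zeros((C, 1)), cum_1mp[:, :-1]], axis=1)
        term = prev + log_p_occ[self.cls, j]
        valid = (j > self.occ[:, None]) & ~self.excluded_mask[None, :] \
            & (p_occ[self.cls, j] > 0)
        self._cap_cache = (p_occ.copy(), term, valid)
        return term, valid

    def log_likelihood(self, surv: np.ndarray, p_occ: np.ndarray) -> float:
        """``surv``: (n_surv,) probabilities; ``p_occ``: (2, T) capture
        probability per class and occasion (zero where no effort).

        Cell log-probability for first recapture at occasion j > entry is
        sum_{k=entry}^{j-1} log phi + sum_{m=entry+1}^{j-1} log(1-p)
        + log p_j; entries before the cohort's entry are structurally zero
        in the masked cumulative sums.
        """
        surv_term = self._surv_term(np.asarray(surv, dtype=float))
        cap_term, valid = self._capture_term(p_occ)
        logcell = surv_term + cap_term
        cell = np.where(valid, np.exp(logcell), 0.0)
        never_p = np.clip(1.0 - cell.sum(axis=1), 1e-300, 1.0)
        if np.any((self.m > 0) & ~valid):
            return -np.inf
        contrib = self.m * np.where((self.m > 0) & valid, logcell, 0.0)
        return float(contrib.sum() + np.dot(self.never, np.log(never_p)))


def _p_occ_from(structure: CjsStructure, p_young: float, p_adult: float,
                eps: Mapping[int, float] | np.ndarray | None) -> np.ndarray:
    T = structure.T
    p_occ = np.zeros((2, T))
    eps_map = {}
    if eps is not None:
        if isinstance(eps, Mapping):
            eps_map = {int(k): float(v) for k, v in eps.items()}
        else:
            eps_map = {int(j): float(e)
                       for j, e in zip(structure.active_occ, np.asarray(eps))}
    for j in range(1, T):
        if structure.excluded_mask[j]:
            continue
        e = eps_map.get(j, eps_map.get(int(structure.occasions[j]), 0.0))
        for cls, p in ((0, p_young), (1, p_adult)):
            if p <= 0.0:
                p_occ[cls, j] = 0.0
            elif p >= 1.0:
                p_occ[cls, j] = 1.0
            else:
                p_occ[cls, j] = _logistic(_logit(p) + e)
    return p_occ


def cjs_log_likelihood(
    params: Mapping[str, object],
    marray: MArray,
    config: CjsConfig | None = None,
) -> float:
    """Multinomial m-array log-likelihood at a parameter point.

    ``params`` keys: ``phi_release`` (scalar, or mapping calendar year ->
    value), ``phi_juvenile`` and ``phi_adult`` (scalar or per-block array),
    ``p_young``, ``p_adult`` (scalars), optional ``eps`` (per active
    occasion).  Probabilities outside [0, 1] are rejected.
    """
    config = config or CjsConfig()
    st = CjsStructure(marray, config)
    surv = np.empty(st.n_surv)

    def fill(vals, start, count, name):
        arr = np.asarray(vals, dtype=float)
        if arr.ndim == 0:
            arr = np.full(count, float(arr))
        if arr.size != count:
            raise ValueError(f"{name} needs {count} values, got {arr.size}")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} outside [0, 1]")
        surv[start:start + count] = arr

    pr = params.get("phi_release", 1.0)
    if isinstance(pr, Mapping):
        arr = [pr[int(st.occasions[o])] for o in st.release_occs]
        fill(arr, 0, st.n_R, "phi_release")
    else:
        fill(pr, 0, st.n_R, "phi_release")
    fill(params.get("phi_juvenile", 1.0), st.n_R, st.n_jb, "phi_juvenile")
    fill(params.get("phi_adult", 1.0), st.n_R + st.n_jb, st.n_ab, "phi_adult")
    for key in ("p_young", "p_adult"):
        v = float(params.get(key, 1.0))
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{key} outside [0, 1]")
    p_occ = _p_occ_from(st, float(params.get("p_young", 1.0)),
                        float(params.get("p_adult", 1.0)), params.get("eps"))
    return st.log_likelihood(surv, p_occ)


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class CjsPosterior:
    """Posterior draws (chains concatenated) plus convergence summaries."""

    occasions: np.ndarray
    release_years: list[int]
    phi_release: np.ndarray     # (n, n_R)
    phi_juvenile: np.ndarray    # (n, n_jb)
    phi_adult: np.ndarray       # (n, n_ab)
    p_young: np.ndarray
    p_adult: np.ndarray
    sigma_p: np.ndarray
    eps: np.ndarray             # (n, n_eps)
    active_occasions: np.ndarray
    rhat: dict[str, np.ndarray]
    exposure: dict[str, np.ndarray]
    config: CjsConfig
    inestimable: bool = False

    @property
    def n_draws(self) -> int:
        return len(self.p_young)

    def mean_survival(self, which: str) -> np.ndarray:
        """Exposure-weighted class-level survival, one value per draw.

        Blocks are weighted by the number of individuals at risk in the
        intervals they govern, so data-free blocks (posterior = prior) do
        not dilute the class-level estimate.
        """
        draws = {"adult": self.phi_adult, "juvenile": self.phi_juvenile,
                 "release": self.phi_release}[which]
        w = self.exposure[which].astype(float)
        if w.sum() == 0:
            w = np.ones_like(w)
        return draws @ (w / w.sum())

    def summary(self) -> pd.DataFrame:
        rows = []

        def add(name, draws, rhat=None):
            draws = np.atleast_2d(draws.T).T
            for i in range(draws.shape[1]):
                label = name if draws.shape[1] == 1 else f"{name}[{i}]"
                q = np.percentile(draws[:, i], [2.5, 97.5])
                rows.append({"parameter": label,
                             "mean": draws[:, i].mean(),
                             "q2.5": q[0], "q97.5": q[1],
                             "rhat": (np.atleast_1d(rhat)[i]
                                      if rhat is not None else np.nan)})

        add("phi_release", self.phi_release, self.rhat.get("phi_release"))
        add("phi_juvenile", self.phi_juvenile, self.rhat.get("phi_juvenile"))
        add("phi_adult", self.phi_adult, self.rhat.get("phi_adult"))
        add("p_young", self.p_young, self.rhat.get("p_young"))
        add("p_adult", self.p_adult, self.rhat.get("p_adult"))
        add("sigma_p", self.sigma_p, self.rhat.get("sigma_p"))
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        cols = {}
        for i, y in enumerate(self.release_years):
            cols[f"phi_release_{y}"] = self.phi_release[:, i]
        for i in range(self.phi_juvenile.shape[1]):
            cols[f"phi_juvenile_b{i}"] = self.phi_juvenile[:, i]
        for i in range(self.phi_adult.shape[1]):
            cols[f"phi_adult_b{i}"] = self.phi_adult[:, i]
        cols["p_young"] = self.p_young
        cols["p_adult"] = self.p_adult
        cols["sigma_p"] = self.sigma_p
        return pd.DataFrame(cols)

    def temporal_sd_logit(self, which: str = "adult") -> float:
        """Posterior-mean SD of block survival on the logit scale; feeds the
        projection model's annual survival deviations."""
        draws = {"adult": self.phi_adult, "juvenile": self.phi_juvenile}[which]
        w = self.exposure[which] > 0
        if w.sum() < 2:
            return 0.0
        x = _logit(np.clip(draws[:, w], 1e-9, 1 - 1e-9))
        return float(np.mean(np.std(x, axis=1, ddof=1)))


# ---------------------------------------------------------------------------
# MCMC fit
# ---------------------------------------------------------------------------

def fit_cjs_mcmc(
    table: pd.DataFrame,
    config: CjsConfig | None = None,
    stratum: str | None = None,
) -> CjsPosterior:
    """Fit the CJS model by blocked adaptive Metropolis.

    Parameters are sampled on the logit scale (log for sigma_p) with the
    Jacobian of the uniform priors included; the annual capture random
    effects are sampled jointly with their N(0, sigma_p^2) prior.  Chains
    are combined after burn-in and thinning; the Gelman-Rubin diagnostic is
    reported per parameter.
    """
    config = config or CjsConfig()
    marray = build_m_array(table, stratum=stratum,
                           excluded_years=config.excluded_years)
    st = CjsStructure(marray, config)
    if st.m.sum() == 0:
        warnings.warn("no recaptures: survival and capture probability are "
                      "inestimable; posterior will echo the prior")
    nS = st.n_surv
    nE = len(st.active_occ)
    d = nS + 2 + 1 + nE
    i_p = nS
    i_sig = nS + 2
    i_eps = nS + 3
    sig_max = config.sigma_p_max

    def log_post(x: np.ndarray) -> float:
        logit_surv = x[:nS]
        surv = _logistic(logit_surv)
        p_young, p_adult = _logistic(x[i_p]), _logistic(x[i_p + 1])
        sigma = math.exp(x[i_sig])
        if sigma > sig_max:
            return -np.inf
        eps = x[i_eps:]
        p_occ = np.zeros((2, st.T))
        pa = _logistic(np.array([_logit(p_young), _logit(p_adult)])[:, None]
                       + eps[None, :])
        p_occ[:, st.active_occ] = pa
        ll = st.log_likelihood(surv, p_occ)
        # U(0,1) priors via logit Jacobian; U(0,5) on sigma via log Jacobian
        with np.errstate(divide="ignore"):
            jac = np.sum(np.log(surv) + np.log1p(-surv))
        jac += math.log(p_young * (1 - p_young) + 1e-300)
        jac += math.log(p_adult * (1 - p_adult) + 1e-300)
        jac += x[i_sig]
        lp_eps = -0.5 * np.sum((eps / sigma) ** 2) - nE * math.log(sigma)
        return ll + jac + lp_eps

    # moderate block sizes keep per-coordinate mixing reasonable without
    # paying one likelihood evaluation per parameter
    blocks = [np.arange(s, min(s + 12, nS)) for s in range(0, nS, 12)]
    blocks.append(np.arange(i_p, i_eps))
    blocks += [np.arange(s, min(s + 15, d)) for s in range(i_eps, d, 15)]
    chains_out = []
    for ch in range(config.chains):
        rng = substream(config.seed, "cjs_fit", stratum, ch)
        x0 = np.zeros(d)
        x0[:nS] = _logit(0.9) + rng.normal(0, 0.1, nS)
        x0[i_p:i_p + 2] = _logit(0.3) + rng.normal(0, 0.1, 2)
        x0[i_sig] = math.log(0.3) + rng.normal(0, 0.1)
        x0[i_eps:] = rng.normal(0, 0.05, nE)
        kept, _ = adaptive_metropolis(
            log_post, x0, config.burn_in, config.iterations, config.thin, rng,
            blocks=blocks)
        chains_out.append(kept)

    n_per = min(len(k) for k in chains_out)
    stacked = np.stack([k[:n_per] for k in chains_out])  # (m, n, d)
    if config.chains >= 2 and n_per >= 10:
        rh = gelman_rubin_psrf(stacked)
    else:
        rh = np.full(d, np.nan)
    draws = stacked.reshape(-1, d)

    surv = _logistic(draws[:, :nS])
    rhat = {
        "phi_release": rh[:st.n_R],
        "phi_juvenile": rh[st.n_R:st.n_R + st.n_jb],
        "phi_adult": rh[st.n_R + st.n_jb:nS],
        "p_young": rh[i_p:i_p + 1],
        "p_adult": rh[i_p + 1:i_p + 2],
        "sigma_p": rh[i_sig:i_sig + 1],
    }
    return CjsPosterior(
        occasions=st.occasions,
        release_years=[int(st.occasions[o]) for o in st.release_occs],
        phi_release=surv[:, :st.n_R],
        phi_juvenile=surv[:, st.n_R:st.n_R + st.n_jb],
        phi_adult=surv[:, st.n_R + st.n_jb:],
        p_young=_logistic(draws[:, i_p]),
        p_adult=_logistic(draws[:, i_p + 1]),
        sigma_p=np.exp(draws[:, i_sig]),
        eps=draws[:, i_eps:],
        active_occasions=st.occasions[st.active_occ],
        rhat=rhat,
        exposure={
            "release": st.exposure[:st.n_R],
            "juvenile": st.exposure[st.n_R:st.n_R + st.n_jb],
            "adult": st.exposure[st.n_R + st.n_jb:],
        },
        config=config,
        inestimable=bool(st.m.sum() == 0),
    )


def fit_all_regions(table: pd.DataFrame, config: CjsConfig | None = None
                    ) -> dict[str, CjsPosterior]:
    """Fit each release region separately (the central Tunas+Caco sites are
    pooled; Gardner Bay is its own stratum)."""
    out = {}
    regions = sorted({REGION_OF_SITE[s] for s in table["release_site"].unique()
                      if s in REGION_OF_SITE})
    for region in regions:
        out[region] = fit_cjs_mcmc(table, config, stratum=region)
    return out


# ---------------------------------------------------------------------------
# Abundance
# ---------------------------------------------------------------------------

@dataclass
class AbundanceEstimate:
    """Expected released survivors per region and year, one row of draws per
    posterior sample."""

    years: np.ndarray
    draws: dict[str, np.ndarray]  # region -> (n_draws, n_years)

    def summary(self) -> pd.DataFrame:
        rows = []
        for region, arr in self.draws.items():
            q = np.percentile(arr, [2.5, 97.5], axis=0)
            for i, y in enumerate(self.years):
                rows.append({"year": int(y), "region": region,
                             "mean": arr[:, i].mean(),
                             "q2.5": q[0, i], "q97.5": q[1, i]})
        return pd.DataFrame(rows)


def derive_abundance(
    posterior: CjsPosterior,
    schedule: pd.DataFrame,
    release_age: int = 4,
    config: CjsConfig | None = None,
) -> AbundanceEstimate:
    """Propagate release cohorts through posterior survival to annual
    expected abundance of released survivors per region.

    Each cohort passes through its year-of-release survival over the first
    interval, then the juvenile or adult block rate appropriate to its age.
    Abundance in the release year equals the cohort size, so draws never
    exceed cumulative releases.
    """
    config = config or posterior.config
    occ = posterior.occasions
    y0, y1 = int(occ[0]), int(occ[-1])
    bad = [int(y) for y in schedule["year"].unique() if y < y0 or y > y1]
    if bad:
        raise ValueError(f"schedule years {bad} outside posterior years "
                         f"{y0}-{y1}")
    n = posterior.n_draws
    T = len(occ)
    jw, aw = config.juvenile_block_years, config.adult_block_years
    n_jb = posterior.phi_juvenile.shape[1]
    n_ab = posterior.phi_adult.shape[1]
    rel_idx = {y: i for i, y in enumerate(posterior.release_years)}
    phi_r_mean = posterior.phi_release.mean(axis=1) if posterior.phi_release.size \
        else np.ones(n)

    regions: dict[str, np.ndarray] = {}
    for _, rec in schedule.iterrows():
        year, site, count = int(rec["year"]), rec["site"], float(rec["count"])
        if count == 0:
            continue
        region = REGION_OF_SITE.get(site, site)
        arr = regions.setdefault(region, np.zeros((n, T)))
        t0 = year - y0
        alive = np.full(n, count)
        arr[:, t0] += alive
        for t in range(t0, T - 1):
            age = release_age + (t - t0)
            if t == t0:
                phi = (posterior.phi_release[:, rel_idx[year]]
                       if year in rel_idx else phi_r_mean)
            elif age < config.juvenile_age_max:
                phi = posterior.phi_juvenile[:, min(t // jw, n_jb - 1)]
            else:
                phi = posterior.phi_adult[:, min(t // aw, n_ab - 1)]
            alive = alive * phi
            arr[:, t + 1] += alive
    return AbundanceEstimate(years=occ.copy(), draws=regions)


def gelman_rubin(chains) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``chains``: array-like of shape (m, n) or (m, n, d), m >= 2 chains of
    equal length n >= 10.  Values near 1 indicate convergence.
    """
    return gelman_rubin_psrf(np.asarray(chains, dtype=float))
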