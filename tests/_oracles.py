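"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: the
likelihood oracle enumerates latent alive/dead paths individual by
individual, and the hull oracle tests each point for extremality against
the hull of the remaining points.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPoint, Point


def latent_path_loglik(table, params, survey_years, excluded=(),
                       juvenile_age_max=8, capture_age_adult=15) -> float:
    """Exact CJS log-likelihood by summing over every individual's possible
    death time.

    ``params``: scalars phi_release, phi_juvenile, phi_adult, p_young,
    p_adult.  Capture probability is zero in excluded years.
    """
    years = sorted(survey_years)
    T = len(years)
    excluded = set(excluded)

    def phi(age, first):
        if first:
            return params["phi_release"]
        return (params["phi_juvenile"] if age < juvenile_age_max
                else params["phi_adult"])

    def p(age, year):
        if year in excluded:
            return 0.0
        return (params["p_young"] if age < capture_age_adult
                else params["p_adult"])

    total = 0.0
    for _, row in table.iterrows():
        e = years.index(int(row["release_year"]))
        age0 = int(row["age_at_release"])
        y = [int(row[f"y{yr}"]) for yr in years]
        det_occ = [j for j in range(T) if y[j] == 1]
        last = max(det_occ) if det_occ else e
        prob = 0.0
        # alive through occasion k, death in interval (k, k+1) (or beyond
        # the final occasion when k == T-1)
        for k in range(last, T):
            path = 1.0
            for i in range(e, min(k, T - 1)):
                path *= phi(age0 + (i - e), i == e)
            if k < T - 1:
                path *= 1.0 - phi(age0 + (k - e), k == e)
            for j in range(e + 1, k + 1):
                pj = p(age0 + (j - e), years[j])
                path *= pj if y[j] else (1.0 - pj)
            prob += path
        if prob <= 0:
            return -np.inf
        total += np.log(prob)
    return float(total)


def brute_force_hull_vertices(points: np.ndarray) -> set[tuple[float, float]]:
    """A point is a hull vertex iff it is not covered by the hull of the
    other points."""
    pts = [tuple(map(float, p)) for p in np.asarray(points).reshape(-1, 2)]
    unique = sorted(set(pts))
    out = set()
    for p in unique:
        others = [q for q in unique if q != p]
        if len(others) < 3:
            out.add(p)
            continue
        hull = MultiPoint(others).convex_hull.buffer(1e-9)
        if not hull.covers(Point(p)):
            out.add(p)
    return out
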