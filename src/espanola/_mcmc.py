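"""Blocked adaptive random-walk Metropolis, shared by the mark-recapture
and habitat-regression samplers.

Proposals are Gaussian per block with per-coordinate standard deviations
taken from a running (Welford) estimate of the posterior spread and a
per-block scalar scale tuned toward a target acceptance rate during
burn-in.  Adaptation stops at the end of burn-in, so the kept draws come
from a fixed Markov kernel.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_burn: int,
    n_keep_iters: int,
    thin: int,
    rng: np.random.Generator,
    blocks: Sequence[np.ndarray] | None = None,
    init_scale: float = 0.2,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one chain; return (kept draws, per-block acceptance rates).

    ``n_keep_iters`` post-burn-in iterations are run and every ``thin``-th
    state is stored.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    if blocks is None:
        blocks = [np.arange(d)]
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial state has non-finite log-posterior")

    log_scales = np.full(len(blocks), np.log(init_scale))
    mean = x.copy()
    m2 = np.full(d, 1e-4)
    n_seen = 1
    accepts = np.zeros(len(blocks))
    tries = np.zeros(len(blocks))
    kept = np.empty(((n_keep_iters + thin - 1) // thin, d))
    k = 0

    total = n_burn + n_keep_iters
    for it in range(total):
        adapting = it < n_burn
        for b, idx in enumerate(blocks):
            sd = np.exp(log_scales[b]) * np.sqrt(m2 / max(n_seen - 1, 1))[idx]
            sd = np.maximum(sd, 1e-3)
            prop = x.copy()
            prop[idx] = x[idx] + rng.normal(size=idx.size) * sd
            lpp = log_post(prop)
            acc = np.log(rng.random()) < lpp - lp
            if acc:
                x, lp = prop, lpp
            tries[b] += 1
            accepts[b] += acc
            if adapting:
                log_scales[b] += (float(acc) - target_accept) / (1 + it) ** 0.55
        if adapting:
            n_seen += 1
            delta = x - mean
            mean += delta / n_seen
            m2 += delta * (x - mean)
        else:
            j = it - n_burn
            if j % thin == 0:
                kept[k] = x
                k += 1
    return kept[:k], accepts / np.maximum(tries, 1)


def gelman_rubin_psrf(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor for an (m, n, d) or (m, n) array."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    chain_means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    v_hat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(v_hat / w)
    r = np.where(w <= 1e-300, 1.0, r)
    return r if d > 1 else r  # always 1-D of length d
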