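"""Largest Lyapunov exponent by the Rosenstein nearest-neighbor method.

The signal is delay-embedded (dimension ``m``, delay ``tau``); each embedded
point is matched to its nearest neighbor outside a Theiler exclusion window;
the mean log distance between the matched trajectories is tracked over time,
and the exponent is the least-squares slope of that divergence curve over an
initial fit window, in units of 1/step (per sample).

Chaotic segments give a positive slope (the logistic map at r=4 gives
ln 2 ~ 0.693 per step); periodic or quasi-periodic segments give a slope
near zero or below.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

MIN_SAMPLES = 50


def autocorr_delay(x: np.ndarray, max_lag: int | None = None) -> int:
    """Embedding delay = first zero crossing of the autocorrelation."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    max_lag = max_lag or n // 2
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    for lag in range(1, max_lag):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0:
            return lag
    return max(1, max_lag // 4)


def delay_embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vectors = len(x) - (m - 1) * tau
    if n_vectors < 2:
        raise ValueError("series too short for the requested embedding")
    return np.column_stack([x[i * tau : i * tau + n_vectors] for i in range(m)])


def largest_lyapunov_exponent(
    x,
    m: int = 5,
    tau: int | None = None,
    fit_steps: int | None = None,
    theiler: int | None = None,
) -> float:
    """Rosenstein estimate of the largest Lyapunov exponent (per step).

    Returns NaN for segments shorter than ``MIN_SAMPLES`` or with a
    degenerate embedding (all points identical).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < MIN_SAMPLES:
        return float("nan")
    if np.ptp(x) == 0:
        return float("nan")

    tau = tau if tau is not None else autocorr_delay(x)
    # keep the embedding window a small fraction of the segment
    tau = max(1, min(tau, len(x) // (4 * (m - 1))))
    while (m - 1) * tau >= len(x) - 4 and m > 2:
        m -= 1
    try:
        emb = delay_embed(x, m, tau)
    except ValueError:
        return float("nan")
    n = len(emb)
    if n < 10:
        return float("nan")

    theiler = theiler if theiler is not None else max(tau * m, 1)
    theiler = min(theiler, max(1, n // 4))  # leave every point a valid neighbor
    dists = cdist(emb, emb)
    np.fill_diagonal(dists, np.inf)
    idx = np.arange(n)
    for offset in range(1, theiler + 1):
        d = idx[:-offset]
        dists[d, d + offset] = np.inf
        dists[d + offset, d] = np.inf
    neighbors = np.argmin(dists, axis=1)
    finite = np.isfinite(dists[idx, neighbors])
    if not finite.any():
        return float("nan")

    max_steps = fit_steps if fit_steps is not None else min(20, n // 4)
    if max_steps < 2:
        return float("nan")
    mean_log = np.full(max_steps, np.nan)
    for k in range(max_steps):
        valid = (idx + k < n) & (neighbors + k < n) & finite
        if valid.sum() < 2:
            break
        sep = np.linalg.norm(emb[idx[valid] + k] - emb[neighbors[valid] + k], axis=1)
        sep = sep[sep > 0]
        if len(sep) < 2:
            break
        mean_log[k] = np.mean(np.log(sep))
    ok_steps = np.flatnonzero(np.isfinite(mean_log))
    if len(ok_steps) < 2:
        return float("nan")
    # fit only the initial divergence, before the curve bends into saturation
    # at the attractor size: keep steps up to the midpoint of the curve's range
    curve = mean_log[ok_steps]
    span = curve.max() - curve[0]
    # flat curves (periodic signals) are fit over the whole window instead
    if span > 1.0:
        cut = np.argmax(curve >= curve[0] + 0.5 * span)
        cut = max(int(cut), 2)
        ok_steps, curve = ok_steps[: cut + 1], curve[: cut + 1]
    slope = np.polyfit(ok_steps, curve, 1)[0]
    return float(slope)
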