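"""Upper-truncated normal sampling, numerically stable far into the tail.

Draws from N(mean, sd^2) conditioned on the value lying at or below ``upper``.
For moderate truncation the inverse-CDF method is used (one uniform per
draw); when the bound lies more than ``TAIL_Z`` standard deviations below the
mean, inverse-CDF underflows and Robert's (1995) translated-exponential
rejection sampler takes over.  Both paths are exact samplers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

#: Standardized bound below which the exponential-rejection tail sampler is used.
TAIL_Z = -5.0


def _tail_std(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw Z ~ N(0,1) | Z <= alpha for alpha << 0 (Robert 1995, reflected)."""
    a = -alpha  # a > 0, sampling the upper tail X >= a, return -X
    out = np.empty(a.shape)
    todo = np.ones(a.shape, dtype=bool)
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while todo.any():
        m = int(todo.sum())
        x = a[todo] - np.log1p(-rng.random(m)) / lam[todo]
        accept = rng.random(m) <= np.exp(-0.5 * (x - lam[todo]) ** 2)
        idx = np.flatnonzero(todo)[accept]
        out[idx] = x[accept]
        todo[idx] = False
    return -out


def sample_truncated_normal(
    mean, sd, upper, rng: np.random.Generator, size: int | None = None
):
    """One draw (or ``size`` draws) from N(mean, sd^2) restricted to (-inf, upper].

    Parameters are broadcast together; ``upper`` may be ``np.inf`` (no
    truncation).  ``sd`` must be strictly positive.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(sd <= 0.0):
        raise ValueError("sd must be > 0")
    scalar = mean.ndim == 0 and sd.ndim == 0 and upper.ndim == 0 and size is None
    shape = (size,) if size is not None else np.broadcast(mean, sd, upper).shape
    if scalar:
        shape = (1,)
    alpha = np.broadcast_to((upper - mean) / sd, shape).astype(float).copy()
    z = np.empty(shape)

    free = np.isinf(alpha) & (alpha > 0)
    mid = (~free) & (alpha > TAIL_Z)
    tail = (~free) & (~mid)
    if free.any():
        z[free] = rng.standard_normal(int(free.sum()))
    if mid.any():
        p = rng.random(int(mid.sum())) * ndtr(alpha[mid])
        # p can underflow to 0 only for alpha near TAIL_Z with tiny u; clip
        z[mid] = ndtri(np.clip(p, 1e-300, 1.0))
    if tail.any():
        z[tail] = _tail_std(alpha[tail], rng)

    out = np.broadcast_to(mean, shape) + np.broadcast_to(sd, shape) * z
    # guard against round-off pushing a draw infinitesimally past the bound
    out = np.minimum(out, np.broadcast_to(upper, shape))
    return float(out[0]) if scalar else out


def truncated_normal_mean(mean: float, sd: float, upper: float) -> float:
    """Analytic mean of N(mean, sd^2) truncated to (-inf, upper]."""
    if np.isinf(upper):
        return mean
    a = (upper - mean) / sd
    phi = np.exp(-0.5 * a * a) / np.sqrt(2.0 * np.pi)
    return mean - sd * phi / ndtr(a)
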