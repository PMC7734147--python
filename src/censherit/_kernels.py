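"""Numba kernel for the sequential breeding-value update.

Every other Gibbs step in the sampler is conditionally independent across
units and is vectorized with numpy; breeding values are the exception, since
A^-1 couples each animal to its parents, progeny and mates, so the sweep must
be sequential.  Randomness is injected through a pre-drawn standard-normal
matrix so the kernel itself holds no RNG state.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_lower(P, L):
    """In-place lower Cholesky of small SPD matrix P into L; returns False on
    a non-positive pivot (caller adds jitter and retries)."""
    T = P.shape[0]
    for i in range(T):
        for j in range(i + 1):
            s = P[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def sample_animals(a, D, v, G0inv, indptr, indices, qdata, z):
    """One Gibbs sweep over all animals' T-trait breeding-value vectors.

    a      : (n, T) current breeding values, updated in place, sequentially.
    D      : (n, T, T) per-animal data precision (records only).
    v      : (n, T) per-animal sum of R^-1-weighted residuals (residuals
             computed with the *current* a entering this sweep).
    G0inv  : (T, T) inverse additive covariance.
    indptr/indices/qdata : CSR of A^-1.
    z      : (n, T) pre-drawn standard normals.

    Full conditional for animal i: precision P = D_i + q_ii * G0inv, mean
    a_i + P^-1 (v_i - G0inv @ (A^-1 a)_i) with (A^-1 a)_i evaluated at the
    freshest values of all other animals.
    """
    n, T = a.shape
    P = np.empty((T, T))
    L = np.empty((T, T))
    w = np.empty(T)
    rhs = np.empty(T)
    y = np.empty(T)
    for i in range(n):
        qii = 0.0
        for t in range(T):
            w[t] = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            q = qdata[p]
            if j == i:
                qii = q
            for t in range(T):
                w[t] += q * a[j, t]
        for t in range(T):
            s = v[i, t]
            for u in range(T):
                P[t, u] = D[i, t, u] + qii * G0inv[t, u]
                s -= G0inv[t, u] * w[u]
            rhs[t] = s
        jitter = 0.0
        while not _chol_lower(P, L):
            jitter = 1e-10 if jitter == 0.0 else jitter * 10.0
            for t in range(T):
                P[t, t] += jitter
        # y = L^-1 rhs ; rhs := L^-T y  (so rhs = P^-1 rhs)
        for t in range(T):
            s = rhs[t]
            for k in range(t):
                s -= L[t, k] * y[k]
            y[t] = s / L[t, t]
        for t in range(T - 1, -1, -1):
            s = y[t]
            for k in range(t + 1, T):
                s -= L[k, t] * rhs[k]
            rhs[t] = s / L[t, t]
        # noise u = L^-T z  has covariance P^-1
        for t in range(T - 1, -1, -1):
            s = z[i, t]
            for k in range(t + 1, T):
                s -= L[k, t] * y[k]
            y[t] = s / L[t, t]
        for t in range(T):
            a[i, t] += rhs[t] + y[t]
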