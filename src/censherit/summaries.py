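"""Posterior summaries: heritabilities, correlations, event means and the
Raftery–Lewis run-length diagnostic.

Derived genetic parameters (h2, c2, r_g, r_c, r_e) are computed per retained
draw and then averaged -- never as ratios of averaged components -- and the
reported spread is the posterior standard deviation over retained draws.
Residual correlations exist only within a residual block; pairs spanning
blocks (or involving the longitudinal trait) are reported as NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ValidationError
from .gibbs import OBSERVED_STATUSES, PosteriorChain
from .model import ModelSpec, VarianceComponents


@dataclass
class DerivedParameters:
    """Per-draw genetic parameters for one set of variance components."""

    h2: np.ndarray  # (T,)
    c2: np.ndarray  # (T,)
    rg: np.ndarray  # (T, T), NaN diagonal-less convention: diag = 1
    rc: np.ndarray
    re: np.ndarray  # NaN outside residual blocks


def _safe_corr(M: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(M), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = M / np.outer(sd, sd)
    C[~np.isfinite(C)] = np.nan
    return C


def derive_parameters(comps: VarianceComponents, spec: ModelSpec) -> DerivedParameters:
    """h2 = sigma_a^2/sigma_p^2 and c2 = sigma_c^2/sigma_p^2 per trait, with
    the phenotypic variance of the longitudinal trait including the
    repeatability variance; correlations from covariance / sd products.
    Zero variances yield NaN entries rather than errors."""
    T = spec.n_traits
    vp = comps.phenotypic_variances(spec)
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(vp > 0, np.diag(comps.G0) / vp, np.nan)
        c2 = (
            np.where(vp > 0, np.diag(comps.C0) / vp, np.nan)
            if comps.C0 is not None
            else np.zeros(T)
        )
    rg = _safe_corr(comps.G0)
    rc = _safe_corr(comps.C0) if comps.C0 is not None else np.full((T, T), np.nan)
    re = np.full((T, T), np.nan)
    for off, blk, R in zip(spec.block_offsets, spec.blocks, comps.R_blocks):
        sl = slice(off, off + blk.k)
        re[sl, sl] = _safe_corr(np.asarray(R))
    if spec.longitudinal is not None:
        re[T - 1, T - 1] = 1.0
    return DerivedParameters(h2=h2, c2=c2, rg=rg, rc=rc, re=re)


@dataclass
class GeneticParameterSummary:
    """Posterior mean and SD of every derived genetic parameter."""

    trait_names: list[str]
    h2_mean: np.ndarray
    h2_sd: np.ndarray
    c2_mean: np.ndarray
    c2_sd: np.ndarray
    rg_mean: np.ndarray
    rg_sd: np.ndarray
    rc_mean: np.ndarray
    rc_sd: np.ndarray
    re_mean: np.ndarray
    re_sd: np.ndarray

    def heritability_table(self) -> pd.DataFrame:
        """Heritabilities on the diagonal, genetic correlations below it,
        residual correlations above it."""
        T = len(self.trait_names)
        M = np.full((T, T), np.nan)
        for i in range(T):
            M[i, i] = self.h2_mean[i]
            for j in range(i):
                M[i, j] = self.rg_mean[i, j]
                M[j, i] = self.re_mean[j, i]
        return pd.DataFrame(M, index=self.trait_names, columns=self.trait_names)

    def fullsib_table(self) -> pd.DataFrame:
        """Fullsib variance proportions on the diagonal, fullsib-effect
        correlations below it."""
        T = len(self.trait_names)
        M = np.full((T, T), np.nan)
        for i in range(T):
            M[i, i] = self.c2_mean[i]
            for j in range(i):
                M[i, j] = self.rc_mean[i, j]
        return pd.DataFrame(M, index=self.trait_names, columns=self.trait_names)


def summarize_chain(chain: PosteriorChain) -> GeneticParameterSummary:
    """Posterior mean ± SD of each derived parameter across retained draws
    (derived per draw, then averaged)."""
    m = len(chain)
    if m == 0:
        raise ValidationError("cannot summarize an empty chain")
    spec = chain.spec
    T = spec.n_traits
    h2 = np.empty((m, T))
    c2 = np.empty((m, T))
    rg = np.empty((m, T, T))
    rc = np.empty((m, T, T))
    re = np.empty((m, T, T))
    for j in range(m):
        d = derive_parameters(chain.components_at(j), spec)
        h2[j], c2[j], rg[j], rc[j], re[j] = d.h2, d.c2, d.rg, d.rc, d.re
    # sample SD over retained draws (ddof=1 when more than one draw);
    # cross-block residual entries are all-NaN by construction
    ddof = 1 if m > 1 else 0
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        warnings.filterwarnings("ignore", "Degrees of freedom <= 0")
        return GeneticParameterSummary(
            trait_names=chain.trait_names,
            h2_mean=h2.mean(0),
            h2_sd=h2.std(0, ddof=ddof),
            c2_mean=c2.mean(0),
            c2_sd=c2.std(0, ddof=ddof),
            rg_mean=rg.mean(0),
            rg_sd=rg.std(0, ddof=ddof),
            rc_mean=np.nanmean(rc, 0) if not np.all(np.isnan(rc)) else rc[0],
            rc_sd=np.nanstd(rc, 0, ddof=ddof) if not np.all(np.isnan(rc)) else rc[0],
            re_mean=np.nanmean(re, 0),
            re_sd=np.nanstd(re, 0, ddof=ddof),
        )


# --------------------------------------------------------------------------
# Raftery–Lewis run-length diagnostic
# --------------------------------------------------------------------------


@dataclass
class RafteryLewisResult:
    quantile: float
    precision: float
    probability: float
    n_min: int
    burn_in: int
    n_required: int
    thinning: int
    dependence_factor: float


def raftery_lewis(
    chain: np.ndarray,
    q: float = 0.025,
    r: float = 0.005,
    s: float = 0.95,
    eps: float = 0.001,
    max_thin: int = 50,
) -> RafteryLewisResult:
    """How many MCMC iterations are needed to estimate the ``q`` quantile to
    within ``±r`` with probability ``s``.

    The chain is dichotomized at its empirical ``q`` quantile; the smallest
    thinning ``k`` at which a first-order two-state Markov chain is preferred
    over a second-order one (by BIC) is found, the transition probabilities
    alpha/beta of the thinned indicator chain are estimated, and burn-in and
    required sample sizes follow from the standard two-state formulas.  The
    dependence factor is (burn-in + required N) / N_min, where N_min is the
    binomial requirement for independent draws.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1:
        raise ValidationError("raftery_lewis expects a scalar chain")
    phi = ndtri(0.5 * (s + 1.0))
    n_min = int(math.ceil(q * (1.0 - q) * phi * phi / (r * r)))
    if x.size < n_min:
        raise ValidationError(
            f"chain of length {x.size} is shorter than the minimum {n_min} "
            "required by the requested precision"
        )
    cut = np.quantile(x, q)
    z = (x <= cut).astype(np.int64)
    if z.all() or not z.any():
        raise ValidationError("chain is constant; quantile dichotomization undefined")

    kthin = 1
    for k in range(1, max_thin + 1):
        kthin = k
        zt = z[::k]
        if zt.size < 3:
            break
        if _markov_first_order_preferred(zt):
            break

    zt = z[::kthin]
    trans = np.zeros((2, 2))
    np.add.at(trans, (zt[:-1], zt[1:]), 1.0)
    alpha = trans[0, 1] / max(trans[0].sum(), 1.0)  # P(0 -> 1)
    beta = trans[1, 0] / max(trans[1].sum(), 1.0)  # P(1 -> 0)
    absum = alpha + beta
    lam = 1.0 - absum
    if alpha <= 0.0 or beta <= 0.0:
        raise ValidationError("degenerate transition matrix; chain too short for the diagnostic")
    if lam <= 0.0:
        burn = kthin  # chain mixes in one step (or anti-correlates)
    else:
        m0 = math.log(eps * absum / max(alpha, beta)) / math.log(lam)
        burn = int(math.ceil(m0)) * kthin
    n_req = int(math.ceil((2.0 - absum) * alpha * beta * phi * phi / (absum**3 * r * r))) * kthin
    return RafteryLewisResult(
        quantile=q,
        precision=r,
        probability=s,
        n_min=n_min,
        burn_in=burn,
        n_required=n_req,
        thinning=kthin,
        dependence_factor=(burn + n_req) / n_min,
    )


def _markov_first_order_preferred(z: np.ndarray) -> bool:
    """BIC comparison of first- vs second-order Markov for a binary chain."""
    n = z.size - 2
    if n <= 0:
        return True
    tri = np.zeros((2, 2, 2))
    np.add.at(tri, (z[:-2], z[1:-1], z[2:]), 1.0)
    g2 = 0.0
    for j in range(2):
        n_j = tri[:, j, :].sum()
        if n_j == 0:
            continue
        for i in range(2):
            for l in range(2):
                o = tri[i, j, l]
                if o == 0:
                    continue
                e = tri[i, j, :].sum() * tri[:, j, l].sum() / n_j
                g2 += 2.0 * o * math.log(o / e)
    bic = g2 - 2.0 * math.log(n)
    return bic < 0.0


# --------------------------------------------------------------------------
# Observed vs model-estimated event means
# --------------------------------------------------------------------------


def estimate_event_means(chain: PosteriorChain, growth: pd.DataFrame) -> pd.DataFrame:
    """Per sampling group (year class × event): the naive mean growth rate of
    recorded fish, and the model's estimate of the mean over *all* fish alive
    then (observed values plus the posterior mean of the augmented phantom
    values for the censored fish)."""
    if chain.event_mean_draws is None:
        raise ValidationError("chain has no longitudinal trait")
    g = growth[growth["status"] != "dead"]
    obs = g[g["status"].isin(OBSERVED_STATUSES)]
    obs_mean = obs.groupby("sampling_group")["growth_rate"].mean()
    n_rows = g.groupby("sampling_group").size()
    n_obs = obs.groupby("sampling_group").size()
    rows = []
    est_mean = chain.event_mean_draws.mean(0)
    est_sd = chain.event_mean_draws.std(0, ddof=1 if len(chain) > 1 else 0)
    for j, label in enumerate(chain.event_group_labels):
        rows.append(
            {
                "sampling_group": label,
                "n_rows": int(n_rows.get(label, 0)),
                "n_observed": int(n_obs.get(label, 0)),
                "observed_mean": float(obs_mean.get(label, np.nan)),
                "estimated_mean": float(est_mean[j]),
                "estimated_sd": float(est_sd[j]),
            }
        )
    return pd.DataFrame(rows)
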