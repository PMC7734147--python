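"""Gibbs sampler for the multi-trait animal model with left-censored
longitudinal growth records.

One sweep updates, in fixed order: (1) augmented phenotypes for censored
growth rows (truncated-normal draws bounded by threshold-weight/age), (2)
augmented values for missing cross-sectional traits (conditional Gaussians
within their residual block), (3) all location effects -- fixed effects,
breeding values, fullsib effects, permanent growth effects -- and (4) all
(co)variance components from their inverse-Wishart / scaled inverse
chi-square full conditionals.

All updates except the breeding-value sweep are conditionally independent
across units and run as vectorized numpy; breeding values use a sequential
numba kernel because A^-1 couples relatives.  Every random draw comes from a
single ``numpy.random.Generator`` seeded from the chain config, so chains
are bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from . import _kernels
from .errors import EstimabilityError, ValidationError
from .model import ModelSpec, VarianceComponents
from .pedigree import Pedigree, build_relationship_inverse, sort_pedigree
from .truncnorm import sample_truncated_normal

logger = logging.getLogger("censherit")

OBSERVED_STATUSES = ("observed_slaughtered", "observed_below_threshold")


def plan_chain(n_iterations: int, burn_in_iterations: int, thinning: int) -> int:
    """Number of retained samples: every ``thinning``-th iteration is a
    sample; samples up to and including the burn-in are discarded."""
    if thinning < 1 or n_iterations < 1:
        raise ValidationError("n_iterations and thinning must be >= 1")
    if burn_in_iterations >= n_iterations:
        raise ValidationError("burn-in must be shorter than the chain")
    return n_iterations // thinning - burn_in_iterations // thinning


@dataclass
class ChainConfig:
    n_iterations: int = 5000
    burn_in_iterations: int = 1000
    thinning_interval: int = 5
    seed: int = 1
    log_every: int = 0  # 0 = auto (~20 log lines)

    def __post_init__(self):
        plan_chain(self.n_iterations, self.burn_in_iterations, self.thinning_interval)
        if self.burn_in_iterations % self.thinning_interval:
            logger.warning(
                "burn-in (%d) is not a multiple of the thinning interval (%d)",
                self.burn_in_iterations,
                self.thinning_interval,
            )

    @property
    def n_retained(self) -> int:
        return plan_chain(self.n_iterations, self.burn_in_iterations, self.thinning_interval)


@dataclass
class Priors:
    """Inverse-Wishart scales/df per covariance block and scaled
    inverse-chi-square hyperparameters for the two scalar variances."""

    g_scale: np.ndarray
    g_df: float
    c_scale: np.ndarray | None
    c_df: float
    r_scales: list[np.ndarray]
    r_dfs: list[float]
    se_long_s0: float | None
    se_long_df: float
    sr_s0: float | None
    sr_df: float


@dataclass
class _BlockData:
    name: str
    index: int
    off: int
    k: int
    y: np.ndarray  # (n, k) observed values, NaN where missing
    miss: np.ndarray  # (n, k) bool
    lvl: np.ndarray  # (n,) combo-factor codes
    n_levels: int
    level_labels: list[str]
    anim: np.ndarray
    fam: np.ndarray
    cnt_lvl: np.ndarray
    cnt_anim: np.ndarray
    cnt_fam: np.ndarray


@dataclass
class _GrowthFactor:
    name: str
    codes: np.ndarray
    n_levels: int
    labels: list[str]
    corner: bool  # first level constrained to zero
    cnt: np.ndarray


@dataclass
class _GrowthData:
    y_obs: np.ndarray  # NaN on censored rows
    cens: np.ndarray
    bound: np.ndarray
    anim: np.ndarray
    fam: np.ndarray
    rfish: np.ndarray
    n_rfish: int
    rfish_ids: list[str]
    factors: list[_GrowthFactor]
    cnt_anim: np.ndarray
    cnt_fam: np.ndarray
    cnt_rfish: np.ndarray


class ChainState:
    """Mutable state of one chain: location effects, augmented phenotypes and
    current variance components."""

    def __init__(self, b_blocks, b_growth, a, c, r, y_blocks, y_long, comps: VarianceComponents):
        self.b_blocks: list[np.ndarray] = b_blocks
        self.b_growth: list[np.ndarray] = b_growth
        self.a = a
        self.c = c
        self.r = r
        self.y_blocks: list[np.ndarray] = y_blocks  # augmented (complete) copies
        self.y_long = y_long
        self.comps = comps
        self.iteration = 0

    def check_finite(self):
        arrays = (
            self.a,
            self.c,
            self.r,
            self.y_long,
            *self.b_blocks,
            *self.b_growth,
            *self.y_blocks,
        )
        for arr in arrays:
            if arr is not None and arr.size and not np.all(np.isfinite(arr)):
                raise RuntimeError(
                    f"divergent chain state at iteration {self.iteration}: "
                    "non-finite values encountered"
                )


@dataclass
class PosteriorChain:
    """Retained draws of all (co)variance components plus the streaming
    per-event means of the (augmented) growth phenotypes."""

    trait_names: list[str]
    spec: ModelSpec
    config: ChainConfig
    G0: np.ndarray  # (m, T, T)
    C0: np.ndarray | None
    R_blocks: list[np.ndarray]
    sigma_e_long: np.ndarray | None
    sigma_r: np.ndarray | None
    event_group_labels: list[str]
    event_mean_draws: np.ndarray | None  # (m, n_groups)
    n_records: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.G0.shape[0]

    def components_at(self, j: int) -> VarianceComponents:
        return VarianceComponents(
            G0=self.G0[j],
            C0=None if self.C0 is None else self.C0[j],
            R_blocks=[R[j] for R in self.R_blocks],
            sigma_e_long=None if self.sigma_e_long is None else float(self.sigma_e_long[j]),
            sigma_r=None if self.sigma_r is None else float(self.sigma_r[j]),
            trait_names=self.trait_names,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat samples table: one row per retained draw, one column per
        unique component (lower triangles) plus the two scalar variances."""
        cols = {}
        T = len(self.trait_names)
        for i in range(T):
            for j in range(i + 1):
                nm = (
                    f"G0[{self.trait_names[i]},{self.trait_names[j]}]"
                    if i != j
                    else f"G0[{self.trait_names[i]}]"
                )
                cols[nm] = self.G0[:, i, j]
        if self.C0 is not None:
            for i in range(T):
                for j in range(i + 1):
                    nm = (
                        f"C0[{self.trait_names[i]},{self.trait_names[j]}]"
                        if i != j
                        else f"C0[{self.trait_names[i]}]"
                    )
                    cols[nm] = self.C0[:, i, j]
        for b, (blk, R) in enumerate(zip(self.spec.blocks, self.R_blocks)):
            for i in range(R.shape[1]):
                for j in range(i + 1):
                    cols[f"R_{blk.name}[{i},{j}]"] = R[:, i, j]
        if self.sigma_e_long is not None:
            cols["sigma_e_long"] = self.sigma_e_long
            cols["sigma_r"] = self.sigma_r
        return pd.DataFrame(cols)


def _factorize(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    codes, labels = pd.factorize(values, sort=True)
    if (codes < 0).any():
        raise ValidationError(f"missing factor value in column {values.name!r}")
    return codes.astype(np.int64), [str(x) for x in labels]


class CensoredGibbsModel:
    """The eight-trait (or any sub-layout) animal model bound to one dataset.

    Parameters
    ----------
    pedigree : Pedigree covering every phenotyped animal.
    phenotypes : cross-sectional table (one row per fish).
    growth : longitudinal growth-record table (may be ``None`` when the
        layout has no longitudinal trait).
    spec : trait layout; defaults to the full eight-trait model.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        phenotypes: pd.DataFrame,
        growth: pd.DataFrame | None = None,
        spec: ModelSpec | None = None,
        priors: Priors | None = None,
    ):
        self.spec = spec if spec is not None else ModelSpec.eight_trait()
        if self.spec.longitudinal is not None and growth is None:
            raise ValidationError("this model layout needs a growth-record table")
        ped = pedigree if pedigree.is_sorted else sort_pedigree(pedigree)
        self.pedigree = ped
        self.ids = list(ped.animal)
        self._pos = {a: i for i, a in enumerate(self.ids)}
        self.n_animals = len(self.ids)
        self.ainv = build_relationship_inverse(ped).tocsr()

        # fullsib families from (sire, dam) pairs; animals with two unknown
        # parents (founders) carry no fullsib effect
        fam_key = {}
        self.family_of = np.full(self.n_animals, -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(ped.sire, ped.dam)):
            if s == "" and d == "":
                continue
            key = (s, d)
            if key not in fam_key:
                fam_key[key] = len(fam_key)
            self.family_of[i] = fam_key[key]
        self.n_families = max(len(fam_key), 1)

        self._build_blocks(phenotypes)
        self._build_growth(growth, phenotypes)
        self._mom_variances()
        self.priors = priors if priors is not None else self.default_priors()
        T = self.spec.n_traits
        self._D = np.zeros((self.n_animals, T, T))
        self._v = np.zeros((self.n_animals, T))
        self._build_translation_index()

    def _build_translation_index(self) -> None:
        """Per-animal Mendelian-sampling quantities and parenthood flags for
        the blocked (effect, breeding-value-shift) updates."""
        from .pedigree import inbreeding_coefficients

        ped = self.pedigree
        si, di = ped.parent_indices()
        F = inbreeding_coefficients(ped)
        n = self.n_animals
        dd = np.empty(n)
        for i in range(n):
            fs = F[si[i]] if si[i] >= 0 else -1.0
            fd = F[di[i]] if di[i] >= 0 else -1.0
            dd[i] = 0.5 - 0.25 * (fs + fd)
        self._si, self._di, self._dd = si, di, dd
        is_parent = np.zeros(n, dtype=bool)
        is_parent[si[si >= 0]] = True
        is_parent[di[di >= 0]] = True
        self._is_parent = is_parent
        if self.growth is not None:
            self._fish_rows = np.array(
                [self._pos[a] for a in self.growth.rfish_ids], dtype=np.int64
            )
        else:
            self._fish_rows = np.zeros(0, dtype=np.int64)

    def _parent_average(self, a: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """0.5 (a_sire + a_dam) with unknown parents contributing zero."""
        out = np.zeros((rows.size, a.shape[1]))
        s = self._si[rows]
        d = self._di[rows]
        out[s >= 0] += 0.5 * a[s[s >= 0]]
        out[d >= 0] += 0.5 * a[d[d >= 0]]
        return out

    # ------------------------------------------------------------------ data
    def _animal_rows(self, series: pd.Series) -> np.ndarray:
        missing = [a for a in series if a not in self._pos]
        if missing:
            raise ValidationError(
                f"{len(missing)} phenotyped animals absent from the pedigree, e.g. {missing[:3]}"
            )
        return np.array([self._pos[a] for a in series], dtype=np.int64)

    def _build_blocks(self, pheno: pd.DataFrame) -> None:
        self.blocks: list[_BlockData] = []
        for bi, (off, blk) in enumerate(zip(self.spec.block_offsets, self.spec.blocks)):
            rows = pheno[pheno["group"] == blk.group]
            y = rows[blk.traits].to_numpy(dtype=float)
            keep = ~np.all(np.isnan(y), axis=1)
            rows = rows[keep]
            y = y[keep]
            if len(rows) == 0:
                raise ValidationError(f"no phenotype rows for block {blk.name!r}")
            if rows["animal"].duplicated().any():
                dup = rows.loc[rows["animal"].duplicated(), "animal"].iloc[0]
                raise ValidationError(f"duplicate phenotype row for animal {dup!r} in group {blk.group}")
            combo = rows[blk.factors].astype(str).agg(":".join, axis=1)
            combo.name = "+".join(blk.factors)
            lvl, labels = _factorize(combo)
            anim = self._animal_rows(rows["animal"])
            self.blocks.append(
                _BlockData(
                    name=blk.name,
                    index=bi,
                    off=off,
                    k=blk.k,
                    y=y,
                    miss=np.isnan(y),
                    lvl=lvl,
                    n_levels=len(labels),
                    level_labels=labels,
                    anim=anim,
                    fam=self.family_of[anim],
                    cnt_lvl=np.bincount(lvl, minlength=len(labels)).astype(float),
                    cnt_anim=np.bincount(anim, minlength=self.n_animals).astype(float),
                    cnt_fam=np.bincount(
                        self.family_of[anim][self.family_of[anim] >= 0],
                        minlength=self.n_families,
                    ).astype(float),
                )
            )

    def _build_growth(self, growth: pd.DataFrame | None, pheno: pd.DataFrame) -> None:
        if self.spec.longitudinal is None:
            self.growth = None
            return
        lspec = self.spec.longitudinal
        g = growth[growth["status"] != "dead"].copy()
        bad = ~g["status"].isin(OBSERVED_STATUSES + ("censored_alive",))
        if bad.any():
            raise ValidationError(f"unknown growth-record status {g.loc[bad, 'status'].iloc[0]!r}")
        cens = (g["status"] == "censored_alive").to_numpy()
        y = g["growth_rate"].to_numpy(dtype=float)
        bound = g["upper_bound"].to_numpy(dtype=float)
        if np.isnan(y[~cens]).any():
            raise ValidationError("observed growth rows must carry a growth rate")
        if np.isnan(bound[cens]).any():
            raise ValidationError("censored growth rows must carry an upper bound")
        # join per-animal columns (sex, ...) needed by the factor list
        pcols = [c for c in lspec.factors if c not in g.columns]
        if pcols:
            g = g.merge(pheno[["animal"] + pcols].drop_duplicates("animal"), on="animal", how="left")
        anim = self._animal_rows(g["animal"])
        rfish_codes, rfish_ids = pd.factorize(g["animal"])
        factors = []
        for fi, name in enumerate(lspec.factors):
            codes, labels = _factorize(g[name])
            cnt = np.bincount(codes, minlength=len(labels)).astype(float)
            if (cnt == 0).any():
                raise EstimabilityError(f"factor {name!r} has an empty level")
            factors.append(
                _GrowthFactor(
                    name=name,
                    codes=codes,
                    n_levels=len(labels),
                    labels=labels,
                    corner=fi > 0,
                    cnt=cnt,
                )
            )
        fam = self.family_of[anim]
        self.growth = _GrowthData(
            y_obs=y,
            cens=cens,
            bound=bound,
            anim=anim,
            fam=fam,
            rfish=rfish_codes.astype(np.int64),
            n_rfish=len(rfish_ids),
            rfish_ids=[str(x) for x in rfish_ids],
            factors=factors,
            cnt_anim=np.bincount(anim, minlength=self.n_animals).astype(float),
            cnt_fam=np.bincount(fam[fam >= 0], minlength=self.n_families).astype(float),
            cnt_rfish=np.bincount(rfish_codes, minlength=len(rfish_ids)).astype(float),
        )

    def _mom_variances(self) -> None:
        """Method-of-moments phenotypic variances per trait (within fixed-
        factor levels), used for priors and initial values."""
        T = self.spec.n_traits
        vp = np.full(T, np.nan)
        for bd in self.blocks:
            for t in range(bd.k):
                obs = ~bd.miss[:, t]
                yv = bd.y[obs, t]
                lv = bd.lvl[obs]
                mu = np.bincount(lv, weights=yv, minlength=bd.n_levels)
                cnt = np.bincount(lv, minlength=bd.n_levels).clip(min=1)
                resid = yv - (mu / cnt)[lv]
                vp[bd.off + t] = max(resid.var(), 1e-8)
        if self.growth is not None:
            gd = self.growth
            obs = ~gd.cens
            f0 = gd.factors[0]
            yv = gd.y_obs[obs]
            lv = f0.codes[obs]
            mu = np.bincount(lv, weights=yv, minlength=f0.n_levels)
            cnt = np.bincount(lv, minlength=f0.n_levels).clip(min=1)
            resid = yv - (mu / cnt)[lv]
            vp[T - 1] = max(resid.var(), 1e-8)
        self.vp_mom = vp

    def default_priors(self) -> Priors:
        """Weak inverse-Wishart priors whose means follow the same
        30% genetic / 10% fullsib / 10% permanent / remainder residual split
        used for initialization (df = dimension + 2, so the prior mean equals
        the scale matrix)."""
        T = self.spec.n_traits
        vp = self.vp_mom
        long_t = self.spec.longitudinal_index
        resid_share = np.full(T, 0.6)
        if long_t is not None:
            resid_share[long_t] = 0.5
        return Priors(
            g_scale=np.diag(0.3 * vp),
            g_df=T + 2.0,
            c_scale=np.diag(0.1 * vp) if self.spec.fullsib else None,
            c_df=T + 2.0,
            r_scales=[
                np.diag(0.6 * vp[bd.off : bd.off + bd.k]) for bd in self.blocks
            ],
            r_dfs=[bd.k + 2.0 for bd in self.blocks],
            se_long_s0=0.5 * vp[long_t] if long_t is not None else None,
            se_long_df=4.1,
            sr_s0=0.1 * vp[long_t] if long_t is not None else None,
            sr_df=4.1,
        )

    # ----------------------------------------------------------------- state
    def _residualized_trait_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-animal, per-trait values with fixed-factor level means removed
        (NaN where unrecorded).  The longitudinal trait uses the per-fish mean
        of its observed, within-level-residualized records."""
        T = self.spec.n_traits
        X = np.full((self.n_animals, T), np.nan)
        for bd in self.blocks:
            for t in range(bd.k):
                obs = ~bd.miss[:, t]
                yv = bd.y[obs, t]
                lv = bd.lvl[obs]
                mu = np.bincount(lv, weights=yv, minlength=bd.n_levels)
                cnt = np.bincount(lv, minlength=bd.n_levels).clip(min=1)
                X[bd.anim[obs], bd.off + t] = yv - (mu / cnt)[lv]
        if self.growth is not None:
            gd = self.growth
            obs = ~gd.cens
            f0 = gd.factors[0]
            mu = np.bincount(f0.codes[obs], weights=gd.y_obs[obs], minlength=f0.n_levels)
            cnt = np.bincount(f0.codes[obs], minlength=f0.n_levels).clip(min=1)
            resid = gd.y_obs[obs] - (mu / cnt)[f0.codes[obs]]
            tot = np.bincount(gd.anim[obs], weights=resid, minlength=self.n_animals)
            per = np.bincount(gd.anim[obs], minlength=self.n_animals)
            has = per > 0
            X[has, T - 1] = tot[has] / per[has]
        return X

    @staticmethod
    def _nearest_spd(M: np.ndarray, floor: float) -> np.ndarray:
        M = 0.5 * (M + M.T)
        w, V = np.linalg.eigh(M)
        return (V * np.clip(w, floor, None)) @ V.T

    def _moment_start_components(self) -> VarianceComponents | None:
        """Pedigree-informed starting values: fullsib covariances estimate
        G0/2 + C0 and halfsib (same sire, different dam) covariances G0/4,
        so G0 = 4 HS and C0 = FS - 2 HS, each projected to positive
        definite; residuals take the remainder.  Returns None when the
        pedigree has too few halfsib groups for the decomposition."""
        T = self.spec.n_traits
        X = self._residualized_trait_values()
        fam = self.family_of
        sire_ids = np.array(self.pedigree.sire)
        # family and sire sums of trait values (NaN-aware)
        have = ~np.isnan(X)
        X0 = np.where(have, X, 0.0)
        fam_keys = {}
        sire_of_fam = np.full(self.n_families, -1, dtype=np.int64)
        for i in range(self.n_animals):
            if fam[i] >= 0 and sire_of_fam[fam[i]] == -1 and sire_ids[i] != "":
                key = sire_ids[i]
                fam_keys.setdefault(key, len(fam_keys))
                sire_of_fam[fam[i]] = fam_keys[key]
        n_sires = len(fam_keys)
        multi = np.bincount(sire_of_fam[sire_of_fam >= 0], minlength=max(n_sires, 1))
        if n_sires < 10 or (multi >= 2).sum() < 5:
            return None
        ok = fam >= 0
        Sf = np.zeros((self.n_families, T))
        Nf = np.zeros((self.n_families, T))
        np.add.at(Sf, fam[ok], X0[ok])
        np.add.at(Nf, fam[ok], have[ok].astype(float))
        Ss = np.zeros((n_sires, T))
        Ns = np.zeros((n_sires, T))
        okf = sire_of_fam >= 0
        np.add.at(Ss, sire_of_fam[okf], Sf[okf])
        np.add.at(Ns, sire_of_fam[okf], Nf[okf])
        same = np.einsum("it,iu->tu", X0[ok], X0[ok])
        n_same = np.einsum("it,iu->tu", have[ok].astype(float), have[ok].astype(float))
        fs_cross = np.einsum("ft,fu->tu", Sf, Sf) - same
        fs_pairs = np.einsum("ft,fu->tu", Nf, Nf) - n_same
        hs_cross = np.einsum("st,su->tu", Ss, Ss) - np.einsum("ft,fu->tu", Sf[okf], Sf[okf])
        hs_pairs = np.einsum("st,su->tu", Ns, Ns) - np.einsum("ft,fu->tu", Nf[okf], Nf[okf])
        if np.any(fs_pairs <= 0) or np.any(hs_pairs <= 0):
            return None
        FS = fs_cross / fs_pairs
        HS = hs_cross / hs_pairs
        vp = self.vp_mom
        floor = 1e-3 * vp
        G0 = self._nearest_spd(4.0 * HS, float(np.min(0.02 * vp)))
        np.fill_diagonal(G0, np.clip(np.diag(G0), 0.02 * vp, 0.8 * vp))
        G0 = self._nearest_spd(G0, float(np.min(0.01 * vp)))
        C0 = self._nearest_spd(FS - 2.0 * HS, float(np.min(0.01 * vp)))
        np.fill_diagonal(C0, np.clip(np.diag(C0), 0.01 * vp, 0.4 * vp))
        C0 = self._nearest_spd(C0, float(np.min(0.005 * vp)))
        # residuals: within-animal covariance minus the family components
        R_blocks = []
        for bd in self.blocks:
            sl = slice(bd.off, bd.off + bd.k)
            Xb = X[bd.anim][:, sl]
            W = pd.DataFrame(Xb).cov().to_numpy()
            R = self._nearest_spd(
                W - G0[sl, sl] - C0[sl, sl], float(np.min(0.05 * vp[sl]))
            )
            R_blocks.append(R)
        se8 = sr = None
        if self.growth is not None:
            t8 = T - 1
            gd = self.growth
            obs = ~gd.cens
            f0 = gd.factors[0]
            mu = np.bincount(f0.codes[obs], weights=gd.y_obs[obs], minlength=f0.n_levels)
            cnt = np.bincount(f0.codes[obs], minlength=f0.n_levels).clip(min=1)
            resid = gd.y_obs[obs] - (mu / cnt)[f0.codes[obs]]
            fish = gd.rfish[obs]
            m1 = np.bincount(fish, weights=resid, minlength=gd.n_rfish)
            m2 = np.bincount(fish, weights=resid**2, minlength=gd.n_rfish)
            nn = np.bincount(fish, minlength=gd.n_rfish)
            rep = nn > 1
            if rep.sum() >= 10:
                within = float(
                    np.sum(m2[rep] - m1[rep] ** 2 / nn[rep]) / np.sum(nn[rep] - 1)
                )
            else:
                within = 0.5 * vp[t8]
            se8 = float(np.clip(within, 0.05 * vp[t8], 0.9 * vp[t8]))
            sr = float(
                np.clip(vp[t8] - G0[t8, t8] - C0[t8, t8] - se8, 0.05 * vp[t8], 0.9 * vp[t8])
            )
        if not self.spec.fullsib:
            C0 = None
        comps = VarianceComponents(
            G0=G0,
            C0=C0,
            R_blocks=R_blocks,
            sigma_e_long=se8,
            sigma_r=sr,
            trait_names=self.spec.trait_names,
        )
        try:
            comps.validate(self.spec)
        except ValidationError:
            return None
        return comps

    def init_state(self) -> ChainState:
        T = self.spec.n_traits
        vp = self.vp_mom
        long_t = self.spec.longitudinal_index
        b_blocks, y_blocks = [], []
        for bd in self.blocks:
            b = np.zeros((bd.k, bd.n_levels))
            y = bd.y.copy()
            for t in range(bd.k):
                obs = ~bd.miss[:, t]
                mu = np.bincount(bd.lvl[obs], weights=bd.y[obs, t], minlength=bd.n_levels)
                cnt = np.bincount(bd.lvl[obs], minlength=bd.n_levels)
                gmean = bd.y[obs, t].mean()
                b[t] = np.where(cnt > 0, mu / cnt.clip(min=1), gmean)
                y[bd.miss[:, t], t] = b[t][bd.lvl[bd.miss[:, t]]]
            b_blocks.append(b)
            y_blocks.append(y)
        b_growth, y_long = [], None
        if self.growth is not None:
            gd = self.growth
            obs = ~gd.cens
            sd0 = float(np.sqrt(vp[long_t]))
            for f in gd.factors:
                if f.corner:
                    b_growth.append(np.zeros(f.n_levels))
                else:
                    mu = np.bincount(f.codes[obs], weights=gd.y_obs[obs], minlength=f.n_levels)
                    cnt = np.bincount(f.codes[obs], minlength=f.n_levels)
                    b_growth.append(
                        np.where(cnt > 0, mu / cnt.clip(min=1), gd.y_obs[obs].mean())
                    )
            y_long = gd.y_obs.copy()
            lm = b_growth[0][gd.factors[0].codes]
            y_long[gd.cens] = np.minimum(lm[gd.cens], gd.bound[gd.cens]) - 0.2 * sd0
        comps = self._moment_start_components()
        if comps is None:
            # fallback: fixed phenotypic-variance split
            comps = VarianceComponents(
                G0=np.diag(0.3 * vp),
                C0=np.diag(0.1 * vp) if self.spec.fullsib else None,
                R_blocks=[np.diag(0.6 * vp[bd.off : bd.off + bd.k]) for bd in self.blocks],
                sigma_e_long=float(0.5 * vp[long_t]) if long_t is not None else None,
                sigma_r=float(0.1 * vp[long_t]) if long_t is not None else None,
                trait_names=self.spec.trait_names,
            )
        return ChainState(
            b_blocks=b_blocks,
            b_growth=b_growth,
            a=np.zeros((self.n_animals, T)),
            c=np.zeros((self.n_families, T)),
            r=np.zeros(self.growth.n_rfish) if self.growth is not None else np.zeros(0),
            y_blocks=y_blocks,
            y_long=y_long,
            comps=comps,
        )

    # ------------------------------------------------------------ predictors
    def _c_part(self, fam: np.ndarray, c: np.ndarray, off: int, k: int) -> np.ndarray:
        out = c[fam, off : off + k]
        out[fam < 0] = 0.0
        return out

    def _block_resid(self, bd: _BlockData, st: ChainState) -> np.ndarray:
        pred = (
            st.b_blocks[bd.index].T[bd.lvl]
            + st.a[bd.anim, bd.off : bd.off + bd.k]
            + self._c_part(bd.fam, st.c, bd.off, bd.k)
        )
        return st.y_blocks[bd.index] - pred

    def _growth_pred(self, st: ChainState) -> np.ndarray:
        gd = self.growth
        t8 = self.spec.longitudinal_index
        pred = st.a[gd.anim, t8] + st.r[gd.rfish]
        cpart = st.c[gd.fam, t8]
        cpart[gd.fam < 0] = 0.0
        pred = pred + cpart
        for f, bf in zip(gd.factors, st.b_growth):
            pred += bf[f.codes]
        return pred

    # ---------------------------------------------------------- augmentation
    def augment_censored(self, st: ChainState, rng: np.random.Generator) -> None:
        """Redraw every censored growth phenotype from the truncated normal
        located at its current linear predictor, bounded above by
        threshold-weight / age."""
        if self.growth is None:
            return
        gd = self.growth
        if not gd.cens.any():
            return
        pred = self._growth_pred(st)
        se = np.sqrt(st.comps.sigma_e_long)
        st.y_long[gd.cens] = sample_truncated_normal(
            pred[gd.cens], se, gd.bound[gd.cens], rng
        )

    def augment_missing(self, st: ChainState, rng: np.random.Generator) -> None:
        """Impute missing cross-sectional traits from their conditional
        Gaussian given the observed traits of the same residual block."""
        for bi, bd in enumerate(self.blocks):
            if not bd.miss.any():
                continue
            R = st.comps.R_blocks[bi]
            y = st.y_blocks[bi]
            pred = (
                st.b_blocks[bi].T[bd.lvl]
                + st.a[bd.anim, bd.off : bd.off + bd.k]
                + self._c_part(bd.fam, st.c, bd.off, bd.k)
            )
            patterns = {}
            for row in np.flatnonzero(bd.miss.any(axis=1)):
                patterns.setdefault(tuple(bd.miss[row]), []).append(row)
            for pat, rows in patterns.items():
                rows = np.asarray(rows)
                mi = np.flatnonzero(pat)
                oi = np.flatnonzero(~np.asarray(pat))
                z = rng.standard_normal((rows.size, mi.size))
                if oi.size == 0:
                    L = np.linalg.cholesky(R)
                    y[rows] = pred[rows] + z @ L.T
                    continue
                Roo = R[np.ix_(oi, oi)]
                Rmo = R[np.ix_(mi, oi)]
                K = np.linalg.solve(Roo, Rmo.T).T
                cov = R[np.ix_(mi, mi)] - K @ Rmo.T
                L = np.linalg.cholesky(cov)
                mean = pred[rows][:, mi] + (y[rows][:, oi] - pred[rows][:, oi]) @ K.T
                y[np.ix_(rows, mi)] = mean + z @ L.T

    # ------------------------------------------------------------- locations
    def sample_fixed(self, st: ChainState, rng: np.random.Generator) -> None:
        for bi, bd in enumerate(self.blocks):
            Rinv = np.linalg.inv(st.comps.R_blocks[bi])
            E = self._block_resid(bd, st)
            b = st.b_blocks[bi]
            for t in range(bd.k):
                s = E @ Rinv[t]
                acc = np.bincount(bd.lvl, weights=s, minlength=bd.n_levels)
                W = bd.cnt_lvl * Rinv[t, t]
                delta = acc / W + rng.standard_normal(bd.n_levels) / np.sqrt(W)
                b[t] += delta
                E[:, t] -= delta[bd.lvl]
        if self.growth is not None:
            gd = self.growth
            inv_se = 1.0 / st.comps.sigma_e_long
            e = st.y_long - self._growth_pred(st)
            for f, bf in zip(gd.factors, st.b_growth):
                acc = np.bincount(f.codes, weights=e, minlength=f.n_levels)
                delta = acc / f.cnt + rng.standard_normal(f.n_levels) / np.sqrt(
                    f.cnt * inv_se
                )
                if f.corner:
                    delta[0] = 0.0
                bf += delta
                e -= delta[f.codes]

    def sample_breeding_values(self, st: ChainState, rng: np.random.Generator) -> None:
        T = self.spec.n_traits
        D, v = self._D, self._v
        D[:] = 0.0
        v[:] = 0.0
        for bi, bd in enumerate(self.blocks):
            Rinv = np.linalg.inv(st.comps.R_blocks[bi])
            sl = slice(bd.off, bd.off + bd.k)
            D[:, sl, sl] += bd.cnt_anim[:, None, None] * Rinv
            E = self._block_resid(bd, st)
            np.add.at(v[:, sl], bd.anim, E @ Rinv)
        if self.growth is not None:
            gd = self.growth
            t8 = self.spec.longitudinal_index
            inv_se = 1.0 / st.comps.sigma_e_long
            D[:, t8, t8] += gd.cnt_anim * inv_se
            e = st.y_long - self._growth_pred(st)
            v[:, t8] += np.bincount(gd.anim, weights=e, minlength=self.n_animals) * inv_se
        G0inv = np.linalg.inv(st.comps.G0)
        z = rng.standard_normal((self.n_animals, T))
        _kernels.sample_animals(
            st.a,
            D,
            v,
            G0inv,
            self.ainv.indptr,
            self.ainv.indices,
            self.ainv.data.astype(np.float64),
            z,
        )

    def sample_fullsib_effects(self, st: ChainState, rng: np.random.Generator) -> None:
        """Blocked update: each family's fullsib vector c_f is drawn jointly
        with a common shift of its members' breeding values.

        Those two directions are strongly negatively correlated a posteriori
        (the data constrain only their sum for every record), so single-site
        updates random-walk between them; the joint 2T-dimensional Gaussian
        draw removes that correlation.  Families are mutually independent
        given parents and are updated in one vectorized batch.  In a family
        whose members are themselves parents the shift is pinned to zero
        (the members' progeny terms would otherwise enter), reducing to the
        plain c_f conditional.
        """
        if not self.spec.fullsib:
            return
        T = self.spec.n_traits
        nf = self.n_families
        D = np.zeros((nf, T, T))
        v = np.zeros((nf, T))
        for bi, bd in enumerate(self.blocks):
            Rinv = np.linalg.inv(st.comps.R_blocks[bi])
            sl = slice(bd.off, bd.off + bd.k)
            D[:, sl, sl] += bd.cnt_fam[:, None, None] * Rinv
            E = self._block_resid(bd, st)
            ok = bd.fam >= 0
            np.add.at(v[:, sl], bd.fam[ok], (E @ Rinv)[ok])
        if self.growth is not None:
            gd = self.growth
            t8 = self.spec.longitudinal_index
            inv_se = 1.0 / st.comps.sigma_e_long
            D[:, t8, t8] += gd.cnt_fam * inv_se
            e = st.y_long - self._growth_pred(st)
            ok = gd.fam >= 0
            v[:, t8] += (
                np.bincount(gd.fam[ok], weights=e[ok], minlength=nf) * inv_se
            )
        C0inv = np.linalg.inv(st.comps.C0)
        G0inv = np.linalg.inv(st.comps.G0)
        fam = self.family_of
        rows = np.flatnonzero(fam >= 0)
        mu = self._parent_average(st.a, rows)
        dev = (st.a[rows] - mu) / self._dd[rows, None]
        h = np.zeros((nf, T))
        np.add.at(h, fam[rows], dev)
        g = np.bincount(fam[rows], weights=1.0 / self._dd[rows], minlength=nf)
        pinned = np.zeros(nf, dtype=bool)
        np.logical_or.at(pinned, fam[rows], self._is_parent[rows])
        g = np.where(pinned, 1e9, g)
        P = np.zeros((nf, 2 * T, 2 * T))
        P[:, :T, :T] = D + C0inv
        P[:, :T, T:] = D
        P[:, T:, :T] = D
        P[:, T:, T:] = D + g[:, None, None] * G0inv
        m = np.concatenate([v - st.c @ C0inv, v - h @ G0inv], axis=1)
        shift = np.linalg.solve(P, m[..., None])[..., 0]
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((nf, 2 * T, 1))
        noise = np.linalg.solve(np.swapaxes(L, 1, 2), z)[..., 0]
        x = shift + noise
        st.c += x[:, :T]
        st.a[rows] += x[fam[rows], T:]

    def sample_permanent_effects(self, st: ChainState, rng: np.random.Generator) -> None:
        """Blocked update of each SW fish's permanent effect r_k jointly with
        its own breeding value for the longitudinal trait (the records see
        only their sum); 2x2 Gaussian conditionals, vectorized over fish."""
        if self.growth is None:
            return
        gd = self.growth
        t8 = self.spec.longitudinal_index
        inv_se = 1.0 / st.comps.sigma_e_long
        inv_sr = 1.0 / st.comps.sigma_r
        G0inv = np.linalg.inv(st.comps.G0)
        e = st.y_long - self._growth_pred(st)
        v = np.bincount(gd.rfish, weights=e, minlength=gd.n_rfish) * inv_se
        D = gd.cnt_rfish * inv_se
        rows = self._fish_rows
        mu = self._parent_average(st.a, rows)
        dev = (st.a[rows] - mu) / self._dd[rows, None]
        h = dev @ G0inv[:, t8]
        ga = np.where(self._is_parent[rows], 1e9, G0inv[t8, t8] / self._dd[rows])
        # joint precision [[D + 1/sr, D], [D, D + ga]], rhs (v - r/sr, v - h)
        p11 = D + inv_sr
        p22 = D + ga
        det = p11 * p22 - D * D
        m1 = v - st.r * inv_sr
        m2 = v - h
        mean1 = (p22 * m1 - D * m2) / det
        mean2 = (p11 * m2 - D * m1) / det
        z1 = rng.standard_normal(gd.n_rfish)
        z2 = rng.standard_normal(gd.n_rfish)
        # noise via the lower Cholesky of the 2x2 precision
        l11 = np.sqrt(p11)
        l21 = D / l11
        l22 = np.sqrt(p22 - l21 * l21)
        n2 = z2 / l22
        n1 = (z1 - l21 * n2) / l11
        st.r += mean1 + n1
        st.a[rows, t8] += mean2 + n2

    def _accumulate_offspring_data(
        self, st: ChainState, group_of: np.ndarray, n_groups: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Data precision and R^-1-weighted residual sums per animal group
        (``group_of`` maps animal row -> group, -1 = ignore)."""
        T = self.spec.n_traits
        D = np.zeros((n_groups, T, T))
        v = np.zeros((n_groups, T))
        for bi, bd in enumerate(self.blocks):
            Rinv = np.linalg.inv(st.comps.R_blocks[bi])
            sl = slice(bd.off, bd.off + bd.k)
            grp = group_of[bd.anim]
            ok = grp >= 0
            cnt = np.bincount(grp[ok], minlength=n_groups).astype(float)
            D[:, sl, sl] += cnt[:, None, None] * Rinv
            E = self._block_resid(bd, st)
            np.add.at(v[:, sl], grp[ok], (E @ Rinv)[ok])
        if self.growth is not None:
            gd = self.growth
            t8 = self.spec.longitudinal_index
            inv_se = 1.0 / st.comps.sigma_e_long
            grp = group_of[gd.anim]
            ok = grp >= 0
            D[:, t8, t8] += np.bincount(grp[ok], minlength=n_groups) * inv_se
            e = st.y_long - self._growth_pred(st)
            v[:, t8] += np.bincount(grp[ok], weights=e[ok], minlength=n_groups) * inv_se
        return D, v

    def _founder_block_move(
        self, st: ChainState, rng: np.random.Generator, which: str
    ) -> None:
        """Blocked update of each founder's breeding value jointly with a
        common shift of its offspring's breeding values.

        The records see only the offspring values, while the pedigree prior
        ties offspring deviations to the parent average, so the founder value
        and its progeny mean are strongly anticorrelated; the joint draw
        removes that. Groups (one per sire or per dam) are disjoint in
        offspring and read the other parent's values only, so they are
        sampled in one vectorized batch.  Groups containing an offspring that
        is itself a parent are skipped (their progeny terms are not included).
        """
        T = self.spec.n_traits
        parent = self._si if which == "sire" else self._di
        founder_rows = np.unique(parent[parent >= 0])
        if founder_rows.size == 0:
            return
        n_g = founder_rows.size
        gid_of_founder = {int(p): g for g, p in enumerate(founder_rows)}
        group_of = np.full(self.n_animals, -1, dtype=np.int64)
        off = parent >= 0
        group_of[off] = [gid_of_founder[int(p)] for p in parent[off]]
        D, v = self._accumulate_offspring_data(st, group_of, n_g)
        G0inv = np.linalg.inv(st.comps.G0)
        rows = np.flatnonzero(off)
        grp = group_of[rows]
        mu = self._parent_average(st.a, rows)
        dev = (st.a[rows] - mu) / self._dd[rows, None]
        h = np.zeros((n_g, T))
        np.add.at(h, grp, dev)
        g = np.bincount(grp, weights=1.0 / self._dd[rows], minlength=n_g)
        skip = np.zeros(n_g, dtype=bool)
        np.logical_or.at(skip, grp, self._is_parent[rows])
        # joint precision over (delta_parent, delta_offspring)
        P = np.zeros((n_g, 2 * T, 2 * T))
        P[:, :T, :T] = (1.0 + 0.25 * g)[:, None, None] * G0inv
        P[:, :T, T:] = -0.5 * g[:, None, None] * G0inv
        P[:, T:, :T] = P[:, :T, T:]
        P[:, T:, T:] = D + g[:, None, None] * G0inv
        m = np.concatenate(
            [0.5 * h @ G0inv - st.a[founder_rows] @ G0inv, v - h @ G0inv], axis=1
        )
        shift = np.linalg.solve(P, m[..., None])[..., 0]
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((n_g, 2 * T, 1))
        x = shift + np.linalg.solve(np.swapaxes(L, 1, 2), z)[..., 0]
        x[skip] = 0.0
        st.a[founder_rows] += x[:, :T]
        st.a[rows] += x[grp, T:]

    def sample_location_effects(self, st: ChainState, rng: np.random.Generator) -> None:
        """One full location sweep in fixed order b, a, c, r, followed by
        the founder-level blocked moves."""
        self.sample_fixed(st, rng)
        self.sample_breeding_values(st, rng)
        self.sample_fullsib_effects(st, rng)
        self.sample_permanent_effects(st, rng)
        self._founder_block_move(st, rng, "sire")
        self._founder_block_move(st, rng, "dam")

    # -------------------------------------------------------------- variances
    def _draw_invwishart(self, df: float, scale: np.ndarray, rng) -> np.ndarray:
        jitter = 0.0
        for _ in range(6):
            try:
                draw = invwishart.rvs(df=df, scale=scale + jitter * np.eye(scale.shape[0]), random_state=rng)
                draw = np.atleast_2d(draw)
                np.linalg.cholesky(draw)
                return draw
            except np.linalg.LinAlgError:
                jitter = 1e-8 * np.trace(scale) if jitter == 0.0 else jitter * 10.0
                logger.warning("non-PD inverse-Wishart draw; retrying with jitter %.1e", jitter)
        raise RuntimeError("inverse-Wishart sampling failed repeatedly")

    def sample_variance_components(self, st: ChainState, rng: np.random.Generator) -> None:
        pr = self.priors
        # G0 | a  ~ IW(prior_df + n_animals, prior_scale + a' A^-1 a)
        S = st.a.T @ (self.ainv @ st.a)
        st.comps.G0 = self._draw_invwishart(pr.g_df + self.n_animals, pr.g_scale + S, rng)
        if self.spec.fullsib:
            Sc = st.c.T @ st.c
            st.comps.C0 = self._draw_invwishart(pr.c_df + self.n_families, pr.c_scale + Sc, rng)
        for bi, bd in enumerate(self.blocks):
            E = self._block_resid(bd, st)
            st.comps.R_blocks[bi] = self._draw_invwishart(
                pr.r_dfs[bi] + E.shape[0], pr.r_scales[bi] + E.T @ E, rng
            )
        if self.growth is not None:
            gd = self.growth
            e = st.y_long - self._growth_pred(st)
            sse = float(e @ e)
            df = pr.se_long_df + e.size
            st.comps.sigma_e_long = (pr.se_long_df * pr.se_long_s0 + sse) / rng.chisquare(df)
            ssr = float(st.r @ st.r)
            dfr = pr.sr_df + gd.n_rfish
            st.comps.sigma_r = (pr.sr_df * pr.sr_s0 + ssr) / rng.chisquare(dfr)

    # ------------------------------------------------------------------- run
    def sweep(self, st: ChainState, rng: np.random.Generator) -> None:
        self.augment_censored(st, rng)
        self.augment_missing(st, rng)
        self.sample_location_effects(st, rng)
        self.sample_variance_components(st, rng)
        st.iteration += 1

    def run_chain(self, config: ChainConfig) -> PosteriorChain:
        """Run the sampler, retaining every ``thinning``-th draw after the
        burn-in; deterministic given ``config.seed``."""
        rng = np.random.default_rng(config.seed)
        st = self.init_state()
        T = self.spec.n_traits
        m = config.n_retained
        G0d = np.empty((m, T, T))
        C0d = np.empty((m, T, T)) if self.spec.fullsib else None
        Rd = [np.empty((m, bd.k, bd.k)) for bd in self.blocks]
        sed = np.empty(m) if self.growth is not None else None
        srd = np.empty(m) if self.growth is not None else None
        if self.growth is not None:
            f0 = self.growth.factors[0]
            emd = np.empty((m, f0.n_levels))
            em_labels = list(f0.labels)
        else:
            emd, em_labels = None, []
        log_every = config.log_every or max(1, config.n_iterations // 20)
        j = 0
        for it in range(1, config.n_iterations + 1):
            self.sweep(st, rng)
            if it % config.thinning_interval == 0 and it > config.burn_in_iterations:
                G0d[j] = st.comps.G0
                if C0d is not None:
                    C0d[j] = st.comps.C0
                for bi in range(len(self.blocks)):
                    Rd[bi][j] = st.comps.R_blocks[bi]
                if self.growth is not None:
                    sed[j] = st.comps.sigma_e_long
                    srd[j] = st.comps.sigma_r
                    f0 = self.growth.factors[0]
                    emd[j] = (
                        np.bincount(f0.codes, weights=st.y_long, minlength=f0.n_levels)
                        / f0.cnt
                    )
                j += 1
            if it % log_every == 0 or it == config.n_iterations:
                st.check_finite()
                msg = f"iter {it}/{config.n_iterations}"
                if self.growth is not None:
                    t8 = self.spec.longitudinal_index
                    vp8 = (
                        st.comps.G0[t8, t8]
                        + (st.comps.C0[t8, t8] if st.comps.C0 is not None else 0.0)
                        + st.comps.sigma_e_long
                        + st.comps.sigma_r
                    )
                    msg += f"  h2(long)={st.comps.G0[t8, t8] / vp8:.3f}"
                logger.info(msg)
        assert j == m
        return PosteriorChain(
            trait_names=self.spec.trait_names,
            spec=self.spec,
            config=config,
            G0=G0d,
            C0=C0d,
            R_blocks=Rd,
            sigma_e_long=sed,
            sigma_r=srd,
            event_group_labels=em_labels,
            event_mean_draws=emd,
            n_records={
                **{bd.name: int(bd.y.shape[0]) for bd in self.blocks},
                **(
                    {"growth_rows": int(self.growth.y_obs.size)}
                    if self.growth is not None
                    else {}
                ),
            },
        )
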