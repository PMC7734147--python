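"""Model layout and (co)variance components for the multi-trait animal model.

The model is

    y = Xb + Za + Mc + [0; Sr] + e

with breeding values ``a ~ N(0, A (x) G0)``, common-fullsib effects
``c ~ N(0, I (x) C0)``, a scalar permanent (repeatability) effect
``r ~ N(0, I sigma_r^2)`` on the longitudinal trait only, and residuals that
are correlated within cross-sectional blocks but independent between blocks
and independent per record for the longitudinal trait.

Traits are organized as a list of cross-sectional blocks (each block is a set
of trait columns recorded together on the same rows, sharing a residual
covariance) plus at most one left-censored longitudinal trait.  The standard
eight-trait layout is: an SA block (FF, FP, VF, GR at the same age), an SW
quality block (FF, FP, VF at slaughter), and longitudinal growth rate GR_SW.
Bivariate sub-models for the pre-correction study use the same machinery with
one- or two-trait blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical eight-trait order.
EIGHT_TRAITS = ("FF_SA", "FP_SA", "VF_SA", "GR_SA", "FF_SW", "FP_SW", "VF_SW", "GR_SW")


@dataclass
class CrossSectionalBlock:
    """Traits recorded together on one set of rows with a shared residual
    covariance. ``traits`` are phenotype-table column names; ``factors`` are
    the columns whose combination forms the block's single fixed factor."""

    name: str
    group: str  # which phenotype group ("SA" or "SW") carries the rows
    traits: list[str]
    factors: list[str] = field(default_factory=lambda: ["year_class", "tank", "sex"])

    @property
    def k(self) -> int:
        return len(self.traits)


@dataclass
class LongitudinalSpec:
    """The single left-censored longitudinal trait (growth rate, g/day).

    ``factors`` are additive fixed factors on the growth-record table (after
    joining phenotype columns); the first factor carries the level means, the
    rest are corner-point constrained (first level fixed at zero).
    """

    trait: str = "GR_SW"
    factors: list[str] = field(default_factory=lambda: ["sampling_group", "sex"])


@dataclass
class ModelSpec:
    """Trait layout of one model instance."""

    blocks: list[CrossSectionalBlock]
    longitudinal: LongitudinalSpec | None = None
    fullsib: bool = True  # include the common-fullsib effect c

    @property
    def trait_names(self) -> list[str]:
        names = []
        for b in self.blocks:
            names += [f"{t}_{b.group}" if not t.endswith(("_SA", "_SW")) else t for t in b.traits]
        if self.longitudinal is not None:
            names.append(self.longitudinal.trait)
        return names

    @property
    def n_traits(self) -> int:
        return sum(b.k for b in self.blocks) + (1 if self.longitudinal is not None else 0)

    @property
    def block_offsets(self) -> list[int]:
        offs, o = [], 0
        for b in self.blocks:
            offs.append(o)
            o += b.k
        return offs

    @property
    def longitudinal_index(self) -> int | None:
        return self.n_traits - 1 if self.longitudinal is not None else None

    @classmethod
    def eight_trait(cls) -> "ModelSpec":
        return cls(
            blocks=[
                CrossSectionalBlock("SA", "SA", ["FF", "FP", "VF", "GR"]),
                CrossSectionalBlock("SWq", "SW", ["FF", "FP", "VF"]),
            ],
            longitudinal=LongitudinalSpec(),
        )

    @classmethod
    def bivariate(cls, trait_x: str, trait_y: str) -> "ModelSpec":
        """Two-trait sub-model. Traits are named like ``FF_SA``/``preFF_SA``/
        ``GR_SW``; ``GR_SW`` is modeled longitudinally, everything else
        cross-sectionally (same-block if recorded on the same rows)."""

        def parse(t):
            base, grp = t.rsplit("_", 1)
            return base, grp

        bx, gx = parse(trait_x)
        if trait_y == "GR_SW":
            return cls(
                blocks=[CrossSectionalBlock(gx, gx, [bx])],
                longitudinal=LongitudinalSpec(),
            )
        by, gy = parse(trait_y)
        if gx == gy:
            return cls(blocks=[CrossSectionalBlock(gx, gx, [bx, by])])
        return cls(
            blocks=[
                CrossSectionalBlock(gx, gx, [bx]),
                CrossSectionalBlock(gy, gy, [by]),
            ]
        )


def _check_spd(M: np.ndarray, name: str) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    ev = np.linalg.eigvalsh(M)
    if ev[0] <= 0:
        raise ValidationError(f"{name} is not positive definite (min eigenvalue {ev[0]:.3g})")


@dataclass
class VarianceComponents:
    """All (co)variance components of one model instance.

    ``G0``/``C0`` are T x T; ``R_blocks`` aligns with the layout's blocks;
    ``sigma_e_long``/``sigma_r`` are the longitudinal residual and
    repeatability variances ((g/day)^2), ``None`` when there is no
    longitudinal trait.  ``C0`` may be ``None`` when the model has no
    common-fullsib effect.
    """

    G0: np.ndarray
    C0: np.ndarray | None
    R_blocks: list[np.ndarray]
    sigma_e_long: float | None = None
    sigma_r: float | None = None
    trait_names: list[str] = field(default_factory=list)

    def validate(self, spec: ModelSpec | None = None) -> None:
        _check_spd(self.G0, "G0")
        if self.C0 is not None:
            _check_spd(self.C0, "C0")
        for i, R in enumerate(self.R_blocks):
            _check_spd(R, f"R_blocks[{i}]")
        for nm, s in (("sigma_e_long", self.sigma_e_long), ("sigma_r", self.sigma_r)):
            if s is not None and s <= 0:
                raise ValidationError(f"{nm} must be > 0, got {s}")
        if spec is not None:
            T = spec.n_traits
            if self.G0.shape != (T, T):
                raise ValidationError(f"G0 shape {self.G0.shape} does not match {T} traits")
            for b, R in zip(spec.blocks, self.R_blocks):
                if np.asarray(R).shape != (b.k, b.k):
                    raise ValidationError(f"residual block {b.name} must be {b.k}x{b.k}")
            if (spec.longitudinal is not None) != (self.sigma_e_long is not None):
                raise ValidationError("longitudinal residual variance missing or superfluous")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            G0=self.G0.copy(),
            C0=None if self.C0 is None else self.C0.copy(),
            R_blocks=[R.copy() for R in self.R_blocks],
            sigma_e_long=self.sigma_e_long,
            sigma_r=self.sigma_r,
            trait_names=list(self.trait_names),
        )

    def phenotypic_variances(self, spec: ModelSpec) -> np.ndarray:
        """sigma_p^2 per trait: additive + fullsib + residual (+ repeatability
        for the longitudinal trait)."""
        T = spec.n_traits
        vp = np.diag(self.G0).copy()
        if self.C0 is not None:
            vp += np.diag(self.C0)
        for off, b, R in zip(spec.block_offsets, spec.blocks, self.R_blocks):
            vp[off : off + b.k] += np.diag(R)
        if spec.longitudinal is not None:
            vp[T - 1] += self.sigma_e_long + self.sigma_r
        return vp


def _corr_to_cov(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return corr * np.outer(sd, sd)


def _lower_to_full(lower: list[float], n: int) -> np.ndarray:
    M = np.eye(n)
    k = 0
    for i in range(1, n):
        for j in range(i):
            M[i, j] = M[j, i] = lower[k]
            k += 1
    return M


# --- published point estimates used as the generator's true values ---------
# heritabilities / fullsib proportions, trait order EIGHT_TRAITS
H2_TRUE = np.array([0.23, 0.11, 0.37, 0.33, 0.20, 0.16, 0.35, 0.35])
C2_TRUE = np.array([0.12, 0.07, 0.06, 0.12, 0.05, 0.08, 0.06, 0.14])
# genetic correlations (below-diagonal, row by row)
RG_TRUE = _lower_to_full(
    [
        -0.37,
        -0.12, 0.08,
        0.59, -0.33, -0.13,
        0.45, -0.03, -0.17, -0.35,
        0.26, 0.13, 0.09, 0.58, -0.38,
        -0.14, 0.06, 0.86, 0.14, -0.45, 0.16,
        0.44, -0.31, -0.09, 0.91, -0.45, 0.62, 0.19,
    ],
    8,
)
# fullsib-effect correlations
RC_TRUE = _lower_to_full(
    [
        -0.59,
        0.21, -0.19,
        0.77, -0.37, 0.17,
        0.50, -0.36, -0.07, -0.03,
        0.12, 0.31, 0.06, 0.39, -0.34,
        0.16, -0.12, 0.70, 0.33, -0.28, 0.06,
        0.65, -0.34, 0.21, 0.87, -0.11, 0.48, 0.38,
    ],
    8,
)
# residual correlations within the SA block (FF, FP, VF, GR) ...
RE_SA_TRUE = _lower_to_full([-0.35, 0.04, -0.08, 0.69, -0.16, -0.21], 4)
# ... and within the SW quality block (FF, FP, VF)
RE_SW_TRUE = _lower_to_full([-0.20, -0.05, -0.13], 3)

#: Phenotypic variances (trait units^2), chosen to match the published
#: descriptive statistics (means and CVs): FF in %, FP in mg/kg, VF in %,
#: GR in g/day.
VP_TRUE = np.array([3.2, 0.72, 1.2, 1.25, 1.9, 0.72, 1.6, 1.0])

#: Of the non-genetic, non-fullsib share of GR_SW variance, the fraction that
#: is the permanent (repeatability) effect: a fish's growth rate is highly
#: consistent between events, so most of it is permanent.
REPEATABILITY_SHARE = 0.70


def paper_like_components() -> VarianceComponents:
    """True components for the eight-trait model, built from the published
    heritabilities, variance proportions and correlations."""
    sd_a = np.sqrt(H2_TRUE * VP_TRUE)
    sd_c = np.sqrt(C2_TRUE * VP_TRUE)
    G0 = _corr_to_cov(sd_a, RG_TRUE)
    C0 = _corr_to_cov(sd_c, RC_TRUE)
    ve = (1.0 - H2_TRUE - C2_TRUE) * VP_TRUE
    R_sa = _corr_to_cov(np.sqrt(ve[:4]), RE_SA_TRUE)
    R_sw = _corr_to_cov(np.sqrt(ve[4:7]), RE_SW_TRUE)
    sigma_r = REPEATABILITY_SHARE * ve[7]
    sigma_e = (1.0 - REPEATABILITY_SHARE) * ve[7]
    comps = VarianceComponents(
        G0=G0,
        C0=C0,
        R_blocks=[R_sa, R_sw],
        sigma_e_long=float(sigma_e),
        sigma_r=float(sigma_r),
        trait_names=list(EIGHT_TRAITS),
    )
    comps.validate(ModelSpec.eight_trait())
    return comps
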