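"""Synthetic salmon populations with sequential weight-threshold slaughter.

The generator emulates the statistical structure the eight-trait animal model
assumes: a nested mating design (each dam mated to one sire, each sire to at
most two dams), fullsib families split at random into an SA group (all fish
slaughtered at one common age) and an SW group (the largest fish slaughtered
at five threshold events and the remainder at a sixth), Gaussian additive /
fullsib / permanent / residual effects with a configurable covariance
structure, and carcass-quality traits observed only at slaughter.

Growth is linear from first feeding with zero intercept (BW = GR x age), the
minimal model consistent with defining growth rate as body weight divided by
days from first feeding; no growth curve beyond that is imposed.  Units are
fixed internally as grams, days and g/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError
from .model import VarianceComponents, paper_like_components
from .pedigree import Pedigree, inbreeding_coefficients


@dataclass(frozen=True)
class SlaughterEvent:
    index: int
    age_days: float
    threshold_g: float | None  # None on the final (slaughter-all) event


@dataclass(frozen=True)
class SlaughterSchedule:
    """Ordered slaughter events plus an initial all-fish weighing.

    Events 1..J-1 carry a weight threshold (only fish at or above it are
    slaughtered); the final event has none and slaughters every survivor.
    The baseline weighing at ``baseline_age_days`` records every fish once,
    which is why each fish ends up with at least two growth rows.
    """

    events: tuple[SlaughterEvent, ...]
    baseline_age_days: float | None = 700.0

    def __post_init__(self):
        ages = [e.age_days for e in self.events]
        if self.baseline_age_days is not None:
            ages = [self.baseline_age_days] + ages
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise DesignError("slaughter-event ages must be strictly increasing")
        if any(e.threshold_g is None for e in self.events[:-1]):
            raise DesignError("all events but the final one need a weight threshold")
        if self.events[-1].threshold_g is not None:
            raise DesignError("the final event slaughters all remaining fish; no threshold")
        if [e.index for e in self.events] != list(range(1, len(self.events) + 1)):
            raise DesignError("event indices must run 1..J")

    @classmethod
    def paper_like(cls) -> "SlaughterSchedule":
        """Six events at the year-class-1 published ages: 4.2 kg threshold at
        the first event, 4.4 kg at events 2-5, everything slaughtered at 6."""
        ages = (805.0, 840.0, 861.0, 887.0, 923.0, 958.0)
        thr = (4200.0, 4400.0, 4400.0, 4400.0, 4400.0, None)
        return cls(
            events=tuple(
                SlaughterEvent(i + 1, a, t) for i, (a, t) in enumerate(zip(ages, thr))
            ),
            baseline_age_days=700.0,
        )


@dataclass
class FixedEffectValues:
    """True fixed-effect sizes (trait units).

    ``trait_means[t, yc]`` is the mean of trait ``t`` in year class ``yc``;
    ``sex_effects[t]`` is added for males; ``gr_event_slope`` is the decline
    in the latent mean growth rate per slaughter-event index (g/day), a mild
    age trend on top of which all the apparent decline in observed means is
    produced by the threshold selection itself.
    """

    trait_means: np.ndarray
    sex_effects: np.ndarray
    gr_event_slope: float = 0.05

    @classmethod
    def paper_like(cls, n_year_classes: int = 2) -> "FixedEffectValues":
        means = np.array(
            [
                [13.8, 17.3],  # FF_SA, %
                [7.3, 7.5],  # FP_SA, mg/kg
                [6.1, 5.3],  # VF_SA, %
                [4.96, 4.47],  # GR_SA, g/day
                [14.4, 16.0],  # FF_SW, %
                [7.2, 7.4],  # FP_SW, mg/kg
                [7.7, 6.5],  # VF_SW, %
                [5.10, 4.60],  # GR_SW latent base, g/day
            ]
        )[:, :n_year_classes]
        sex = np.array([0.2, 0.05, 0.1, 0.15, 0.2, 0.05, 0.1, 0.15])
        return cls(trait_means=means, sex_effects=sex)


@dataclass
class SimulationDesign:
    """Everything that defines one synthetic population."""

    n_sires: int = 120
    n_dams: int = 206
    offspring_per_family_sa: int = 12
    offspring_per_family_sw: int = 14
    n_year_classes: int = 2
    n_sw_tanks_per_yc: int = 1
    schedule: SlaughterSchedule = field(default_factory=SlaughterSchedule.paper_like)
    true_components: VarianceComponents = field(default_factory=paper_like_components)
    fixed_effects: FixedEffectValues | None = None
    sa_age_days: tuple[float, ...] = (896.0, 1031.0)
    mortality_rate: float = 0.05
    below_threshold_fraction: float = 0.30
    below_threshold_band: float = 0.05
    missing_rate: float = 0.005
    seed: int = 20201130

    def __post_init__(self):
        if self.fixed_effects is None:
            self.fixed_effects = FixedEffectValues.paper_like(self.n_year_classes)
        if min(self.n_sires, self.n_dams, self.offspring_per_family_sa,
               self.offspring_per_family_sw, self.n_year_classes) <= 0:
            raise DesignError("all design counts must be positive")
        if self.n_dams < self.n_sires:
            raise DesignError("nested design requires n_dams >= n_sires")
        if self.n_dams > 2 * self.n_sires:
            raise DesignError(
                f"nested design infeasible: {self.n_dams} dams cannot be covered by "
                f"{self.n_sires} sires at <= 2 dams per sire"
            )
        if len(self.sa_age_days) < self.n_year_classes:
            raise DesignError("need one SA slaughter age per year class")

    def scaled(self, **kw) -> "SimulationDesign":
        return replace(self, **kw)


@dataclass
class SimulatedPedigree:
    pedigree: Pedigree  # sorted, founders first
    animals: pd.DataFrame  # per offspring: animal, family, year_class, group, sex, tank
    families: pd.DataFrame  # family, sire, dam, year_class


@dataclass
class GeneticEffects:
    a: np.ndarray  # (n_animals, T) breeding values, rows follow pedigree order
    c: np.ndarray  # (n_families, T) common-fullsib effects
    r: np.ndarray  # per-SW-fish permanent growth effect, aligned to sw_animal_rows
    sw_animal_rows: np.ndarray  # pedigree row index of each SW fish


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent child streams per logical component of the simulation."""
    ss = np.random.SeedSequence(seed)
    names = ["pedigree", "genetics", "residuals", "mortality", "missing"]
    return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


def simulate_pedigree(design: SimulationDesign, rng: np.random.Generator | None = None) -> SimulatedPedigree:
    """Founders plus offspring under the nested 1-sire-per-dam mating design.

    Dams are assigned one per sire first; the surplus dams become second
    mates, so every sire has one or two dams.  Each family's offspring are
    divided at random between the SA and SW groups at the design's sizes.
    """
    rng = rng if rng is not None else _streams(design.seed)["pedigree"]
    ns, nd = design.n_sires, design.n_dams
    sires = [f"S{i + 1:04d}" for i in range(ns)]
    dams = [f"D{i + 1:04d}" for i in range(nd)]
    sire_of_dam = list(range(ns)) + list(range(nd - ns))

    fam_rows = []
    for f, (dam_i, sire_i) in enumerate(zip(range(nd), sire_of_dam)):
        fam_rows.append(
            {
                "family": f,
                "sire": sires[sire_i],
                "dam": dams[dam_i],
                "year_class": sire_i % design.n_year_classes,
            }
        )
    families = pd.DataFrame(fam_rows)

    n_off = design.offspring_per_family_sa + design.offspring_per_family_sw
    animal, sire_col, dam_col, rows = [], [], [], []
    k = 0
    for fr in fam_rows:
        yc = fr["year_class"]
        groups = ["SA"] * design.offspring_per_family_sa + ["SW"] * design.offspring_per_family_sw
        groups = list(rng.permutation(groups))
        for g in groups:
            k += 1
            aid = f"A{k:06d}"
            animal.append(aid)
            sire_col.append(fr["sire"])
            dam_col.append(fr["dam"])
            if g == "SW":
                tank = f"SW{int(rng.integers(design.n_sw_tanks_per_yc)) + 1}-yc{yc + 1}"
            else:
                tank = f"SA-yc{yc + 1}"
            rows.append(
                {
                    "animal": aid,
                    "family": fr["family"],
                    "year_class": yc,
                    "group": g,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "tank": tank,
                }
            )
    ped = Pedigree(
        animal=sires + dams + animal,
        sire=[""] * (ns + nd) + sire_col,
        dam=[""] * (ns + nd) + dam_col,
        is_sorted=True,
    )
    assert n_off * nd == len(rows)
    return SimulatedPedigree(pedigree=ped, animals=pd.DataFrame(rows), families=families)


def simulate_genetic_effects(
    sim_ped: SimulatedPedigree,
    comps: VarianceComponents,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> GeneticEffects:
    """Draw a ~ N(0, A (x) G0) by pedigree recursion, c ~ N(0, I (x) C0) and
    the per-SW-fish permanent effects r ~ N(0, sigma_r^2).

    The recursion (founders from N(0, G0); offspring = parent average plus a
    Mendelian-sampling deviation scaled by parental inbreeding) realizes the
    A (x) G0 covariance without ever factorizing A.
    """
    comps.validate()
    if rng is None:
        rng = np.random.default_rng(seed) if seed is not None else _streams(0)["genetics"]
    ped = sim_ped.pedigree
    si, di = ped.parent_indices()
    F = inbreeding_coefficients(ped)
    T = comps.G0.shape[0]
    Lg = np.linalg.cholesky(comps.G0)
    n = len(ped)
    z = rng.standard_normal((n, T))
    a = np.empty((n, T))
    for i in range(n):
        s, d = si[i], di[i]
        mend = Lg @ z[i]
        if s < 0 and d < 0:
            a[i] = mend
        elif s >= 0 and d >= 0:
            a[i] = 0.5 * (a[s] + a[d]) + np.sqrt(0.5 - 0.25 * (F[s] + F[d])) * mend
        else:
            p = s if s >= 0 else d
            a[i] = 0.5 * a[p] + np.sqrt(0.75 - 0.25 * F[p]) * mend

    n_fam = len(sim_ped.families)
    if comps.C0 is not None:
        c = rng.standard_normal((n_fam, T)) @ np.linalg.cholesky(comps.C0).T
    else:
        c = np.zeros((n_fam, T))

    pos = {aid: i for i, aid in enumerate(ped.animal)}
    sw = sim_ped.animals.loc[sim_ped.animals["group"] == "SW", "animal"]
    sw_rows = np.array([pos[aid] for aid in sw], dtype=np.int64)
    sigma_r = comps.sigma_r if comps.sigma_r is not None else 0.0
    r = np.sqrt(sigma_r) * rng.standard_normal(sw_rows.size)
    return GeneticEffects(a=a, c=c, r=r, sw_animal_rows=sw_rows)


def simulate_growth_and_slaughter(
    sim_ped: SimulatedPedigree,
    effects: GeneticEffects,
    design: SimulationDesign,
    rng_resid: np.random.Generator,
    rng_mort: np.random.Generator,
    rng_miss: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the slaughter protocol; returns (growth records, phenotypes, truth).

    SW fish receive a fresh latent growth rate at every event (fixed effects
    + breeding value + fullsib + permanent + event residual); body weight is
    growth rate times age.  Fish at or above the event threshold are
    slaughtered and acquire the three quality traits with the SW residual
    covariance; of the unslaughtered fish within ``below_threshold_band`` of
    the threshold, a ``below_threshold_fraction`` share get an ordinary
    observed (not slaughtered) record; everyone else contributes a censored
    row bounded by threshold/age.  Survivors are all slaughtered at the final
    event.  SA fish get the four cross-sectional traits at one common age.

    The truth table holds, per year class and event, the mean latent growth
    rate over *all* fish alive at that event -- the quantity the censored
    model's estimated event means should recover.
    """
    comps = design.true_components
    fe = design.fixed_effects
    ped = sim_ped.pedigree
    pos = {aid: i for i, aid in enumerate(ped.animal)}
    animals = sim_ped.animals
    T = comps.G0.shape[0]
    if T != 8:
        raise ValidationError("the generator expects the eight-trait layout")
    t8 = 7

    Lsa = np.linalg.cholesky(comps.R_blocks[0])
    Lsw = np.linalg.cholesky(comps.R_blocks[1])
    se = np.sqrt(comps.sigma_e_long)

    events = design.schedule.events
    n_events = len(events)
    growth_rows: list[dict] = []
    pheno_rows: list[dict] = []
    truth_acc: dict[tuple[int, int], list[float]] = {}

    r_of = dict(zip(effects.sw_animal_rows.tolist(), effects.r.tolist()))

    for rec in animals.itertuples(index=False):
        i = pos[rec.animal]
        yc = rec.year_class
        fam = rec.family
        sexe = fe.sex_effects * (1.0 if rec.sex == "M" else 0.0)
        base = fe.trait_means[:, yc] + sexe + effects.a[i] + effects.c[fam]

        if rec.group == "SA":
            age = design.sa_age_days[yc]
            y = base[:4] + Lsa @ rng_resid.standard_normal(4)
            miss = rng_miss.random(4) < design.missing_rate
            vals = [np.nan if m else v for v, m in zip(y, miss)]
            gr = vals[3]
            pheno_rows.append(
                {
                    "animal": rec.animal,
                    "group": "SA",
                    "year_class": f"yc{yc + 1}",
                    "tank": rec.tank,
                    "sex": rec.sex,
                    "age_days": age,
                    "body_weight_kg": (gr * age / 1000.0) if np.isfinite(gr or np.nan) else np.nan,
                    "FF": vals[0],
                    "FP": vals[1],
                    "VF": vals[2],
                    "GR": gr,
                }
            )
            continue

        # --- SW fish ------------------------------------------------------
        r_i = r_of[i]
        dead_at = 0
        if rng_mort.random() < design.mortality_rate:
            dead_at = int(rng_mort.integers(1, n_events + 1))
        fish_level = base[t8] + r_i

        def latent_gr(event_idx: int) -> float:
            return (
                fish_level
                - fe.gr_event_slope * event_idx
                + se * rng_resid.standard_normal()
            )

        if design.schedule.baseline_age_days is not None:
            g0 = latent_gr(0)
            growth_rows.append(
                {
                    "animal": rec.animal,
                    "event_index": 0,
                    "age_days": design.schedule.baseline_age_days,
                    "body_weight_g": g0 * design.schedule.baseline_age_days,
                    "threshold_g": np.nan,
                    "status": "observed_below_threshold",
                    "sampling_group": f"yc{yc + 1}:ev0",
                }
            )
            truth_acc.setdefault((yc, 0), []).append(g0)

        slaughtered = False
        for ev in events:
            if dead_at == ev.index:
                growth_rows.append(
                    {
                        "animal": rec.animal,
                        "event_index": ev.index,
                        "age_days": ev.age_days,
                        "body_weight_g": np.nan,
                        "threshold_g": np.nan,
                        "status": "dead",
                        "sampling_group": f"yc{yc + 1}:ev{ev.index}",
                    }
                )
                break
            g = latent_gr(ev.index)
            bw = g * ev.age_days
            truth_acc.setdefault((yc, ev.index), []).append(g)
            sg = f"yc{yc + 1}:ev{ev.index}"
            if ev.threshold_g is None or bw >= ev.threshold_g:
                growth_rows.append(
                    {
                        "animal": rec.animal,
                        "event_index": ev.index,
                        "age_days": ev.age_days,
                        "body_weight_g": bw,
                        "threshold_g": ev.threshold_g if ev.threshold_g is not None else np.nan,
                        "status": "observed_slaughtered",
                        "sampling_group": sg,
                    }
                )
                q = base[4:7] + Lsw @ rng_resid.standard_normal(3)
                qmiss = rng_miss.random(3) < design.missing_rate
                qv = [np.nan if m else v for v, m in zip(q, qmiss)]
                pheno_rows.append(
                    {
                        "animal": rec.animal,
                        "group": "SW",
                        "year_class": f"yc{yc + 1}",
                        "tank": rec.tank,
                        "sex": rec.sex,
                        "age_days": ev.age_days,
                        "body_weight_kg": bw / 1000.0,
                        "FF": qv[0],
                        "FP": qv[1],
                        "VF": qv[2],
                        "GR": g,
                    }
                )
                slaughtered = True
                break
            in_band = bw >= (1.0 - design.below_threshold_band) * ev.threshold_g
            if in_band and rng_mort.random() < design.below_threshold_fraction:
                growth_rows.append(
                    {
                        "animal": rec.animal,
                        "event_index": ev.index,
                        "age_days": ev.age_days,
                        "body_weight_g": bw,
                        "threshold_g": ev.threshold_g,
                        "status": "observed_below_threshold",
                        "sampling_group": sg,
                    }
                )
            else:
                growth_rows.append(
                    {
                        "animal": rec.animal,
                        "event_index": ev.index,
                        "age_days": ev.age_days,
                        "body_weight_g": np.nan,
                        "threshold_g": ev.threshold_g,
                        "status": "censored_alive",
                        "sampling_group": sg,
                    }
                )
        if not slaughtered and dead_at == 0:
            # cannot happen: the final event has no threshold
            raise RuntimeError("fish neither slaughtered nor dead")
        if not slaughtered:
            # dead fish still need a phenotype row for sex/tank joins
            pheno_rows.append(
                {
                    "animal": rec.animal,
                    "group": "SW",
                    "year_class": f"yc{yc + 1}",
                    "tank": rec.tank,
                    "sex": rec.sex,
                    "age_days": np.nan,
                    "body_weight_kg": np.nan,
                    "FF": np.nan,
                    "FP": np.nan,
                    "VF": np.nan,
                    "GR": np.nan,
                }
            )

    growth = pd.DataFrame(growth_rows)
    growth["growth_rate"] = growth["body_weight_g"] / growth["age_days"]
    growth["upper_bound"] = np.where(
        growth["status"] == "censored_alive",
        growth["threshold_g"] / growth["age_days"],
        np.nan,
    )
    pheno = pd.DataFrame(pheno_rows)
    truth = pd.DataFrame(
        [
            {
                "year_class": f"yc{yc + 1}",
                "event_index": ev,
                "n_alive": len(v),
                "true_mean_gr": float(np.mean(v)),
                "true_sd_gr": float(np.std(v)),
            }
            for (yc, ev), v in sorted(truth_acc.items())
        ]
    )
    return growth, pheno, truth


def count_records(growth: pd.DataFrame) -> dict[str, dict[int, int]]:
    """Histograms of rows per fish: observed only, and observed + censored.

    Dead-marker rows are not records and are excluded.  Counts in each
    histogram sum to the number of fish with at least one such record.
    """
    if len(growth) == 0:
        return {"observed": {}, "observed_and_censored": {}}
    obs = growth[growth["status"].str.startswith("observed")]
    both = growth[growth["status"] != "dead"]
    out = {}
    for name, df in (("observed", obs), ("observed_and_censored", both)):
        per_fish = df.groupby("animal").size()
        out[name] = {int(k): int(v) for k, v in per_fish.value_counts().sort_index().items()}
    return out


@dataclass
class SimulatedPopulation:
    design: SimulationDesign
    pedigree: Pedigree
    animals: pd.DataFrame
    families: pd.DataFrame
    effects: GeneticEffects
    phenotypes: pd.DataFrame
    growth: pd.DataFrame
    truth: pd.DataFrame


def simulate_population(design: SimulationDesign) -> SimulatedPopulation:
    """Full generator pipeline: pedigree -> effects -> growth and slaughter.

    One independent child RNG stream per logical component (pedigree,
    genetics, residuals, mortality, missingness), all derived from
    ``design.seed``, so each component is reproducible in isolation.
    """
    streams = _streams(design.seed)
    sp = simulate_pedigree(design, streams["pedigree"])
    eff = simulate_genetic_effects(sp, design.true_components, streams["genetics"])
    growth, pheno, truth = simulate_growth_and_slaughter(
        sp, eff, design, streams["residuals"], streams["mortality"], streams["missing"]
    )
    return SimulatedPopulation(
        design=design,
        pedigree=sp.pedigree,
        animals=sp.animals,
        families=sp.families,
        effects=eff,
        phenotypes=pheno,
        growth=growth,
        truth=truth,
    )
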