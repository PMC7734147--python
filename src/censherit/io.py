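"""CSV readers/writers, validation and run configuration.

All tables are plain comma-separated UTF-8 with a header and ``.`` decimals;
missing values are empty cells.  Readers validate and reject rather than
silently coerce, and every error message names the file, row and column.
Weights are grams and ages integer days from first feeding internally;
phenotype body weights are carried in kg (matching how slaughter weights are
reported) and converted where needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .gibbs import OBSERVED_STATUSES, ChainConfig, ModelSpec, PosteriorChain
from .pedigree import Pedigree

GROWTH_STATUSES = OBSERVED_STATUSES + ("censored_alive", "dead")
TRAIT_COLUMNS = ("FF", "FP", "VF", "GR")


def compute_growth_rate(body_weight_g: float, age_days: float) -> float:
    """Growth rate in g/day: round body weight divided by days from first
    feeding.  Exact division; any rounding happens at presentation only."""
    if age_days <= 0:
        raise ValidationError(f"age must be positive, got {age_days}")
    if body_weight_g < 0:
        raise ValidationError(f"body weight must be >= 0, got {body_weight_g}")
    return body_weight_g / age_days


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, row {row + 2}"
        )
    return out


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Cross-sectional phenotype table: one row per fish, columns ``animal,
    group, year_class, tank, sex`` plus trait columns (blank = missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.mask(df == "")
    required = ["animal", "group", "year_class", "tank", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: phenotype table lacks columns {missing}")
    known_extra = {"age_days", "body_weight_kg"}
    for col in df.columns:
        if col in required:
            continue
        if col in known_extra or col in TRAIT_COLUMNS or col.startswith("pre"):
            df[col] = _numeric(df, col, path)
        else:
            raise ValidationError(f"{path}: unknown column {col!r} in phenotype table")
    bad_group = ~df["group"].isin(["SA", "SW"])
    if bad_group.any():
        row = int(np.flatnonzero(bad_group)[0])
        raise ValidationError(
            f"{path}: unknown group {df['group'].iloc[row]!r} in row {row + 2}"
        )
    dup = df.duplicated(subset=["animal", "group"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValidationError(
            f"{path}: duplicate animal {df['animal'].iloc[row]!r} within group "
            f"{df['group'].iloc[row]!r} (row {row + 2})"
        )
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_growth_records(path) -> pd.DataFrame:
    """Longitudinal growth-record table, one row per fish × event.

    On load, observed rows get ``growth_rate = body_weight_g / age_days`` and
    censored rows ``upper_bound = threshold_g / age_days``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.mask(df == "")
    required = ["animal", "event_index", "age_days", "body_weight_g", "threshold_g", "status", "sampling_group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: growth-record table lacks columns {missing}")
    for col in ("event_index", "age_days", "body_weight_g", "threshold_g"):
        df[col] = _numeric(df, col, path)
    bad = ~df["status"].isin(GROWTH_STATUSES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: unknown status {df['status'].iloc[row]!r} in row {row + 2}; "
            f"expected one of {GROWTH_STATUSES}"
        )
    live = df["status"] != "dead"
    bad_age = live & ~(df["age_days"] > 0)
    if bad_age.any():
        row = int(np.flatnonzero(bad_age)[0])
        raise ValidationError(f"{path}: non-positive age_days in row {row + 2}")
    obs = df["status"].isin(OBSERVED_STATUSES)
    if (obs & df["body_weight_g"].isna()).any():
        row = int(np.flatnonzero(obs & df["body_weight_g"].isna())[0])
        raise ValidationError(f"{path}: observed row without a body weight (row {row + 2})")
    cens = df["status"] == "censored_alive"
    if (cens & df["threshold_g"].isna()).any():
        row = int(np.flatnonzero(cens & df["threshold_g"].isna())[0])
        raise ValidationError(f"{path}: censored row without a threshold (row {row + 2})")
    df["growth_rate"] = df["body_weight_g"] / df["age_days"]
    df["upper_bound"] = np.where(cens, df["threshold_g"] / df["age_days"], np.nan)
    return df


def write_growth_records(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c not in ("growth_rate", "upper_bound")]
    df[cols].to_csv(path, index=False)


def count_below_threshold_records(
    growth: pd.DataFrame, event_index: int, sampling_group: str | None = None
) -> int:
    """Number of fish weighed but not slaughtered at an event: rows with
    status ``observed_below_threshold``.  When the table mirrors published
    per-event accounting this equals recorded minus slaughtered."""
    sel = growth["event_index"] == event_index
    if sampling_group is not None:
        sel &= growth["sampling_group"] == sampling_group
    if not sel.any():
        raise ValidationError(f"no growth records at event {event_index}"
                              + (f" in group {sampling_group!r}" if sampling_group else ""))
    return int((growth.loc[sel, "status"] == "observed_below_threshold").sum())


# --------------------------------------------------------------------------
# Run configuration and simulation output
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    pedigree: str = "pedigree.csv"
    phenotypes: str = "phenotypes.csv"
    growth_records: str = "growth_records.csv"
    out_dir: str = "censherit_out"
    chain: ChainConfig = field(default_factory=ChainConfig)
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        chain = ChainConfig(**raw.pop("chain", {}))
        return cls(chain=chain, **raw)

    def validate_inputs(self) -> None:
        for p in (self.pedigree, self.phenotypes, self.growth_records):
            if not Path(p).exists():
                raise ValidationError(f"input file {p} does not exist")


def write_provenance(out_dir, seed: int, payload: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(
        json.dumps({"seed": seed, **payload}, indent=2, default=str)
    )


def save_simulation(pop, out_dir) -> None:
    """Write a simulated population as the three model-input CSVs plus the
    truth table and a provenance file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree(pop.pedigree, out / "pedigree.csv")
    write_phenotypes(pop.phenotypes, out / "phenotypes.csv")
    write_growth_records(pop.growth, out / "growth_records.csv")
    pop.truth.to_csv(out / "true_event_means.csv", index=False)
    d = pop.design
    write_provenance(
        out,
        d.seed,
        {
            "design": {
                "n_sires": d.n_sires,
                "n_dams": d.n_dams,
                "offspring_per_family_sa": d.offspring_per_family_sa,
                "offspring_per_family_sw": d.offspring_per_family_sw,
                "n_year_classes": d.n_year_classes,
                "mortality_rate": d.mortality_rate,
                "below_threshold_fraction": d.below_threshold_fraction,
                "below_threshold_band": d.below_threshold_band,
                "missing_rate": d.missing_rate,
                "schedule": [
                    (e.index, e.age_days, e.threshold_g) for e in d.schedule.events
                ],
                "baseline_age_days": d.schedule.baseline_age_days,
            }
        },
    )


def save_chain(chain: PosteriorChain, out_dir) -> None:
    """Samples table, per-event augmented-mean draws and a metadata echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chain.to_frame().to_csv(out / "samples.csv", index=False)
    if chain.event_mean_draws is not None:
        pd.DataFrame(chain.event_mean_draws, columns=chain.event_group_labels).to_csv(
            out / "event_mean_draws.csv", index=False
        )
    meta = {
        "trait_names": chain.trait_names,
        "blocks": [
            {"name": b.name, "group": b.group, "traits": b.traits, "factors": b.factors}
            for b in chain.spec.blocks
        ],
        "longitudinal": (
            {"trait": chain.spec.longitudinal.trait, "factors": chain.spec.longitudinal.factors}
            if chain.spec.longitudinal is not None
            else None
        ),
        "fullsib": chain.spec.fullsib,
        "config": asdict(chain.config),
        "n_records": chain.n_records,
    }
    (out / "chain_metadata.json").write_text(json.dumps(meta, indent=2))


def load_chain(out_dir) -> PosteriorChain:
    """Rebuild a PosteriorChain from ``save_chain`` output."""
    from .model import CrossSectionalBlock, LongitudinalSpec

    out = Path(out_dir)
    meta = json.loads((out / "chain_metadata.json").read_text())
    df = pd.read_csv(out / "samples.csv")
    names = meta["trait_names"]
    T = len(names)
    m = len(df)
    spec = ModelSpec(
        blocks=[
            CrossSectionalBlock(b["name"], b["group"], b["traits"], b["factors"])
            for b in meta["blocks"]
        ],
        longitudinal=(
            LongitudinalSpec(meta["longitudinal"]["trait"], meta["longitudinal"]["factors"])
            if meta["longitudinal"]
            else None
        ),
        fullsib=meta["fullsib"],
    )

    def unpack(prefix):
        M = np.zeros((m, T, T))
        for i in range(T):
            for j in range(i + 1):
                col = (
                    f"{prefix}[{names[i]},{names[j]}]" if i != j else f"{prefix}[{names[i]}]"
                )
                M[:, i, j] = M[:, j, i] = df[col].to_numpy()
        return M

    R_blocks = []
    for b in spec.blocks:
        k = len(b.traits)
        R = np.zeros((m, k, k))
        for i in range(k):
            for j in range(i + 1):
                R[:, i, j] = R[:, j, i] = df[f"R_{b.name}[{i},{j}]"].to_numpy()
        R_blocks.append(R)
    emd, labels = None, []
    if spec.longitudinal is not None and (out / "event_mean_draws.csv").exists():
        em = pd.read_csv(out / "event_mean_draws.csv")
        emd, labels = em.to_numpy(), list(em.columns)
    return PosteriorChain(
        trait_names=names,
        spec=spec,
        config=ChainConfig(**meta["config"]),
        G0=unpack("G0"),
        C0=unpack("C0") if spec.fullsib else None,
        R_blocks=R_blocks,
        sigma_e_long=df["sigma_e_long"].to_numpy() if "sigma_e_long" in df else None,
        sigma_r=df["sigma_r"].to_numpy() if "sigma_r" in df else None,
        event_group_labels=labels,
        event_mean_draws=emd,
        n_records=meta.get("n_records", {}),
    )
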