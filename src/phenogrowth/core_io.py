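"""Domain types and tabular IO for the phenotyping pipeline.

The experiment unit is the *pot*: three seedlings are maintained per pot but
replication, imaging and watering all happen per pot, so one "plant" record
here means one pot. Days are integer days-after-treatment (DAT), with day 0
the day water stress was imposed. Water mass and volume are interchangeable
at 1 g = 1 ml.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "PlantKey",
    "ExperimentDesign",
    "FeatureTable",
    "BiomassTable",
    "WateringLedger",
    "SchemaError",
    "IntegrityError",
    "ReferentialError",
    "RangeError",
    "read_design",
    "read_feature_table",
    "read_biomass_table",
    "read_watering_ledger",
    "write_design",
    "write_feature_table",
    "write_biomass_table",
    "write_watering_ledger",
]

# 1 g of water == 1 ml; tolerance for ledger bookkeeping checks, in grams.
WATER_TOLERANCE_G = 1.0


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class IntegrityError(ValueError):
    """A within-table invariant is violated (duplicates, inconsistent record)."""


class ReferentialError(ValueError):
    """An identifier does not resolve against the experiment design."""


class RangeError(ValueError):
    """A numeric value is outside its physically admissible range."""


class Treatment(str, enum.Enum):
    WELL_WATERED = "well_watered"
    WATER_STRESSED = "water_stressed"

    @classmethod
    def parse(cls, value: str) -> "Treatment":
        try:
            return cls(str(value))
        except ValueError:
            raise SchemaError(
                f"unknown treatment {value!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True)
class PlantKey:
    plant_id: str
    genotype: str
    treatment: Treatment
    replicate: int

    def __post_init__(self):
        if self.replicate < 1:
            raise IntegrityError(
                f"replicate must be a positive integer, got {self.replicate}"
            )


@dataclass
class ExperimentDesign:
    """Genotype x treatment x replicate layout plus the observation days."""

    plants: list[PlantKey]
    days: list[int] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.plant_id for p in self.plants]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise IntegrityError(f"duplicate plant_id in design: {sorted(dup)}")
        if len(self.genotypes) < 2:
            raise IntegrityError("design needs >= 2 genotypes")
        if self.days:
            d = np.asarray(self.days)
            if len(d) < 2:
                raise IntegrityError("design needs >= 2 observation days")
            if not np.all(np.diff(d) > 0):
                raise IntegrityError("days must be strictly increasing")

    @property
    def genotypes(self) -> list[str]:
        return sorted({p.genotype for p in self.plants})

    @property
    def treatments(self) -> list[Treatment]:
        return sorted({p.treatment for p in self.plants}, key=lambda t: t.value)

    @property
    def plant_ids(self) -> list[str]:
        return [p.plant_id for p in self.plants]

    def key(self, plant_id: str) -> PlantKey:
        for p in self.plants:
            if p.plant_id == plant_id:
                return p
        raise ReferentialError(f"plant_id {plant_id!r} not in design")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant_id": [p.plant_id for p in self.plants],
                "genotype": [p.genotype for p in self.plants],
                "treatment": [p.treatment.value for p in self.plants],
                "replicate": [p.replicate for p in self.plants],
            }
        )


@dataclass
class FeatureTable:
    """Per (plant_id, day) image-derived predictors.

    ``data`` has index columns plant_id (str) and day (int) as ordinary
    columns; every other column is a numeric feature named
    ``<feature>.<view>`` (views: top, side0, side90). NaN marks a missing
    observation (e.g. an empty segmentation mask).
    """

    data: pd.DataFrame

    KEYS = ("plant_id", "day")

    def __post_init__(self):
        df = self.data
        for k in self.KEYS:
            if k not in df.columns:
                raise SchemaError(f"feature table missing key column {k!r}")
        dup = df.duplicated(subset=list(self.KEYS))
        if dup.any():
            rows = df.loc[dup, list(self.KEYS)].values.tolist()
            raise IntegrityError(f"duplicate (plant_id, day) rows: {rows[:5]}")
        feats = self.feature_columns
        if not feats:
            raise SchemaError("feature table has no feature columns")
        bad = df[feats].apply(lambda c: np.isinf(c)).any()
        if bad.any():
            raise IntegrityError(
                f"non-finite values in columns {list(bad[bad].index)}"
            )
        df["plant_id"] = df["plant_id"].astype(str)
        df["day"] = df["day"].astype(int)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.KEYS]

    def geometry_columns(self) -> list[str]:
        """Geometry-only predictor subset (drops NIR mean-gray columns)."""
        return [c for c in self.feature_columns if not c.startswith("nir_")]

    def on_day(self, day: int) -> pd.DataFrame:
        return self.data[self.data["day"] == day].reset_index(drop=True)

    @property
    def days(self) -> list[int]:
        return sorted(self.data["day"].unique().tolist())


@dataclass
class BiomassTable:
    """Destructively harvested final-day shoot biomass, per pot."""

    data: pd.DataFrame  # plant_id, fresh_weight_g, dry_weight_g, harvest_day

    COLUMNS = ("plant_id", "fresh_weight_g", "dry_weight_g", "harvest_day")

    def __post_init__(self):
        df = self.data
        for c in self.COLUMNS:
            if c not in df.columns:
                raise SchemaError(f"biomass table missing column {c!r}")
        if df["plant_id"].duplicated().any():
            raise IntegrityError("duplicate plant_id in biomass table")
        if (df["dry_weight_g"] < 0).any():
            raise RangeError("negative dry weight")
        if (df["fresh_weight_g"] < df["dry_weight_g"]).any():
            bad = df.loc[df["fresh_weight_g"] < df["dry_weight_g"], "plant_id"]
            raise RangeError(
                f"fresh weight below dry weight for {list(bad)[:5]}"
            )
        df["plant_id"] = df["plant_id"].astype(str)


@dataclass
class WateringLedger:
    """Daily pre/post-watering pot weights and water added, per pot.

    Pot constants (tare and dry soil weight, grams) are shared across pots by
    default, matching pots filled from one soil batch.
    """

    data: pd.DataFrame  # pot_id, day, weight_before_g, weight_after_g, water_added_ml
    tare_g: float = 0.0
    dry_soil_weight_g: float = 0.0

    COLUMNS = ("pot_id", "day", "weight_before_g", "weight_after_g", "water_added_ml")

    def __post_init__(self):
        df = self.data
        for c in self.COLUMNS:
            if c not in df.columns:
                raise SchemaError(f"watering ledger missing column {c!r}")
        if df.duplicated(subset=["pot_id", "day"]).any():
            raise IntegrityError("duplicate (pot_id, day) in watering ledger")
        if (df[["weight_before_g", "weight_after_g"]] < 0).to_numpy().any():
            raise RangeError("negative pot weight in watering ledger")
        if (df["weight_after_g"] < df["weight_before_g"] - WATER_TOLERANCE_G).any():
            raise IntegrityError("weight_after below weight_before")
        delta = df["weight_after_g"] - df["weight_before_g"]
        off = (df["water_added_ml"] - delta).abs() > WATER_TOLERANCE_G
        if off.any():
            row = df.loc[off].iloc[0]
            raise IntegrityError(
                "water_added inconsistent with weight delta (1 g = 1 ml): "
                f"pot {row['pot_id']} day {row['day']} added "
                f"{row['water_added_ml']} vs delta {delta[off.idxmax()]:.1f}"
            )
        df["pot_id"] = df["pot_id"].astype(str)
        df["day"] = df["day"].astype(int)


# ---------------------------------------------------------------------------
# Readers / writers. CSV schemas:
#   design.csv   plant_id,genotype,treatment,replicate
#   features.csv plant_id,day,<feature columns>
#   watering.csv pot_id,day,weight_before_g,weight_after_g,water_added_ml
#   biomass.csv  plant_id,fresh_weight_g,dry_weight_g,harvest_day
# ---------------------------------------------------------------------------


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _coerce_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: unparseable numeric at row {i + 2}, column {c!r}: "
                f"{df[c].iloc[i]!r}"
            )
        df[c] = coerced
    return df


def read_design(path) -> ExperimentDesign:
    df = _read_csv(path, ("plant_id", "genotype", "treatment", "replicate"))
    df = _coerce_numeric(df, ["replicate"], path)
    plants = [
        PlantKey(
            plant_id=str(r.plant_id),
            genotype=str(r.genotype),
            treatment=Treatment.parse(r.treatment),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
    return ExperimentDesign(plants=plants)


def read_feature_table(path) -> FeatureTable:
    df = _read_csv(path, FeatureTable.KEYS)
    feats = [c for c in df.columns if c not in FeatureTable.KEYS]
    df = _coerce_numeric(df, ["day"] + feats, path)
    return FeatureTable(df)


def read_biomass_table(path, design: ExperimentDesign | None = None) -> BiomassTable:
    df = _read_csv(path, BiomassTable.COLUMNS)
    df = _coerce_numeric(df, list(BiomassTable.COLUMNS[1:]), path)
    table = BiomassTable(df)
    if design is not None:
        orphan = set(table.data["plant_id"].astype(str)) - set(design.plant_ids)
        if orphan:
            raise ReferentialError(
                f"biomass plant_ids not in design: {sorted(orphan)[:5]}"
            )
    return table


def read_watering_ledger(
    path,
    design: ExperimentDesign | None = None,
    tare_g: float = 0.0,
    dry_soil_weight_g: float = 0.0,
) -> WateringLedger:
    df = _read_csv(path, WateringLedger.COLUMNS)
    df = _coerce_numeric(df, list(WateringLedger.COLUMNS[1:]), path)
    ledger = WateringLedger(df, tare_g=tare_g, dry_soil_weight_g=dry_soil_weight_g)
    if design is not None:
        orphan = set(ledger.data["pot_id"].astype(str)) - set(design.plant_ids)
        if orphan:
            raise ReferentialError(
                f"ledger pot_ids not in design: {sorted(orphan)[:5]}"
            )
    return ledger


def write_design(design: ExperimentDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_biomass_table(table: BiomassTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_watering_ledger(ledger: WateringLedger, path) -> None:
    ledger.data.to_csv(path, index=False)
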