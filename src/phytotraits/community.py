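"""Counting-unit observation I/O, exclusion filters, and biomass conversion.

Observations are long-format microscopy counting results: one row per
(sample, taxon, counting-unit type) with abundance (units per litre), cells
per counting unit, biovolume per unit (µm³), wet-weight biomass (µg L⁻¹)
and the maximum morphometric dimension of the counting unit (µm).

The exclusion filters drop heterotrophic taxa, resting stages (akinetes,
heterocytes, cysts), mainly benthic/littoral taxa, single-celled
picoplankton and *Synechococcus* — categories that light microscopy of
Lugol's-preserved samples enumerates unreliably or that fall outside the
pelagic phototrophic community.  Filtering is driven entirely by the trait
table's ``excluded_category`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from phytotraits.trait_table import TraitTable

logger = logging.getLogger(__name__)

UNIT_TYPES = frozenset({"cell", "colony", "coenobium", "chain", "filament_100um"})

#: µg wet weight per µm³ at the conventional density of 1 g cm⁻³.
WET_WEIGHT_UG_PER_UM3 = 1e-6

OBS_COLUMNS = (
    "sample_id",
    "taxon_id",
    "unit_type",
    "units_per_litre",
    "cells_per_unit",
    "biovolume_per_unit",
    "biomass",
    "max_dimension",
)

SEA_AREAS = ("BS", "AS", "wGF", "eGF")


class ObservationError(ValueError):
    """Raised for schema or domain violations in observation tables."""


@dataclass(frozen=True)
class CountingUnitObservation:
    """One taxon's counting result in one sample."""

    sample_id: str
    taxon_id: str
    unit_type: str
    units_per_litre: float
    cells_per_unit: float
    biovolume_per_unit: float
    biomass: float
    max_dimension: float

    def __post_init__(self) -> None:
        if self.unit_type not in UNIT_TYPES:
            raise ObservationError(f"unknown unit_type {self.unit_type!r}")
        if self.units_per_litre < 0:
            raise ObservationError(f"negative units_per_litre for {self.taxon_id!r}")
        if self.cells_per_unit < 1:
            raise ObservationError(f"cells_per_unit < 1 for {self.taxon_id!r}")
        if self.unit_type == "cell" and self.cells_per_unit != 1:
            raise ObservationError(
                f"unit_type 'cell' requires cells_per_unit == 1, got "
                f"{self.cells_per_unit} for {self.taxon_id!r}"
            )
        if self.biovolume_per_unit < 0 or self.biomass < 0:
            raise ObservationError(f"negative biovolume/biomass for {self.taxon_id!r}")
        if self.max_dimension <= 0:
            raise ObservationError(f"non-positive max_dimension for {self.taxon_id!r}")


def read_observations(
    path: str | Path, cells_per_unit_defaults: dict[str, float] | None = None
) -> list[CountingUnitObservation]:
    """Read an observations CSV into validated records.

    Rows with a missing ``cells_per_unit`` are filled from the optional
    per-taxon defaults table (the single fallback when the counting result
    itself lacks the value); taxa with neither raise an error naming them.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationError(f"observations file {path} missing columns {missing}")
    return observations_from_frame(df, cells_per_unit_defaults)


def read_cells_per_unit_defaults(path: str | Path) -> dict[str, float]:
    """Read the optional per-taxon defaults CSV (taxon_id, default_cells_per_unit)."""
    df = pd.read_csv(path, dtype={"taxon_id": str})
    missing = [c for c in ("taxon_id", "default_cells_per_unit") if c not in df.columns]
    if missing:
        raise ObservationError(f"defaults file {path} missing columns {missing}")
    return dict(zip(df["taxon_id"], df["default_cells_per_unit"].astype(float)))


def observations_from_frame(
    df: pd.DataFrame, cells_per_unit_defaults: dict[str, float] | None = None
) -> list[CountingUnitObservation]:
    if df["cells_per_unit"].isna().any():
        defaults = cells_per_unit_defaults or {}
        filled = df["cells_per_unit"].copy()
        need = df["cells_per_unit"].isna()
        filled[need] = df.loc[need, "taxon_id"].map(defaults)
        unresolved = sorted(df.loc[filled.isna(), "taxon_id"].unique())
        if unresolved:
            raise ObservationError(
                f"cells_per_unit missing and no per-taxon default for: {unresolved}"
            )
        df = df.assign(cells_per_unit=filled)
    return [
        CountingUnitObservation(
            sample_id=str(r.sample_id),
            taxon_id=str(r.taxon_id),
            unit_type=str(r.unit_type),
            units_per_litre=float(r.units_per_litre),
            cells_per_unit=float(r.cells_per_unit),
            biovolume_per_unit=float(r.biovolume_per_unit),
            biomass=float(r.biomass),
            max_dimension=float(r.max_dimension),
        )
        for r in df.itertuples(index=False)
    ]


def observations_to_frame(obs: Iterable[CountingUnitObservation]) -> pd.DataFrame:
    return pd.DataFrame([o.__dict__ for o in obs], columns=list(OBS_COLUMNS))


def read_station_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample→station→water-body→sea-area metadata.

    Validates strict nesting (each station in exactly one water body, each
    water body in exactly one sea area) and flags whether the date falls in
    the mid/late-summer window (1 July – 15 September).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "station_id": str, "water_body_id": str})
    required = ["sample_id", "station_id", "water_body_id", "sea_area", "date"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ObservationError(f"station metadata missing columns {missing}")
    bad_area = sorted(set(df["sea_area"]) - set(SEA_AREAS))
    if bad_area:
        raise ObservationError(f"unknown sea areas {bad_area}")
    for child, parent in (("station_id", "water_body_id"), ("water_body_id", "sea_area")):
        n_parents = df.groupby(child)[parent].nunique()
        broken = n_parents[n_parents > 1]
        if not broken.empty:
            raise ObservationError(f"{child} crosses {parent} boundaries: {list(broken.index)}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    md = df["date"].dt.month * 100 + df["date"].dt.day
    df["in_summer_window"] = (md >= 701) & (md <= 915)
    return df


def apply_exclusion_filters(
    observations: Sequence[CountingUnitObservation], table: TraitTable
) -> tuple[list[CountingUnitObservation], dict[str, int]]:
    """Drop observations of excluded taxa; return survivors and a report.

    The report maps each exclusion category to the number of observation
    rows removed for it.  Retained records pass through unchanged (pure
    selection).  An empty result is allowed but logged.
    """
    table.validate_against(o.taxon_id for o in observations)
    kept: list[CountingUnitObservation] = []
    report: dict[str, int] = {}
    for obs in observations:
        category = table.get(obs.taxon_id).excluded_category
        if category is None:
            kept.append(obs)
        else:
            report[category] = report.get(category, 0) + 1
    if observations and not kept:
        logger.warning("exclusion filters removed every observation")
    return kept, report


def convert_biomass(
    biovolume_per_litre: float, ug_per_um3: float = WET_WEIGHT_UG_PER_UM3
) -> float:
    """Convert biovolume concentration (µm³ L⁻¹) to wet-weight biomass (µg L⁻¹).

    Uses the standard wet-weight convention of density 1 g cm⁻³, i.e.
    10⁻⁶ µg per µm³; the factor is configurable for other conventions.
    """
    if biovolume_per_litre < 0:
        raise ObservationError("biovolume must be non-negative")
    return biovolume_per_litre * ug_per_um3
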