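"""Taxon trait table: data model, loading, and trait-assignment rules.

Each taxon carries binary *potential* traits (N-fixation, mixotrophy,
motility, buoyancy, harmfulness).  Records identified above species level
(genus, order, higher) are considered potential carriers of a trait if one
or more member species carry it — a logical OR — except for explicitly
listed overrides, which are data-level decisions shipped with the table
(e.g. *Snowella* spp. is not treated as buoyant although some member
species are).  Taxa flagged with an ``excluded_category`` (heterotrophs,
resting stages, benthic/littoral forms, single-celled picoplankton,
*Synechococcus*) are removed before any trait aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

RANKS = frozenset({"species", "genus", "order", "higher"})
GROUPS = frozenset({"cyanobacteria", "eukaryote"})
EXCLUDED_CATEGORIES = frozenset(
    {
        "heterotroph",
        "akinete",
        "heterocyte",
        "cyst",
        "benthic_littoral",
        "picoplankton_single",
        "synechococcus",
    }
)
TRAIT_NAMES = ("n_fixation", "mixotrophy", "motility", "buoyancy", "harmful")

#: Columns required in a trait-table CSV; booleans encoded as 0/1.
CSV_COLUMNS = (
    "taxon_id",
    "taxon_name",
    "rank",
    "parent_genus",
    "group",
    "n_fixation",
    "mixotrophy",
    "motility",
    "buoyancy",
    "harmful",
    "excluded_category",
    "override_note",
)


class TraitTableError(ValueError):
    """Raised for malformed trait tables or unresolvable taxa."""


@dataclass(frozen=True)
class TraitRecord:
    """One taxon row with binary trait potentials and grouping metadata.

    ``override_traits`` lists trait names whose stored values take
    precedence over the genus/order OR-rule when this record is resolved.
    """

    taxon_id: str
    taxon_name: str
    rank: str
    group: str
    n_fixation: bool = False
    mixotrophy: bool = False
    motility: bool = False
    buoyancy: bool = False
    harmful: bool = False
    parent_genus: Optional[str] = None
    excluded_category: Optional[str] = None
    override_traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise TraitTableError(f"unknown rank {self.rank!r} for {self.taxon_id!r}")
        if self.group not in GROUPS:
            raise TraitTableError(f"unknown group {self.group!r} for {self.taxon_id!r}")
        if self.excluded_category is not None and self.excluded_category not in EXCLUDED_CATEGORIES:
            raise TraitTableError(
                f"unknown excluded_category {self.excluded_category!r} for {self.taxon_id!r}"
            )
        for t in self.override_traits:
            if t not in TRAIT_NAMES:
                raise TraitTableError(f"override names unknown trait {t!r}")

    def flags(self) -> dict[str, bool]:
        return {name: bool(getattr(self, name)) for name in TRAIT_NAMES}


@dataclass
class TraitTable:
    """Validated collection of :class:`TraitRecord`, keyed by ``taxon_id``."""

    records: dict[str, TraitRecord] = field(default_factory=dict)
    version: str = "fixture"

    @classmethod
    def from_records(cls, records: Iterable[TraitRecord], version: str = "fixture") -> "TraitTable":
        out: dict[str, TraitRecord] = {}
        for rec in records:
            if rec.taxon_id in out:
                raise TraitTableError(f"duplicate taxon_id {rec.taxon_id!r}")
            out[rec.taxon_id] = rec
        return cls(records=out, version=version)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.records

    def get(self, taxon_id: str) -> TraitRecord:
        try:
            return self.records[taxon_id]
        except KeyError:
            raise TraitTableError(f"taxon {taxon_id!r} not present in trait table") from None

    def member_species(self, genus_name: str) -> list[TraitRecord]:
        """Species records whose ``parent_genus`` matches ``genus_name``."""
        return [
            r
            for r in self.records.values()
            if r.rank == "species" and r.parent_genus == genus_name
        ]

    def validate_against(self, taxon_ids: Iterable[str]) -> None:
        """Require every observed taxon to be resolvable; list offenders."""
        missing = sorted({t for t in taxon_ids if t not in self.records})
        if missing:
            raise TraitTableError(f"taxa absent from trait table: {missing}")


def _parse_bool(value: object, col: str, taxon: str) -> bool:
    if pd.isna(value):
        return False
    if value in (0, 1, "0", "1", True, False):
        return bool(int(value))
    raise TraitTableError(f"column {col!r} for {taxon!r} must be 0/1, got {value!r}")


def load_trait_table(path: str | Path) -> TraitTable:
    """Read a trait-table CSV and return a validated :class:`TraitTable`.

    Raises :class:`TraitTableError` on missing columns, unknown rank/group
    tokens, or duplicated taxon ids.  An empty (header-only) file yields an
    empty table with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"trait table {path} missing columns {missing}")
    if df.empty:
        logger.warning("trait table %s contains no records", path)
        return TraitTable.from_records([], version=str(path))

    records = []
    for row in df.itertuples(index=False):
        taxon = str(row.taxon_id)
        note = "" if pd.isna(row.override_note) else str(row.override_note)
        overrides = tuple(t.strip() for t in note.split(";") if t.strip())
        records.append(
            TraitRecord(
                taxon_id=taxon,
                taxon_name=str(row.taxon_name),
                rank=str(row.rank),
                parent_genus=None if pd.isna(row.parent_genus) else str(row.parent_genus),
                group=str(row.group),
                n_fixation=_parse_bool(row.n_fixation, "n_fixation", taxon),
                mixotrophy=_parse_bool(row.mixotrophy, "mixotrophy", taxon),
                motility=_parse_bool(row.motility, "motility", taxon),
                buoyancy=_parse_bool(row.buoyancy, "buoyancy", taxon),
                harmful=_parse_bool(row.harmful, "harmful", taxon),
                excluded_category=None
                if pd.isna(row.excluded_category)
                else str(row.excluded_category),
                override_traits=overrides,
            )
        )
    return TraitTable.from_records(records, version=str(path))


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write a table back to the CSV schema (round-trip of :func:`load_trait_table`)."""
    rows = []
    for rec in table.records.values():
        rows.append(
            {
                "taxon_id": rec.taxon_id,
                "taxon_name": rec.taxon_name,
                "rank": rec.rank,
                "parent_genus": rec.parent_genus or "",
                "group": rec.group,
                **{t: int(getattr(rec, t)) for t in TRAIT_NAMES},
                "excluded_category": rec.excluded_category or "",
                "override_note": ";".join(rec.override_traits),
            }
        )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def assign_traits(taxon_id: str, table: TraitTable) -> TraitRecord:
    """Resolve the effective trait flags for one observed taxon.

    Species-rank records return their stored flags.  Records above species
    rank take, per trait, the OR over member-species flags — a genus is a
    potential carrier if any member species is — except traits named in the
    record's override list, which keep the record's stored value (order-rank
    and 'higher' records with no enumerable members always use stored
    values).  Unresolvable taxa raise :class:`TraitTableError`.
    """
    rec = table.get(taxon_id)
    if rec.rank == "species":
        return rec
    members = table.member_species(rec.taxon_name)
    if not members:
        # No enumerable members (order/higher-level records, or a genus whose
        # species are not in the table): the stored flags are authoritative.
        return rec
    resolved = {}
    for trait in TRAIT_NAMES:
        if trait in rec.override_traits:
            resolved[trait] = bool(getattr(rec, trait))
        else:
            resolved[trait] = any(getattr(m, trait) for m in members)
    return replace(rec, **resolved)


def harmful_partition(flags: dict[str, bool] | TraitRecord, group: str | None = None) -> str:
    """Classify a taxon into ``HABcyano`` / ``HABalg`` / ``nonHAB``.

    Harmfulness is split by lineage: harmful cyanobacteria versus harmful
    eukaryotic phytoplankton; everything else is non-harmful.  The three
    classes are exhaustive and mutually exclusive.
    """
    if isinstance(flags, TraitRecord):
        group = flags.group
        harmful = flags.harmful
    else:
        if group is None:
            raise ValueError("group required when flags is a plain mapping")
        harmful = bool(flags["harmful"])
    if group not in GROUPS:
        raise TraitTableError(f"unknown group {group!r}")
    if not harmful:
        return "nonHAB"
    return "HABcyano" if group == "cyanobacteria" else "HABalg"
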