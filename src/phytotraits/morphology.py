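"""Size traits: the 10 µm counting-unit size classification and the
cell-count-weighted average Equivalent Spherical Diameter (aveESD).

The ESD of a cell is the diameter of the sphere with the cell's biovolume,
ESD = (6V/π)^(1/3).  The sample aveESD weights each taxon's ESD by its
cell density (cells L⁻¹ = counting units L⁻¹ × cells per unit), i.e. it is
the mean ESD over individual cells in the sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SIZE_THRESHOLD_UM = 10.0


class MorphologyError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonSizeSummary:
    """Per-taxon morphometrics within one sample."""

    taxon_id: str
    cell_density: float  # cells L⁻¹
    per_cell_biovolume: float  # µm³
    esd: float  # µm

    @property
    def total_taxon_esd(self) -> float:
        """Cell density times ESD (µm · cells L⁻¹)."""
        return self.cell_density * self.esd


def classify_size(max_dimension: float) -> str:
    """Classify a counting unit as ``small`` (≤10 µm) or ``large`` (>10 µm).

    The classification applies to the *counting unit*'s maximum morphometric
    measure: a colony of 2 µm cells spanning 40 µm is large.
    """
    if max_dimension <= 0:
        raise MorphologyError(f"max_dimension must be positive, got {max_dimension}")
    return "small" if max_dimension <= SIZE_THRESHOLD_UM else "large"


def per_cell_biovolume(biovolume_per_unit: float, cells_per_unit: float) -> float:
    """Biovolume of a single cell given the counting unit's biovolume."""
    if cells_per_unit < 1:
        raise MorphologyError(f"cells_per_unit must be ≥ 1, got {cells_per_unit}")
    if biovolume_per_unit < 0:
        raise MorphologyError("biovolume must be non-negative")
    return biovolume_per_unit / cells_per_unit


def equivalent_spherical_diameter(cell_biovolume: float) -> float:
    """Diameter (µm) of the sphere with volume ``cell_biovolume`` (µm³)."""
    if cell_biovolume < 0:
        raise MorphologyError("biovolume must be non-negative")
    return (6.0 * cell_biovolume / math.pi) ** (1.0 / 3.0)


def sphere_volume(diameter: float) -> float:
    """Volume (µm³) of a sphere of the given diameter (µm); inverse of ESD."""
    return math.pi * diameter**3 / 6.0


def sample_ave_esd(
    summaries: Sequence[TaxonSizeSummary], include_zero_biovolume: bool = True
) -> float:
    """Cell-count-weighted mean ESD over the taxa of one sample.

    aveESD = Σᵢ (cell densityᵢ × ESDᵢ) / Σᵢ cell densityᵢ.  Records with
    positive cell density but zero biovolume contribute zero to the
    numerator; whether their cells enter the denominator is controlled by
    ``include_zero_biovolume`` (default: yes, with a logged warning).
    """
    total_cells = 0.0
    total_esd = 0.0
    for s in summaries:
        if s.cell_density <= 0:
            continue
        if s.per_cell_biovolume == 0:
            logger.warning(
                "taxon %s has cells but zero biovolume; ESD contribution is zero", s.taxon_id
            )
            if not include_zero_biovolume:
                continue
        total_cells += s.cell_density
        total_esd += s.total_taxon_esd
    if total_cells == 0:
        raise MorphologyError("total cell count is zero; aveESD undefined")
    return total_esd / total_cells


def summaries_from_observations(observations: Iterable) -> list[TaxonSizeSummary]:
    """Build per-observation size summaries from counting-unit records."""
    out = []
    for obs in observations:
        v_cell = per_cell_biovolume(obs.biovolume_per_unit, obs.cells_per_unit)
        out.append(
            TaxonSizeSummary(
                taxon_id=obs.taxon_id,
                cell_density=obs.units_per_litre * obs.cells_per_unit,
                per_cell_biovolume=v_cell,
                esd=equivalent_spherical_diameter(v_cell),
            )
        )
    return out
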