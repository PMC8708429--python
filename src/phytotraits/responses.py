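"""Construction of the 27 per-sample response variables and the Box–Cox
transformation applied before modelling.

For each binary trait (N-fixation, buoyancy, motility, mixotrophy) the
response set holds the summed biomass of carriers, of non-carriers, and
both as shares of total sample biomass; size contributes small/large
(counting-unit maximum dimension ≤10 µm vs >10 µm) biomasses and shares
plus the cell-count-weighted average equivalent spherical diameter; the
harmfulness trait is split three ways (harmful cyanobacteria, harmful
eukaryotes, non-harmful).  That yields 27 named columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phytotraits import morphology
from phytotraits.trait_table import TraitTable, assign_traits, harmful_partition

logger = logging.getLogger(__name__)

#: Canonical response-variable names, in table order.
RESPONSE_COLUMNS = (
    "Nfix biom",
    "Nfix share",
    "nonNfix biom",
    "nonNfix share",
    "Buo biom",
    "Buo share",
    "nonBuo biom",
    "nonBuo share",
    "Mot biom",
    "Mot share",
    "nonMot biom",
    "nonMot share",
    "MX biom",
    "MX share",
    "AU biom",
    "AU share",
    "Small biom",
    "Small share",
    "Large biom",
    "Large share",
    "aveESD",
    "HABalg biom",
    "HABalg share",
    "HABcyano biom",
    "HABcyano share",
    "nonHAB biom",
    "nonHAB share",
)

_TRAIT_PREFIX = {
    "n_fixation": ("Nfix", "nonNfix"),
    "buoyancy": ("Buo", "nonBuo"),
    "motility": ("Mot", "nonMot"),
    "mixotrophy": ("MX", "AU"),
}


class ResponseError(ValueError):
    pass


@dataclass(frozen=True)
class BoxCoxResult:
    """Fitted Box–Cox transform for one response variable."""

    lam: float
    shift: float
    transformed: np.ndarray


def build_responses(
    observations: Sequence, table: TraitTable, include_zero_biovolume: bool = True
) -> pd.DataFrame:
    """Aggregate filtered observations into the 27-column response matrix.

    Trait biomass is the sum of biomasses of carrier taxa; shares are
    fractions of total sample biomass.  Samples whose total biomass is zero
    are dropped with a warning (their shares are undefined).  Row order of
    the input is irrelevant; output is indexed by sample_id.
    """
    rows: dict[str, dict[str, float]] = {}
    esd_summaries: dict[str, list] = {}
    for obs in observations:
        rec = assign_traits(obs.taxon_id, table)
        if rec.excluded_category is not None:
            raise ResponseError(
                f"observation of excluded taxon {obs.taxon_id!r}; run exclusion filters first"
            )
        acc = rows.setdefault(obs.sample_id, {"total": 0.0})
        acc["total"] += obs.biomass
        for trait, (carrier, _) in _TRAIT_PREFIX.items():
            if getattr(rec, trait):
                acc[carrier] = acc.get(carrier, 0.0) + obs.biomass
        size = morphology.classify_size(obs.max_dimension)
        key = "Small" if size == "small" else "Large"
        acc[key] = acc.get(key, 0.0) + obs.biomass
        hab = harmful_partition(rec)
        acc[hab] = acc.get(hab, 0.0) + obs.biomass
        v_cell = morphology.per_cell_biovolume(obs.biovolume_per_unit, obs.cells_per_unit)
        esd_summaries.setdefault(obs.sample_id, []).append(
            morphology.TaxonSizeSummary(
                taxon_id=obs.taxon_id,
                cell_density=obs.units_per_litre * obs.cells_per_unit,
                per_cell_biovolume=v_cell,
                esd=morphology.equivalent_spherical_diameter(v_cell),
            )
        )

    out_rows = []
    index = []
    for sample_id in sorted(rows):
        acc = rows[sample_id]
        total = acc["total"]
        if total <= 0:
            logger.warning("sample %s has zero total biomass; dropped", sample_id)
            continue
        row: dict[str, float] = {}
        for trait, (carrier, non_carrier) in _TRAIT_PREFIX.items():
            b = acc.get(carrier, 0.0)
            row[f"{carrier} biom"] = b
            row[f"{carrier} share"] = b / total
            row[f"{non_carrier} biom"] = total - b
            row[f"{non_carrier} share"] = 1.0 - b / total
        for key in ("Small", "Large"):
            b = acc.get(key, 0.0)
            row[f"{key} biom"] = b
            row[f"{key} share"] = b / total
        for key in ("HABalg", "HABcyano", "nonHAB"):
            b = acc.get(key, 0.0)
            row[f"{key} biom"] = b
            row[f"{key} share"] = b / total
        row["aveESD"] = morphology.sample_ave_esd(
            esd_summaries[sample_id], include_zero_biovolume=include_zero_biovolume
        )
        out_rows.append(row)
        index.append(sample_id)
    matrix = pd.DataFrame(out_rows, index=pd.Index(index, name="sample_id"))
    return matrix.reindex(columns=list(RESPONSE_COLUMNS))


def boxcox_lambda(
    values: np.ndarray, grid: Optional[np.ndarray] = None, shift: float = 0.0
) -> float:
    """Profile-likelihood Box–Cox λ over a grid [−2, 2] in steps of 0.01.

    ``values + shift`` must be strictly positive and non-constant.
    """
    y = np.asarray(values, dtype=float) + shift
    if np.any(y <= 0):
        raise ResponseError("Box–Cox requires strictly positive values after shift")
    if np.ptp(y) == 0:
        raise ResponseError("Box–Cox undefined for constant input")
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 401)  # step 0.01
    llf = np.array([stats.boxcox_llf(lam, y) for lam in grid])
    return float(grid[int(np.argmax(llf))])


def positivity_shift(values: np.ndarray) -> float:
    """Shift for zero-containing responses: half the smallest positive value."""
    y = np.asarray(values, dtype=float)
    if np.all(y > 0):
        return 0.0
    positive = y[y > 0]
    if positive.size == 0:
        raise ResponseError("no positive values; cannot construct a shift")
    return float(positive.min() / 2.0)


def boxcox_transform(values: np.ndarray, lam: float, shift: float = 0.0) -> np.ndarray:
    """Apply the Box–Cox power transform: log at λ=0, else ((y+s)^λ − 1)/λ."""
    y = np.asarray(values, dtype=float) + shift
    if np.any(y <= 0):
        raise ResponseError("values + shift must be strictly positive")
    if abs(lam) < 1e-8:  # log branch, numerically stable near zero
        return np.log(y)
    return (y**lam - 1.0) / lam


def boxcox_inverse(z: np.ndarray, lam: float, shift: float = 0.0) -> np.ndarray:
    """Invert :func:`boxcox_transform`."""
    z = np.asarray(z, dtype=float)
    if abs(lam) < 1e-8:
        return np.exp(z) - shift
    return (z * lam + 1.0) ** (1.0 / lam) - shift


def fit_boxcox(values: np.ndarray) -> BoxCoxResult:
    """Estimate shift and λ for one response and return the transformed values."""
    shift = positivity_shift(values)
    lam = boxcox_lambda(values, shift=shift)
    return BoxCoxResult(lam=lam, shift=shift, transformed=boxcox_transform(values, lam, shift))


def transform_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Box–Cox-transform every response column; return data + metadata.

    Metadata maps column name → {"lambda", "shift"} for the fit log.
    """
    out = {}
    meta = {}
    for col in matrix.columns:
        res = fit_boxcox(matrix[col].to_numpy())
        out[col] = res.transformed
        meta[col] = {"lambda": res.lam, "shift": res.shift}
    return pd.DataFrame(out, index=matrix.index), meta
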