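"""Hydrographic covariates: surface-layer means, seawater density,
the stratification index, and the nutrient-loading-source typology.

Density is the one-atmosphere EOS-80 polynomial (UNESCO 1983): the
pure-water term plus the practical-salinity correction, valid for
T ∈ [−2, 40] °C and S ∈ [0, 42] psu.  The stratification index is

    E = (σ_bottom − σ_surface) × 1000 / depth_deepest

with σ in kg m⁻³ and depth in m; the bottom value is the deepest joint
temperature/salinity measurement (nominally 1 m above the bottom).  E may
be negative for an unstably stratified column.

Water bodies are typed by the dominant source (argmax of shares) of their
nitrogen and phosphorus loads: (1) N offshore & P offshore, (2) N river &
P point, (3) N river & P offshore, (4) N river & P river, (5) N river &
P sediment.  Any other dominant-source combination is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

LOADING_SOURCES = ("river", "point", "sediment", "offshore")

#: Dominant (N source, P source) pairs → loading type 1–5.
LOADING_TYPE_MAP = {
    ("offshore", "offshore"): 1,
    ("river", "point"): 2,
    ("river", "offshore"): 3,
    ("river", "river"): 4,
    ("river", "sediment"): 5,
}

SURFACE_LAYER_MAX_DEPTH_M = 10.0


class HydrographyError(ValueError):
    pass


class UnclassifiedLoadingError(HydrographyError):
    """Dominant-source combination outside the five enumerated types."""


@dataclass(frozen=True)
class HydroSummary:
    """Per-sample hydrographic covariates used as model inputs."""

    sample_id: str
    temp_mean: float  # °C, 0–10 m mean
    sal_mean: float  # psu, 0–10 m mean
    tp_mean: float  # µg L⁻¹, 0–10 m mean
    secchi: float  # m
    e_index: float  # stratification index, Eq. units as printed
    bottom_depth_used: float  # m, depth of deepest T/S measurement
    loading_type: Optional[int] = None


@dataclass(frozen=True)
class LoadingShares:
    """Source shares of the N and P loads of one water body (each sums to 1)."""

    water_body_id: str
    n_shares: Mapping[str, float]
    p_shares: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, shares in (("n_shares", self.n_shares), ("p_shares", self.p_shares)):
            unknown = set(shares) - set(LOADING_SOURCES)
            if unknown:
                raise HydrographyError(f"{label} has unknown sources {sorted(unknown)}")
            vals = np.array([shares.get(s, 0.0) for s in LOADING_SOURCES], dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise HydrographyError(f"{label} outside [0, 1] for {self.water_body_id}")
            if abs(vals.sum() - 1.0) > 1e-6:
                raise HydrographyError(
                    f"{label} of {self.water_body_id} sums to {vals.sum():.8f}, not 1"
                )


def surface_layer_mean(
    depths, values, max_depth: float = SURFACE_LAYER_MAX_DEPTH_M
) -> float:
    """Unweighted mean of a profile variable over the 0–10 m surface layer.

    Stations shallower than ``max_depth`` contribute their entire water
    column (all available depths).  Depth order is irrelevant.
    """
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    if depths.shape != values.shape or depths.size == 0:
        raise HydrographyError("depths and values must be equal-length, non-empty")
    mask = depths <= max_depth
    if not mask.any():
        # station deeper than the layer but with no measurements inside it
        raise HydrographyError("no measurements within the surface layer")
    if depths.max() <= max_depth:
        mask = np.ones_like(mask)  # entire water column of a shallow station
    sel = values[mask]
    sel = sel[~np.isnan(sel)]
    if sel.size == 0:
        raise HydrographyError("no usable (non-missing) surface measurements")
    return float(sel.mean())


def water_density(temperature: float, salinity: float) -> float:
    """One-atmosphere seawater density σ (kg m⁻³) from EOS-80.

    Check values: ρ(5 °C, 0 psu) = 999.96675, ρ(5 °C, 35 psu) = 1027.67547.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        raise HydrographyError("temperature outside EOS-80 validity [-2, 40] °C")
    if np.any(s < 0.0) or np.any(s > 42.0):
        raise HydrographyError("salinity outside EOS-80 validity [0, 42] psu")
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    rho = rho_w + a * s + b * s**1.5 + c * s**2
    return float(rho) if rho.ndim == 0 else rho


def stratification_index(
    sigma_surface: float, sigma_bottom: float, depth_deepest: float
) -> float:
    """Stratification index E = (σ_bottom − σ_surface) × 1000 / depth."""
    if depth_deepest <= 0:
        raise HydrographyError(f"depth must be positive, got {depth_deepest}")
    return (sigma_bottom - sigma_surface) * 1000.0 / depth_deepest


def classify_loading_source(shares: LoadingShares) -> int:
    """Map a water body's dominant N and P load sources to loading type 1–5.

    Ties in the argmax are an error (the typology presupposes a clearly
    dominant source), as are dominant-source pairs outside the five types.
    """
    dominant = {}
    for nutrient, share_map in (("N", shares.n_shares), ("P", shares.p_shares)):
        vals = np.array([share_map.get(s, 0.0) for s in LOADING_SOURCES], dtype=float)
        top = vals.max()
        winners = [s for s, v in zip(LOADING_SOURCES, vals) if v == top]
        if len(winners) > 1:
            raise UnclassifiedLoadingError(
                f"tied dominant {nutrient} sources {winners} for {shares.water_body_id}"
            )
        dominant[nutrient] = winners[0]
    key = (dominant["N"], dominant["P"])
    if key not in LOADING_TYPE_MAP:
        raise UnclassifiedLoadingError(
            f"dominant sources N={key[0]}, P={key[1]} for {shares.water_body_id} "
            "fall outside the five enumerated loading types"
        )
    return LOADING_TYPE_MAP[key]


def summarize_sample(
    profile: pd.DataFrame,
    secchi: float,
    sample_id: str,
    loading_type: Optional[int] = None,
) -> HydroSummary:
    """Build the per-sample hydrographic summary from a depth profile.

    ``profile`` columns: depth, temperature, salinity, tp (tp optional per
    depth).  Surface means use the 0–10 m rule; σ_surface is the density at
    the surface-layer mean T/S, σ_bottom the density at the deepest joint
    T/S measurement.
    """
    if profile.empty:
        raise HydrographyError(f"empty profile for sample {sample_id}")
    depths = profile["depth"].to_numpy(dtype=float)
    temp_mean = surface_layer_mean(depths, profile["temperature"].to_numpy(dtype=float))
    sal_mean = surface_layer_mean(depths, profile["salinity"].to_numpy(dtype=float))
    if "tp" in profile.columns and profile["tp"].notna().any():
        tp_mean = surface_layer_mean(depths, profile["tp"].to_numpy(dtype=float))
    else:
        tp_mean = float("nan")
    joint = profile.dropna(subset=["temperature", "salinity"])
    deepest = joint.loc[joint["depth"].idxmax()]
    depth_deepest = float(deepest["depth"])
    sigma_surface = water_density(temp_mean, sal_mean)
    sigma_bottom = water_density(float(deepest["temperature"]), float(deepest["salinity"]))
    e = stratification_index(sigma_surface, sigma_bottom, depth_deepest)
    return HydroSummary(
        sample_id=sample_id,
        temp_mean=temp_mean,
        sal_mean=sal_mean,
        tp_mean=tp_mean,
        secchi=float(secchi),
        e_index=e,
        bottom_depth_used=depth_deepest,
        loading_type=loading_type,
    )


def read_loading_shares(path) -> dict[str, LoadingShares]:
    """Read a loading-shares CSV (water_body_id, nutrient, river, point,
    sediment, offshore; one row per water body and nutrient)."""
    df = pd.read_csv(path, dtype={"water_body_id": str})
    out: dict[str, LoadingShares] = {}
    for wb, grp in df.groupby("water_body_id"):
        maps = {}
        for nutrient in ("N", "P"):
            row = grp[grp["nutrient"] == nutrient]
            if len(row) != 1:
                raise HydrographyError(f"water body {wb}: need one {nutrient} share row")
            maps[nutrient] = {s: float(row.iloc[0][s]) for s in LOADING_SOURCES}
        out[str(wb)] = LoadingShares(str(wb), n_shares=maps["N"], p_shares=maps["P"])
    return out
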