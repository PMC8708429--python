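"""Synthetic coastal phytoplankton surveys with known ground truth.

The generator emulates the structure of summer monitoring data from four
coastal sea areas: stations nested in water bodies nested in areas,
repeated mid/late-summer visits (1 July – 15 September) over a span of
years, per-area environmental gradients (temperature, salinity, Secchi
depth, total phosphorus, stratification), water-body nutrient-loading
source shares covering all five loading types, and a taxon pool with
internally consistent trait flags (N-fixers and buoyant taxa are
cyanobacteria; mixotrophy and motility occur in eukaryotes).

Communities are generated at taxon level: each taxon's log biomass is a
linear function of standardized environmental covariates through the
traits it carries, plus water-body and station random intercepts, a
sample-level continuous-time AR(1) component within station, and
area-scaled noise — the same structure the additive mixed model assumes.
All randomness flows from a single seed through named child generators,
so every artefact is bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from phytotraits import hydrography
from phytotraits.community import observations_from_frame
from phytotraits.hydrography import LOADING_TYPE_MAP, LoadingShares
from phytotraits.trait_table import (
    EXCLUDED_CATEGORIES,
    TraitRecord,
    TraitTable,
    write_trait_table,
)

AREAS = ("BS", "AS", "wGF", "eGF")

#: Per-area environmental distributions: surface means (SDs) chosen to
#: mirror the reported gradients — AS warmest and most saline, eGF fresh
#: and clearer with stronger stratification, wGF variable with highest TP.
DEFAULT_AREA_ENV = {
    #        temp        sal         secchi      log-TP       bottom ΔS  bottom ΔT
    "BS": dict(temp=(15.0, 2.5), sal=(5.3, 0.5), secchi=(3.0, 0.9), log_tp=(2.5, 0.4), d_sal=(0.5, 0.2), d_temp=(4.0, 1.5)),
    "AS": dict(temp=(17.0, 2.5), sal=(6.0, 0.4), secchi=(2.8, 0.9), log_tp=(2.9, 0.4), d_sal=(0.4, 0.2), d_temp=(4.0, 1.5)),
    "wGF": dict(temp=(16.0, 3.0), sal=(4.8, 0.8), secchi=(2.5, 1.1), log_tp=(3.3, 0.6), d_sal=(0.8, 0.3), d_temp=(5.0, 2.0)),
    "eGF": dict(temp=(16.0, 2.5), sal=(2.8, 0.6), secchi=(3.5, 1.1), log_tp=(2.7, 0.4), d_sal=(1.0, 0.3), d_temp=(5.0, 2.0)),
}

#: Standardized effects of covariates on log biomass through trait carriage,
#: qualitatively mirroring the reported pattern: temperature favours
#: N-fixers/buoyant cyanobacteria and disfavours motile/mixotrophic taxa,
#: transparency relates negatively to biomasses overall, TP favours large
#: cells and disfavours mixotrophs; salinity and stratification are null.
DEFAULT_EFFECTS = {
    ("Temp", "n_fixation"): 0.8,
    ("Temp", "buoyancy"): 0.7,
    ("Temp", "mixotrophy"): -0.6,
    ("Temp", "motility"): -0.6,
    ("Secchi", "all"): -0.5,
    ("Secchi", "harmful"): -0.5,
    ("TP", "large"): 0.6,
    ("TP", "mixotrophy"): -0.5,
}

DEFAULT_PREVALENCE = {
    "n_fixation": 0.10,
    "mixotrophy": 0.25,
    "motility": 0.35,
    "buoyancy": 0.15,
    "harmful": 0.15,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the survey generator, seeded once."""

    seed: int = 0
    n_areas: int = 4
    wb_per_area: int = 11
    stations_per_wb: int = 2
    n_samples: int = 912
    years: tuple[int, int] = (2009, 2020)
    taxon_pool: int = 60
    prevalence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    area_env: Mapping[str, Mapping] = field(default_factory=lambda: dict(DEFAULT_AREA_ENV))
    sd_water_body: float = 0.30
    sd_station: float = 0.20
    ar1_phi: float = 0.40  # correlation at a 1-day gap
    ar1_sd: float = 0.25
    resid_sd: float = 0.40
    area_resid_mult: tuple[float, ...] = (1.0, 1.2, 1.5, 0.8)
    baseline_log_biomass: tuple[float, float] = (0.5, 1.0)  # mean, sd across taxa
    occupancy: float = 0.85
    taxon_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.taxon_pool <= 0:
            raise ValueError("taxon_pool must be positive")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("ar1_phi must lie in [0, 1)")
        for t, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {t} outside [0, 1]")
        if self.sd_water_body < 0 or self.sd_station < 0 or self.resid_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_areas > len(AREAS):
            raise ValueError(f"at most {len(AREAS)} areas supported")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("traits", "structure", "environment", "community", "loading")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


# --------------------------------------------------------------------------
# trait table


def simulate_trait_table(config: SimulationConfig) -> TraitTable:
    """Draw a taxon pool with internally consistent trait flags.

    The pool holds ``taxon_pool`` analysable taxa plus one taxon per
    exclusion category so that the exclusion filters are always exercised.
    """
    rng = _rng_streams(config.seed)["traits"]
    prev = config.prevalence
    records = []
    for i in range(config.taxon_pool):
        n_fix = rng.random() < prev["n_fixation"]
        buo = rng.random() < prev["buoyancy"]
        cyano = n_fix or buo or (rng.random() < 0.10)
        if cyano:
            mixo = False  # diazotrophic / colonial cyanobacteria: non-mixotrophic here
            mot = False
        else:
            mixo = rng.random() < prev["mixotrophy"]
            mot = rng.random() < prev["motility"]
        harmful = rng.random() < prev["harmful"]
        records.append(
            TraitRecord(
                taxon_id=f"TAX{i:03d}",
                taxon_name=f"Taxon {i:03d}",
                rank="species",
                parent_genus=f"Genus{i // 4:02d}",
                group="cyanobacteria" if cyano else "eukaryote",
                n_fixation=n_fix,
                mixotrophy=mixo,
                motility=mot,
                buoyancy=buo and cyano,
                harmful=harmful,
            )
        )
    records = _ensure_trait_coverage(records)
    for j, category in enumerate(sorted(EXCLUDED_CATEGORIES)):
        records.append(
            TraitRecord(
                taxon_id=f"EXC{j:02d}",
                taxon_name=f"Excluded {category}",
                rank="species",
                parent_genus="GenusEX",
                group="cyanobacteria" if category == "synechococcus" else "eukaryote",
                excluded_category=category,
            )
        )
    return TraitTable.from_records(records, version=f"synthetic-seed{config.seed}")


def _ensure_trait_coverage(records: list[TraitRecord]) -> list[TraitRecord]:
    """Guarantee at least one carrier per trait and per harmfulness class,
    so every trait biomass is realizable (shares of an absent trait would be
    identically zero across the whole survey)."""
    from dataclasses import replace

    records = list(records)

    def force(predicate, **flags):
        if any(predicate(r) for r in records):
            return
        for i, r in enumerate(records):
            candidate = replace(r, **flags)
            if predicate(candidate):
                records[i] = candidate
                return

    force(lambda r: r.n_fixation, group="cyanobacteria", n_fixation=True,
          mixotrophy=False, motility=False)
    force(lambda r: r.buoyancy, group="cyanobacteria", buoyancy=True,
          mixotrophy=False, motility=False)
    force(lambda r: r.mixotrophy and r.group == "eukaryote",
          group="eukaryote", mixotrophy=True, n_fixation=False, buoyancy=False)
    force(lambda r: r.motility and r.group == "eukaryote",
          group="eukaryote", motility=True, n_fixation=False, buoyancy=False)
    force(lambda r: r.harmful and r.group == "cyanobacteria",
          group="cyanobacteria", harmful=True, mixotrophy=False, motility=False)
    force(lambda r: r.harmful and r.group == "eukaryote",
          group="eukaryote", harmful=True, n_fixation=False, buoyancy=False)
    force(lambda r: not r.harmful, harmful=False)
    return records


def _taxon_geometry(table: TraitTable, rng: np.random.Generator) -> pd.DataFrame:
    """Counting-unit geometry per taxon: unit type, cells per unit, per-cell
    diameter, implied biovolume and maximum dimension."""
    rows = []
    for rec in table.records.values():
        d_cell = float(np.exp(rng.normal(np.log(8.0), 0.6)))
        d_cell = float(np.clip(d_cell, 1.0, 60.0))
        if rec.group == "cyanobacteria" and rec.taxon_id.startswith("TAX"):
            unit_type = str(rng.choice(["filament_100um", "colony", "cell"], p=[0.4, 0.4, 0.2]))
        else:
            unit_type = str(rng.choice(["cell", "colony", "chain"], p=[0.6, 0.2, 0.2]))
        cells = 1 if unit_type == "cell" else int(rng.integers(2, 50))
        v_cell = np.pi * d_cell**3 / 6.0
        if unit_type == "filament_100um":
            max_dim = 100.0
        elif unit_type == "cell":
            max_dim = d_cell
        else:
            max_dim = d_cell * float(np.ceil(np.sqrt(cells)))
        rows.append(
            {
                "taxon_id": rec.taxon_id,
                "unit_type": unit_type,
                "cells_per_unit": cells,
                "cell_diameter": d_cell,
                "biovolume_per_unit": v_cell * cells,
                "max_dimension": max_dim,
            }
        )
    geo = pd.DataFrame(rows).set_index("taxon_id")
    # both size classes must be realizable for the Small/Large responses
    if not (geo["max_dimension"] <= 10.0).any():
        tid = geo.index[0]
        geo.loc[tid, ["unit_type", "cells_per_unit", "cell_diameter", "max_dimension"]] = (
            "cell", 1, 6.0, 6.0)
        geo.loc[tid, "biovolume_per_unit"] = np.pi * 6.0**3 / 6.0
    if not (geo["max_dimension"] > 10.0).any():
        tid = geo.index[-1]
        geo.loc[tid, ["unit_type", "cells_per_unit", "cell_diameter", "max_dimension"]] = (
            "cell", 1, 20.0, 20.0)
        geo.loc[tid, "biovolume_per_unit"] = np.pi * 20.0**3 / 6.0
    return geo


# --------------------------------------------------------------------------
# structure + environment


def simulate_structure(config: SimulationConfig) -> pd.DataFrame:
    """Sample → station → water body → area assignment with visit dates."""
    rng = _rng_streams(config.seed)["structure"]
    stations = []
    for a in range(config.n_areas):
        area = AREAS[a]
        for w in range(config.wb_per_area):
            wb = f"{area}-wb{w:02d}"
            for s in range(config.stations_per_wb):
                stations.append((f"{wb}-st{s}", wb, area))
    rows = []
    y0, y1 = config.years
    window_days = (pd.Timestamp(2000, 9, 15) - pd.Timestamp(2000, 7, 1)).days
    depth_by_station = {
        st: float(rng.uniform(6.0, 40.0)) for st, _, _ in stations
    }
    seen: set[tuple[str, pd.Timestamp]] = set()
    for i in range(config.n_samples):
        st, wb, area = stations[i % len(stations)]
        while True:  # one visit per station and day
            year = int(rng.integers(y0, y1 + 1))
            day = int(rng.integers(0, window_days + 1))
            date = pd.Timestamp(year, 7, 1) + pd.Timedelta(days=day)
            if (st, date) not in seen:
                seen.add((st, date))
                break
        rows.append(
            {
                "sample_id": f"S{i:04d}",
                "station_id": st,
                "water_body_id": wb,
                "sea_area": area,
                "date": date,
                "bottom_depth": depth_by_station[st],
            }
        )
    return pd.DataFrame(rows)


def simulate_loading_shares(config: SimulationConfig) -> dict[str, LoadingShares]:
    """Per-water-body N/P source shares covering all five loading types."""
    rng = _rng_streams(config.seed)["loading"]
    type_keys = list(LOADING_TYPE_MAP)  # (N source, P source) pairs, types 1..5
    out: dict[str, LoadingShares] = {}
    wb_ids = [
        f"{AREAS[a]}-wb{w:02d}"
        for a in range(config.n_areas)
        for w in range(config.wb_per_area)
    ]
    for i, wb in enumerate(wb_ids):
        n_dom, p_dom = type_keys[i % len(type_keys)]
        shares = {}
        for nutrient, dom in (("N", n_dom), ("P", p_dom)):
            dom_share = float(rng.uniform(0.55, 0.8))
            rest = rng.dirichlet(np.ones(3)) * (1.0 - dom_share)
            others = [s for s in hydrography.LOADING_SOURCES if s != dom]
            m = {dom: dom_share}
            m.update({o: float(r) for o, r in zip(others, rest)})
            shares[nutrient] = m
        out[wb] = LoadingShares(wb, n_shares=shares["N"], p_shares=shares["P"])
    return out


def simulate_environment(
    config: SimulationConfig, structure: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, LoadingShares]]:
    """Depth profiles, Secchi depths and loading shares for every sample.

    Returns (profiles, secchi, loading_shares).  Profiles hold 0/5/10 m
    surface measurements (only depths above the bottom for shallow
    stations) plus the deepest measurement 1 m above the bottom, with
    bottom water colder and more saline than the surface so that the
    implied stratification index is predominantly positive.
    """
    if structure is None:
        structure = simulate_structure(config)
    rng = _rng_streams(config.seed)["environment"]
    profile_rows = []
    secchi_rows = []
    for row in structure.itertuples(index=False):
        env = config.area_env[row.sea_area]
        temp = float(rng.normal(*env["temp"]))
        sal = max(0.5, float(rng.normal(*env["sal"])))
        secchi = max(0.3, float(rng.normal(*env["secchi"])))
        tp = float(np.exp(rng.normal(*env["log_tp"])))
        d_sal = max(0.0, float(rng.normal(*env["d_sal"])))
        d_temp = max(0.0, float(rng.normal(*env["d_temp"])))
        deepest = row.bottom_depth - 1.0
        depths = [d for d in (0.0, 5.0, 10.0) if d < deepest] + [deepest]
        for d in depths:
            if d < deepest:
                t_d = temp + float(rng.normal(0.0, 0.1))
                s_d = sal + float(rng.normal(0.0, 0.05))
            else:
                # bottom water: colder, saltier (positive density contrast)
                t_d = max(2.0, temp - d_temp)
                s_d = sal + d_sal
            profile_rows.append(
                {
                    "sample_id": row.sample_id,
                    "depth": d,
                    "temperature": t_d,
                    "salinity": s_d,
                    "tp": tp * float(np.exp(rng.normal(0.0, 0.05))),
                }
            )
        secchi_rows.append({"sample_id": row.sample_id, "secchi": secchi})
    profiles = pd.DataFrame(profile_rows)
    secchi_df = pd.DataFrame(secchi_rows)
    return profiles, secchi_df, simulate_loading_shares(config)


def _covariates_from_environment(
    structure: pd.DataFrame,
    profiles: pd.DataFrame,
    secchi: pd.DataFrame,
    loading: dict[str, LoadingShares],
) -> pd.DataFrame:
    """Run the hydrography module over the generated inputs to obtain the
    per-sample covariates (the same values the analysis pipeline sees)."""
    secchi_map = secchi.set_index("sample_id")["secchi"]
    ltype = {wb: hydrography.classify_loading_source(sh) for wb, sh in loading.items()}
    rows = []
    for row in structure.itertuples(index=False):
        prof = profiles[profiles["sample_id"] == row.sample_id]
        summ = hydrography.summarize_sample(
            prof, secchi_map[row.sample_id], row.sample_id, ltype[row.water_body_id]
        )
        rows.append(
            {
                "sample_id": row.sample_id,
                "Temp": summ.temp_mean,
                "Sal": summ.sal_mean,
                "Secchi": summ.secchi,
                "E": summ.e_index,
                "TP": summ.tp_mean,
                "L": summ.loading_type,
                "Area": row.sea_area,
                "water_body": row.water_body_id,
                "station": row.station_id,
                "date": row.date,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# communities


def _taxon_effect_keys(rec: TraitRecord, geometry: pd.Series) -> list[str]:
    keys = ["all"]
    for trait in ("n_fixation", "mixotrophy", "motility", "buoyancy", "harmful"):
        if getattr(rec, trait):
            keys.append(trait)
    keys.append("small" if geometry["max_dimension"] <= 10.0 else "large")
    if rec.harmful:
        keys.append("harmful_cyano" if rec.group == "cyanobacteria" else "harmful_alg")
    return keys


def simulate_communities(
    config: SimulationConfig,
    table: TraitTable,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Generate the observation table and its ground-truth record.

    log biomass(taxon, sample) = baseline(taxon)
        + Σ_c effect(c, key) · z_c(sample)   for each trait key the taxon carries
        + b_wb + b_station + AR1(date; within station) + area-scaled noise
        + taxon-level microscale noise.
    """
    rng = _rng_streams(config.seed)["community"]
    geometry = _taxon_geometry(table, rng)
    cov = covariates.reset_index(drop=True)
    smooth_covs = ("Temp", "Sal", "Secchi", "E", "TP")
    z = {
        c: (cov[c] - cov[c].mean()) / (cov[c].std() if cov[c].std() > 0 else 1.0)
        for c in smooth_covs
    }

    wbs = sorted(cov["water_body"].unique())
    sts = sorted(cov["station"].unique())
    b_wb = {w: float(rng.normal(0.0, config.sd_water_body)) for w in wbs}
    b_st = {s: float(rng.normal(0.0, config.sd_station)) for s in sts}

    area_mult = {AREAS[i]: config.area_resid_mult[i] for i in range(config.n_areas)}

    # sample-level AR(1) within station (continuous-time decay on date gaps)
    ar = np.zeros(len(cov))
    if config.ar1_sd > 0:
        for _, idx in cov.groupby("station").indices.items():
            idx = np.asarray(idx)
            t = cov.loc[idx, "date"]
            t = (t - t.min()).dt.total_seconds().to_numpy() / 86400.0
            order = np.argsort(t, kind="stable")
            e = np.zeros(idx.size)
            prev_t = None
            for k in order:
                if prev_t is None or config.ar1_phi == 0.0:
                    e[k] = rng.normal(0.0, 1.0)
                else:
                    rho = config.ar1_phi ** (t[k] - prev_t)
                    e[k] = rho * e_prev + np.sqrt(max(1e-12, 1.0 - rho**2)) * rng.normal()
                e_prev = e[k]
                prev_t = t[k]
            ar[idx] = e * config.ar1_sd

    eps = rng.normal(0.0, 1.0, size=len(cov)) * config.resid_sd
    eps *= cov["Area"].map(area_mult).to_numpy()
    common = ar + eps + cov["water_body"].map(b_wb).to_numpy() + cov["station"].map(b_st).to_numpy()

    baselines = {
        rec.taxon_id: float(rng.normal(*config.baseline_log_biomass))
        for rec in table.records.values()
    }

    rows = []
    for rec in table.records.values():
        geo = geometry.loc[rec.taxon_id]
        keys = _taxon_effect_keys(rec, geo)
        slope = np.zeros(len(cov))
        for c in smooth_covs:
            eff = sum(config.effects.get((c, k), 0.0) for k in keys)
            if eff:
                slope += eff * z[c].to_numpy()
        micro = rng.normal(0.0, config.taxon_noise_sd, size=len(cov))
        log_b = baselines[rec.taxon_id] + slope + common + micro
        present = rng.random(len(cov)) < config.occupancy
        biomass = np.exp(log_b)
        for i in np.flatnonzero(present):
            b = float(biomass[i])
            units = b / (float(geo["biovolume_per_unit"]) * 1e-6)
            rows.append(
                {
                    "sample_id": cov.loc[i, "sample_id"],
                    "taxon_id": rec.taxon_id,
                    "unit_type": geo["unit_type"],
                    "units_per_litre": units,
                    "cells_per_unit": float(geo["cells_per_unit"]),
                    "biovolume_per_unit": float(geo["biovolume_per_unit"]),
                    "biomass": b,
                    "max_dimension": float(geo["max_dimension"]),
                }
            )
    obs = pd.DataFrame(rows)
    truth = {
        "seed": config.seed,
        "effects": {f"{c}:{k}": v for (c, k), v in config.effects.items()},
        "sd_water_body": config.sd_water_body,
        "sd_station": config.sd_station,
        "ar1_phi": config.ar1_phi,
        "ar1_sd": config.ar1_sd,
        "resid_sd": config.resid_sd,
        "area_resid_mult": {AREAS[i]: config.area_resid_mult[i] for i in range(config.n_areas)},
        "covariate_means": {c: float(cov[c].mean()) for c in smooth_covs},
        "covariate_sds": {c: float(cov[c].std()) for c in smooth_covs},
        "n_taxa": len(table),
    }
    return obs, truth


# --------------------------------------------------------------------------
# full bundle


@dataclass(frozen=True)
class SurveyBundle:
    """In-memory synthetic survey: every input the pipeline consumes."""

    config: SimulationConfig
    trait_table: TraitTable
    structure: pd.DataFrame
    profiles: pd.DataFrame
    secchi: pd.DataFrame
    loading: dict[str, LoadingShares]
    covariates: pd.DataFrame
    observations: pd.DataFrame
    ground_truth: dict


def simulate_survey(
    config: SimulationConfig, outdir: Optional[str | Path] = None
) -> SurveyBundle:
    """Generate a complete survey; optionally write all input CSVs + truth JSON."""
    table = simulate_trait_table(config)
    structure = simulate_structure(config)
    profiles, secchi, loading = simulate_environment(config, structure)
    covariates = _covariates_from_environment(structure, profiles, secchi, loading)
    observations, truth = simulate_communities(config, table, covariates)

    bundle = SurveyBundle(
        config=config,
        trait_table=table,
        structure=structure,
        profiles=profiles,
        secchi=secchi,
        loading=loading,
        covariates=covariates,
        observations=observations,
        ground_truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trait_table(table, outdir / "trait_table.csv")
        structure.drop(columns=["bottom_depth"]).assign(
            date=structure["date"].dt.strftime("%Y-%m-%d")
        ).to_csv(outdir / "stations.csv", index=False)
        profiles.to_csv(outdir / "profiles.csv", index=False)
        secchi.to_csv(outdir / "secchi.csv", index=False)
        rows = []
        for wb, sh in loading.items():
            for nutrient, m in (("N", sh.n_shares), ("P", sh.p_shares)):
                rows.append({"water_body_id": wb, "nutrient": nutrient, **m})
        pd.DataFrame(rows).to_csv(outdir / "loading_shares.csv", index=False)
        observations.to_csv(outdir / "observations.csv", index=False)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    # validate the bundle through the observation reader's type checks
    observations_from_frame(observations)
    return bundle
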