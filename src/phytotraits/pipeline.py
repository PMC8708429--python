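"""End-to-end glue: from survey inputs to fitted models and summary tables.

Ties the modules together in the order the analysis prescribes: exclusion
filtering, response construction, hydrographic covariates, Box–Cox
transformation, one additive mixed model per response, and the per-term /
pairwise-contrast summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from phytotraits import community, gamm, hydrography, responses
from phytotraits.synthetic_data import SurveyBundle
from phytotraits.trait_table import TraitTable, load_trait_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Responses, covariates and transform metadata, aligned on sample_id."""

    response_matrix: pd.DataFrame
    transformed: pd.DataFrame
    transform_meta: dict
    covariates: pd.DataFrame
    exclusion_report: dict


def prepare(
    observations: Sequence,
    table: TraitTable,
    covariates: pd.DataFrame,
) -> PipelineResult:
    """Filter observations, build + transform the response matrix, and align
    it with the per-sample covariate frame."""
    kept, report = community.apply_exclusion_filters(observations, table)
    matrix = responses.build_responses(kept, table)
    cov = covariates.set_index("sample_id").loc[matrix.index].reset_index()
    transformed, meta = responses.transform_matrix(matrix)
    return PipelineResult(
        response_matrix=matrix,
        transformed=transformed,
        transform_meta=meta,
        covariates=cov,
        exclusion_report=report,
    )


def prepare_bundle(bundle: SurveyBundle) -> PipelineResult:
    """Run :func:`prepare` on an in-memory synthetic survey."""
    obs = community.observations_from_frame(bundle.observations)
    return prepare(obs, bundle.trait_table, bundle.covariates)


def load_bundle_dir(path: str | Path) -> PipelineResult:
    """Load a written survey bundle directory and run :func:`prepare`."""
    path = Path(path)
    table = load_trait_table(path / "trait_table.csv")
    obs = community.read_observations(path / "observations.csv")
    structure = community.read_station_metadata(path / "stations.csv")
    profiles = pd.read_csv(path / "profiles.csv")
    secchi = pd.read_csv(path / "secchi.csv").set_index("sample_id")["secchi"]
    loading = hydrography.read_loading_shares(path / "loading_shares.csv")
    ltype = {wb: hydrography.classify_loading_source(sh) for wb, sh in loading.items()}
    rows = []
    for r in structure.itertuples(index=False):
        prof = profiles[profiles["sample_id"] == r.sample_id]
        summ = hydrography.summarize_sample(
            prof, secchi[r.sample_id], r.sample_id, ltype[r.water_body_id]
        )
        rows.append(
            {
                "sample_id": r.sample_id,
                "Temp": summ.temp_mean,
                "Sal": summ.sal_mean,
                "Secchi": summ.secchi,
                "E": summ.e_index,
                "TP": summ.tp_mean,
                "L": summ.loading_type,
                "Area": r.sea_area,
                "water_body": r.water_body_id,
                "station": r.station_id,
                "date": r.date,
            }
        )
    return prepare(obs, table, pd.DataFrame(rows))


def fit_response(
    result: PipelineResult, response: str, spec: Optional[gamm.GAMMSpec] = None
) -> gamm.GAMMFit:
    """Fit the additive mixed model for one named response variable."""
    spec = spec or gamm.GAMMSpec()
    design = gamm.build_design(spec, result.covariates)
    return gamm.fit_gamm(design, result.transformed[response].to_numpy())


def fit_all(
    result: PipelineResult,
    which: Optional[Sequence[str]] = None,
    spec: Optional[gamm.GAMMSpec] = None,
) -> dict[str, gamm.GAMMFit]:
    """Fit models for several (default: all 27) response variables."""
    spec = spec or gamm.GAMMSpec()
    design = gamm.build_design(spec, result.covariates)
    fits = {}
    for col in which if which is not None else result.transformed.columns:
        fits[col] = gamm.fit_gamm(design, result.transformed[col].to_numpy())
    return fits


def term_table(fits: dict[str, gamm.GAMMFit]) -> pd.DataFrame:
    """Response × term p-values with direction codes (per-term summary)."""
    rows = []
    for resp, fit in fits.items():
        entry = {"response": resp, "converged": fit.converged}
        for b in fit.design.blocks:
            if b.kind == "smooth":
                entry[b.name] = gamm.term_pvalue(fit, b.name)
                entry[f"{b.name}_dir"] = gamm.classify_effect_direction(
                    fit, b.name, fit.design.spec.alpha
                )
            elif b.kind == "factor":
                entry[b.name] = gamm.term_pvalue(fit, b.name)
        rows.append(entry)
    return pd.DataFrame(rows).set_index("response")


def contrast_table(fits: dict[str, gamm.GAMMFit], factor: str = "Area") -> pd.DataFrame:
    """Response × area-pair Tukey-adjusted p-values (pairwise summary)."""
    rows = []
    for resp, fit in fits.items():
        emm = gamm.estimated_marginal_means(fit, factor)
        entry = {"response": resp}
        for c in gamm.tukey_pairwise(emm):
            entry[f"{c.level_a}-{c.level_b}"] = c.p_adjusted
        rows.append(entry)
    return pd.DataFrame(rows).set_index("response")
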