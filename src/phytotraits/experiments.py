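"""Calibration and recovery experiments for the modelling machinery.

These generate data with known structure, refit it with the package's own
estimators, and report calibration (type-I error of the term tests),
parameter recovery (slope, random-intercept SD, CAR(1) φ), agreement of
the pairwise contrasts with classical Tukey HSD, and recovery of the
signs of effects injected into full synthetic surveys.  They are used by
the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from phytotraits import gamm, pipeline
from phytotraits.synthetic_data import SimulationConfig, simulate_survey

#: Injected trait effects with |standardized magnitude| ≥ 0.5 and the trait
#: biomass response that carries each one (see synthetic_data.DEFAULT_EFFECTS).
EFFECT_RESPONSE_PAIRS = (
    ("Temp", "Nfix biom", "+"),
    ("Temp", "Buo biom", "+"),
    ("Temp", "MX biom", "-"),
    ("Temp", "Mot biom", "-"),
    ("Secchi", "nonHAB biom", "-"),
    ("Secchi", "HABcyano biom", "-"),
    ("Secchi", "HABalg biom", "-"),
    ("Secchi", "MX biom", "-"),
    ("Secchi", "Buo biom", "-"),
    ("TP", "Large biom", "+"),
)

#: Covariates generated with zero effect on every taxon.
NULL_COVARIATES = ("Sal", "E")


def _lean_spec() -> gamm.GAMMSpec:
    return gamm.GAMMSpec(
        smooths=("x",), factors=(), random=(), ar1_group=None, variance_by=None
    )


def null_term_type1(n_reps: int = 500, n: int = 120, alpha: float = 0.05,
                    seed: int = 0) -> float:
    """Rejection rate of the smooth-term test under a true null."""
    rng = np.random.default_rng(seed)
    spec = _lean_spec()
    rejections = 0
    for _ in range(n_reps):
        df = pd.DataFrame({"x": rng.uniform(0.0, 1.0, n)})
        y = rng.normal(size=n)
        fit = gamm.fit_gamm(gamm.build_design(spec, df), y)
        rejections += gamm.term_pvalue(fit, "x") < alpha
    return rejections / n_reps


def strong_linear_power(n_reps: int = 200, n: int = 300, alpha: float = 0.001,
                        seed: int = 1) -> float:
    """Detection rate of a standardized slope of 1 at the working alpha."""
    rng = np.random.default_rng(seed)
    spec = _lean_spec()
    hits = 0
    for _ in range(n_reps):
        x = rng.uniform(0.0, 1.0, n)
        z = (x - x.mean()) / x.std()
        y = z + rng.normal(size=n)
        fit = gamm.fit_gamm(gamm.build_design(spec, pd.DataFrame({"x": x})), y)
        hits += gamm.term_pvalue(fit, "x") < alpha
    return hits / n_reps


def linear_slope_recovery(seed: int = 2, n: int = 300, slope: float = 2.0):
    """Single generate-and-refit: returns (slope error in SEs, term edf)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n)
    y = 1.0 + slope * x + rng.normal(size=n)
    fit = gamm.fit_gamm(gamm.build_design(_lean_spec(), pd.DataFrame({"x": x})), y)
    f, Vf = fit.smooth_values("x", np.array([0.0, 1.0]))
    est = f[1] - f[0]
    se = float(np.sqrt(Vf[0, 0] + Vf[1, 1] - 2.0 * Vf[0, 1]))
    return (est - slope) / se, fit.term_edf("x")


def station_sd_recovery(n_reps: int = 200, n_station: int = 40, m: int = 10,
                        sd: float = 1.0, seed: int = 3) -> float:
    """Median estimated random-intercept SD over generate-and-refit reps."""
    rng = np.random.default_rng(seed)
    spec = gamm.GAMMSpec(smooths=(), factors=(), random=("station",),
                         ar1_group=None, variance_by=None)
    codes = np.repeat(np.arange(n_station), m)
    df = pd.DataFrame({"station": [f"s{i:03d}" for i in codes]})
    design = gamm.build_design(spec, df)
    out = []
    for _ in range(n_reps):
        b = rng.normal(0.0, sd, n_station)
        y = b[codes] + rng.normal(size=n_station * m)
        fit = gamm.fit_gamm(design, y)
        out.append(fit.random_effect_sd("station"))
    return float(np.median(out))


def phi_recovery(n_reps: int = 120, n_station: int = 40, m: int = 12,
                 phi: float = 0.6, seed: int = 4) -> float:
    """Median estimated CAR(1) φ on regularly spaced dates."""
    rng = np.random.default_rng(seed)
    codes = np.repeat(np.arange(n_station), m)
    df = pd.DataFrame(
        {"station": [f"s{i:03d}" for i in codes], "t": np.tile(np.arange(m, dtype=float), n_station)}
    )
    spec = gamm.GAMMSpec(smooths=(), factors=(), random=(), ar1_group="station",
                         ar1_time="t", variance_by=None)
    design = gamm.build_design(spec, df)
    out = []
    sigma_innov = np.sqrt(1.0 - phi**2)
    for _ in range(n_reps):
        y = np.empty(n_station * m)
        for s in range(n_station):
            e = rng.normal()
            for k in range(m):
                if k:
                    e = phi * e + sigma_innov * rng.normal()
                y[s * m + k] = e
        fit = gamm.fit_gamm(design, y)
        out.append(fit.phi)
    return float(np.median(out))


def tukey_hsd_agreement(seed: int = 5, k: int = 4, n: int = 10) -> float:
    """Max |adjusted p − classical Tukey HSD p| on a balanced one-way layout."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(k)], n)
    y = rng.normal(0.0, 1.0, k * n) + np.repeat(np.linspace(0.0, 1.5, k), n)
    df = pd.DataFrame({"g": groups, "y": y})
    spec = gamm.GAMMSpec(smooths=(), factors=("g",), random=(), ar1_group=None,
                         variance_by=None)
    fit = gamm.fit_gamm(gamm.build_design(spec, df), y)
    contrasts = gamm.tukey_pairwise(gamm.estimated_marginal_means(fit, "g"))
    means = df.groupby("g")["y"].mean()
    mse = float(((df["y"] - df["g"].map(means)) ** 2).sum() / (k * n - k))
    worst = 0.0
    for c in contrasts:
        q = abs(means[c.level_a] - means[c.level_b]) / np.sqrt(mse / n)
        p_classic = float(stats.studentized_range.sf(q, k, k * n - k))
        worst = max(worst, abs(c.p_adjusted - p_classic))
    return worst


def sign_recovery_experiment(seed: int = 42, n_samples: int = 912) -> dict:
    """Fit the full model to one default-scale survey and score recovery of
    the injected effect signs, plus specificity on the null covariates.

    Returns a dict with the recovery rate over :data:`EFFECT_RESPONSE_PAIRS`,
    the fraction of null-covariate term tests that stay non-significant at
    the working alpha, and the per-pair classifications.
    """
    config = SimulationConfig(seed=seed, n_samples=n_samples)
    bundle = simulate_survey(config)
    result = pipeline.prepare_bundle(bundle)
    needed = sorted({resp for _, resp, _ in EFFECT_RESPONSE_PAIRS})
    fits = pipeline.fit_all(result, which=needed)

    detail = {}
    hits = 0
    for cov, resp, sign in EFFECT_RESPONSE_PAIRS:
        direction = gamm.classify_effect_direction(fits[resp], cov)
        ok = (direction == "positive" and sign == "+") or (
            direction == "negative" and sign == "-"
        )
        hits += ok
        detail[f"{cov}->{resp}"] = direction
    null_ns = 0
    null_total = 0
    for resp in needed:
        for cov in NULL_COVARIATES:
            null_total += 1
            null_ns += gamm.term_pvalue(fits[resp], cov) >= gamm.ALPHA
    return {
        "recovery_rate": hits / len(EFFECT_RESPONSE_PAIRS),
        "n_effects": len(EFFECT_RESPONSE_PAIRS),
        "null_ns_rate": null_ns / null_total,
        "n_null_tests": null_total,
        "n_samples": n_samples,
        "classifications": detail,
        "all_converged": all(f.converged for f in fits.values()),
    }
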