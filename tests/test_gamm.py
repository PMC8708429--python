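"""Design construction, REML fitting, inference, and Tukey contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phytotraits import gamm
from phytotraits.gamm import (
    GAMMSpec,
    GammError,
    build_design,
    classify_effect_direction,
    estimated_marginal_means,
    fit_gamm,
    term_pvalue,
    tukey_pairwise,
)


def _plain_spec(**kw):
    base = dict(smooths=("x",), factors=(), random=(), ar1_group=None, variance_by=None)
    base.update(kw)
    return GAMMSpec(**base)


def test_smooth_basis_loses_one_column_to_centering():
    df = pd.DataFrame({"x": np.linspace(0, 1, 100)})
    design = build_design(_plain_spec(k=6), df)
    assert design.p == 1 + 5  # intercept + (k-1) centered spline columns
    assert design.block("x").penalty_rank == 4  # linear null space survives


def test_single_level_factor_rejected():
    df = pd.DataFrame({"x": np.linspace(0, 1, 50), "g": ["a"] * 50})
    with pytest.raises(GammError, match="fewer than 2"):
        build_design(_plain_spec(factors=("g",)), df)


def test_duplicated_covariate_warns():
    x = np.linspace(0, 1, 80)
    df = pd.DataFrame({"x": x, "x2": x})
    with pytest.warns(UserWarning, match="identical"):
        build_design(_plain_spec(smooths=("x", "x2")), df)


def test_linear_effect_recovered_with_unit_edf():
    rng = np.random.default_rng(5)
    n = 300
    x = rng.uniform(0, 1, n)
    y = 1.0 + 2.0 * x + rng.normal(0, 1, n)
    design = build_design(_plain_spec(), pd.DataFrame({"x": x}))
    fit = fit_gamm(design, y)
    assert fit.converged
    assert fit.term_edf("x") == pytest.approx(1.0, abs=0.35)
    f, Vf = fit.smooth_values("x", np.array([0.0, 1.0]))
    slope = f[1] - f[0]
    se = np.sqrt(Vf[0, 0] + Vf[1, 1] - 2 * Vf[0, 1])
    assert abs(slope - 2.0) < 2 * se
    assert classify_effect_direction(fit, "x", alpha=0.05) == "positive"


def test_station_intercept_sd_recovered():
    rng = np.random.default_rng(6)
    n_station, m = 40, 10
    codes = np.repeat(np.arange(n_station), m)
    b = rng.normal(0, 1.0, n_station)
    x = rng.uniform(0, 1, n_station * m)
    y = b[codes] + rng.normal(0, 1, n_station * m)
    df = pd.DataFrame({"x": x, "station": [f"s{i:02d}" for i in codes]})
    fit = fit_gamm(build_design(_plain_spec(random=("station",)), df), y)
    assert 0.6 < fit.random_effect_sd("station") < 1.4


def test_car1_phi_recovered_on_regular_dates():
    rng = np.random.default_rng(7)
    rows = []
    for s in range(50):
        e = rng.normal()
        for k in range(12):
            if k:
                e = 0.6 * e + np.sqrt(1 - 0.36) * rng.normal()
            rows.append({"station": f"s{s:02d}", "t": float(k), "y": e})
    df = pd.DataFrame(rows)
    spec = GAMMSpec(smooths=(), factors=(), random=(), ar1_group="station",
                    ar1_time="t", variance_by=None)
    fit = fit_gamm(build_design(spec, df), df["y"].to_numpy())
    assert fit.converged
    assert 0.4 < fit.phi < 0.8


def test_constant_response_rejected():
    df = pd.DataFrame({"x": np.linspace(0, 1, 40)})
    design = build_design(_plain_spec(), df)
    with pytest.raises(GammError, match="constant"):
        fit_gamm(design, np.ones(40))


def test_unknown_term_rejected():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"x": rng.uniform(0, 1, 60)})
    fit = fit_gamm(build_design(_plain_spec(), df), rng.normal(size=60))
    with pytest.raises(GammError):
        term_pvalue(fit, "nope")


def test_null_effect_classified_ns():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({"x": rng.uniform(0, 1, 200)})
    fit = fit_gamm(build_design(_plain_spec(), df), rng.normal(size=200))
    assert classify_effect_direction(fit, "x") == "ns"


def test_unimodal_effect_classified_nonlinear():
    rng = np.random.default_rng(10)
    x = rng.uniform(-1, 1, 400)
    y = 1.0 - 3.0 * x**2 + rng.normal(0, 0.5, 400)
    fit = fit_gamm(build_design(_plain_spec(), pd.DataFrame({"x": x})), y)
    assert classify_effect_direction(fit, "x") == "nonlinear"


def test_heavy_penalty_collapses_smooth_to_line():
    """As the smoothing parameter grows the smooth tends to the least-squares line."""
    rng = np.random.default_rng(11)
    n = 150
    x = rng.uniform(0, 1, n)
    y = 0.5 + np.sin(6 * x) + rng.normal(0, 0.3, n)
    design = build_design(_plain_spec(), pd.DataFrame({"x": x}))
    _, beta, *_ = gamm._reml_core(design, design.X, y, np.array([1e9]), 0.0)
    fitted = design.X @ beta
    line = np.polyval(np.polyfit(x, y, 1), x)
    assert np.allclose(fitted, line, atol=1e-3)


def test_fixed_lambda_matches_direct_penalized_solve():
    """With the structure fixed the fit is ridge regression on the spline basis."""
    rng = np.random.default_rng(12)
    n = 120
    x = rng.uniform(0, 1, n)
    y = np.sin(4 * x) + rng.normal(0, 0.3, n)
    design = build_design(_plain_spec(), pd.DataFrame({"x": x}))
    lam = np.array([3.7])
    _, beta, *_ = gamm._reml_core(design, design.X, y, lam, 0.0)
    S = np.zeros((design.p, design.p))
    b = design.block("x")
    S[b.sl, b.sl] = lam[0] * b.penalty
    beta_direct = np.linalg.solve(design.X.T @ design.X + S, design.X.T @ y)
    assert np.allclose(beta, beta_direct, atol=1e-6)


def _balanced_oneway(seed=13, k=4, n=10):
    rng = np.random.default_rng(seed)
    means = [0.0, 0.5, 1.5, 1.6][:k]
    rows = []
    for g in range(k):
        for v in rng.normal(means[g], 1.0, n):
            rows.append({"g": f"g{g}", "y": v})
    return pd.DataFrame(rows)


def _fit_oneway(df):
    spec = GAMMSpec(smooths=(), factors=("g",), random=(), ar1_group=None, variance_by=None)
    design = build_design(spec, df)
    return fit_gamm(design, df["y"].to_numpy())


def test_emm_reduces_to_cell_means_in_balanced_oneway():
    df = _balanced_oneway()
    emm = estimated_marginal_means(_fit_oneway(df), "g")
    raw = df.groupby("g")["y"].mean()
    assert np.allclose(emm.estimates, raw[list(emm.levels)].to_numpy(), atol=1e-10)


def test_emm_unchanged_by_balanced_centered_covariate():
    """A covariate with identical distribution in every group cannot move
    the level contrasts (orthogonality of the centered basis)."""
    df = _balanced_oneway(seed=14)
    xs = np.linspace(0.05, 0.95, 10)
    df["x"] = np.tile(xs, 4)
    fit_plain = _fit_oneway(df)
    spec = GAMMSpec(smooths=("x",), factors=("g",), random=(), ar1_group=None,
                    variance_by=None)
    fit_cov = fit_gamm(build_design(spec, df), df["y"].to_numpy())
    emm_plain = estimated_marginal_means(fit_plain, "g")
    emm_cov = estimated_marginal_means(fit_cov, "g")
    d_plain = emm_plain.estimates - emm_plain.estimates[0]
    d_cov = emm_cov.estimates - emm_cov.estimates[0]
    assert np.allclose(d_plain, d_cov, atol=1e-8)


def test_tukey_matches_classical_hsd_on_balanced_fixture():
    df = _balanced_oneway()
    fit = _fit_oneway(df)
    contrasts = tukey_pairwise(estimated_marginal_means(fit, "g"))
    k, n = 4, 10
    means = df.groupby("g")["y"].mean()
    resid = df["y"] - df["g"].map(means)
    mse = float((resid**2).sum() / (len(df) - k))
    for c in contrasts:
        q = abs(means[c.level_a] - means[c.level_b]) / np.sqrt(mse / n)
        p_classic = float(stats.studentized_range.sf(q, k, len(df) - k))
        assert c.p_adjusted == pytest.approx(p_classic, abs=1e-6)


def test_tukey_against_statsmodels_reference():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = _balanced_oneway(seed=15)
    fit = _fit_oneway(df)
    ours = {
        tuple(sorted((c.level_a, c.level_b))): c.p_adjusted
        for c in tukey_pairwise(estimated_marginal_means(fit, "g"))
    }
    from itertools import combinations

    ref = pairwise_tukeyhsd(df["y"], df["g"])
    pairs = list(combinations(sorted(df["g"].unique()), 2))
    for (a, b), p in zip(pairs, ref.pvalues):
        assert ours[tuple(sorted((a, b)))] == pytest.approx(p, abs=1e-4)


def test_two_level_adjustment_is_identity():
    df = _balanced_oneway(k=2)
    contrasts = tukey_pairwise(estimated_marginal_means(_fit_oneway(df), "g"))
    assert len(contrasts) == 1
    c = contrasts[0]
    assert c.p_adjusted == pytest.approx(c.p_unadjusted, abs=1e-9)


def test_identical_group_means_give_null_pvalues():
    rng = np.random.default_rng(16)
    df = pd.DataFrame({"g": np.repeat(list("abcd"), 25), "y": rng.normal(size=100)})
    df["y"] -= df["g"].map(df.groupby("g")["y"].mean())  # exactly equal means
    contrasts = tukey_pairwise(estimated_marginal_means(_fit_oneway(df), "g"))
    assert all(c.p_adjusted > 0.999 for c in contrasts)


def test_spec_round_trips_through_yaml(tmp_path):
    import yaml

    cfg = {"smooths": ["Temp", "TP"], "k": 8, "factors": ["Area"], "random": [],
           "ar1_group": None, "variance_by": None, "alpha": 0.001}
    path = tmp_path / "model.yaml"
    path.write_text(yaml.safe_dump(cfg))
    spec = gamm.spec_from_file(path)
    assert spec.smooths == ("Temp", "TP") and spec.k == 8
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump({"nope": 1}))
    with pytest.raises(GammError, match="unknown"):
        gamm.spec_from_file(bad)


def test_adjusted_p_monotone_in_unadjusted():
    df = _balanced_oneway(seed=17)
    contrasts = tukey_pairwise(estimated_marginal_means(_fit_oneway(df), "g"))
    order_unadj = np.argsort([c.p_unadjusted for c in contrasts])
    order_adj = np.argsort([c.p_adjusted for c in contrasts])
    assert list(order_unadj) == list(order_adj)
    assert all(c.p_adjusted >= c.p_unadjusted - 1e-12 for c in contrasts)
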