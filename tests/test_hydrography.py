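"""Surface-layer means, EOS-80 density, stratification index, loading typology."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytotraits.hydrography import (
    LOADING_SOURCES,
    HydrographyError,
    LoadingShares,
    UnclassifiedLoadingError,
    classify_loading_source,
    stratification_index,
    summarize_sample,
    surface_layer_mean,
    water_density,
)


def test_surface_mean_basic_and_shallow_station():
    assert surface_layer_mean([0, 5, 10], [18, 16, 14]) == pytest.approx(16.0)
    # station 7 m deep: the entire water column is averaged
    assert surface_layer_mean([0, 3, 6], [18, 17, 13]) == pytest.approx(16.0)
    assert surface_layer_mean([0], [12.5]) == pytest.approx(12.5)


def test_surface_mean_excludes_deep_measurements():
    assert surface_layer_mean([0, 10, 30], [18, 14, 4]) == pytest.approx(16.0)


def test_surface_mean_requires_data():
    with pytest.raises(HydrographyError):
        surface_layer_mean([], [])
    with pytest.raises(HydrographyError):
        surface_layer_mean([15.0, 30.0], [10.0, 4.0])  # deep station, nothing ≤ 10 m


@given(perm=st.permutations(list(range(5))))
@settings(max_examples=30, deadline=None)
def test_surface_mean_permutation_invariant(perm):
    depths = np.array([0.0, 2.0, 5.0, 8.0, 10.0])
    values = np.array([18.0, 17.5, 16.0, 15.0, 14.0])
    ref = surface_layer_mean(depths, values)
    assert surface_layer_mean(depths[perm], values[perm]) == pytest.approx(ref)


def test_density_check_values_to_five_decimals():
    assert water_density(5.0, 0.0) == pytest.approx(999.96675, abs=5e-6)
    assert water_density(5.0, 35.0) == pytest.approx(1027.67547, abs=5e-6)


def test_density_monotone_in_salinity_study_range():
    t_grid = np.linspace(0, 26, 14)
    for t in t_grid:
        rho = water_density(np.full(8, t), np.linspace(0, 7, 8))
        assert np.all(np.diff(rho) > 0)
    assert water_density(5, 6) > water_density(5, 3)


def _density_reference(t, s):
    """Independently coded one-atmosphere EOS-80 density (Horner-form
    coefficients transcribed separately from the UNESCO tables)."""
    rho_w = 999.842594 + t * (
        6.793952e-2 + t * (-9.095290e-3 + t * (1.001685e-4 + t * (-1.120083e-6 + t * 6.536332e-9)))
    )
    A = 0.824493 + t * (-4.0899e-3 + t * (7.6438e-5 + t * (-8.2467e-7 + t * 5.3875e-9)))
    B = -5.72466e-3 + t * (1.0227e-4 + t * (-1.6546e-6))
    return rho_w + A * s + B * s**1.5 + 4.8314e-4 * s**2


def test_density_agrees_with_reference_over_study_range():
    """Agreement to <0.005 kg m⁻³ across the coastal study envelope."""
    for t in np.linspace(0, 26, 27):
        for s in np.linspace(0, 7, 15):
            assert abs(water_density(t, s) - _density_reference(t, s)) < 0.005


def test_density_rejects_out_of_range():
    with pytest.raises(HydrographyError):
        water_density(45.0, 5.0)
    with pytest.raises(HydrographyError):
        water_density(5.0, -1.0)


def test_stratification_index_direct_substitution():
    assert stratification_index(1002.0, 1002.0, 30.0) == 0.0
    assert stratification_index(1002.0, 1004.5, 25.0) == pytest.approx(100.0)
    assert stratification_index(1003.0, 1002.5, 10.0) == pytest.approx(-50.0)


def test_stratification_index_rejects_bad_depth():
    with pytest.raises(HydrographyError):
        stratification_index(1002.0, 1003.0, 0.0)


@given(
    delta=st.floats(-5, 5),
    depth=st.floats(0.5, 200),
    scale=st.floats(0.1, 10),
)
@settings(max_examples=60, deadline=None)
def test_stratification_linear_in_difference_and_inverse_in_depth(delta, depth, scale):
    base = stratification_index(1000.0, 1000.0 + delta, depth)
    assert stratification_index(1000.0, 1000.0 + scale * delta, depth) == pytest.approx(
        scale * base, rel=1e-9, abs=1e-9
    )
    assert stratification_index(1000.0, 1000.0 + delta, scale * depth) == pytest.approx(
        base / scale, rel=1e-9, abs=1e-9
    )


def _shares(wb, n_dom, p_dom, dom=0.7):
    def mk(dominant):
        rest = (1.0 - dom) / 3.0
        return {s: (dom if s == dominant else rest) for s in LOADING_SOURCES}

    return LoadingShares(wb, n_shares=mk(n_dom), p_shares=mk(p_dom))


def test_loading_classifier_exhaustive_enumeration():
    """Exactly five dominant-source pairs map to types; all others reject."""
    mapped = {}
    for n_dom, p_dom in itertools.product(LOADING_SOURCES, repeat=2):
        shares = _shares("wb", n_dom, p_dom)
        try:
            mapped[(n_dom, p_dom)] = classify_loading_source(shares)
        except UnclassifiedLoadingError:
            pass
    assert mapped == {
        ("offshore", "offshore"): 1,
        ("river", "point"): 2,
        ("river", "offshore"): 3,
        ("river", "river"): 4,
        ("river", "sediment"): 5,
    }


def test_loading_tie_is_an_error():
    tied = {s: 0.25 for s in LOADING_SOURCES}
    shares = LoadingShares("wb", n_shares=tied, p_shares=tied)
    with pytest.raises(UnclassifiedLoadingError, match="tied"):
        classify_loading_source(shares)


def test_loading_shares_must_sum_to_one():
    bad = {"river": 0.5, "point": 0.1, "sediment": 0.1, "offshore": 0.1}
    with pytest.raises(HydrographyError, match="sums to"):
        LoadingShares("wb", n_shares=bad, p_shares={s: 0.25 for s in LOADING_SOURCES})


def test_summarize_sample_homogeneous_column_gives_zero_e():
    prof = pd.DataFrame(
        {
            "depth": [0.0, 5.0, 10.0, 24.0],
            "temperature": [15.0] * 4,
            "salinity": [5.0] * 4,
            "tp": [20.0] * 4,
        }
    )
    summ = summarize_sample(prof, secchi=3.0, sample_id="S1")
    assert summ.e_index == pytest.approx(0.0, abs=1e-9)
    assert summ.bottom_depth_used == 24.0
    assert summ.temp_mean == pytest.approx(15.0)
    assert summ.tp_mean == pytest.approx(20.0)


def test_summarize_sample_stratified_column_positive_e():
    prof = pd.DataFrame(
        {
            "depth": [0.0, 5.0, 10.0, 29.0],
            "temperature": [18.0, 18.0, 18.0, 6.0],
            "salinity": [5.0, 5.0, 5.0, 7.0],
        }
    )
    summ = summarize_sample(prof, secchi=4.0, sample_id="S1")
    sigma_s = water_density(18.0, 5.0)
    sigma_b = water_density(6.0, 7.0)
    assert summ.e_index == pytest.approx((sigma_b - sigma_s) * 1000.0 / 29.0)
    assert summ.e_index > 0
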