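"""Response-matrix construction and Box–Cox transformation."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from phytotraits.community import CountingUnitObservation
from phytotraits.responses import (
    RESPONSE_COLUMNS,
    ResponseError,
    boxcox_inverse,
    boxcox_lambda,
    boxcox_transform,
    build_responses,
    fit_boxcox,
    positivity_shift,
    transform_matrix,
)
from phytotraits.trait_table import TraitRecord, TraitTable


def _table():
    recs = [
        TraitRecord("NFIX", "Fixer", "species", "cyanobacteria", n_fixation=True,
                    buoyancy=True, harmful=True, parent_genus="G1"),
        TraitRecord("DIAT", "Diatom", "species", "eukaryote", parent_genus="G2"),
        TraitRecord("FLAG", "Flagellate", "species", "eukaryote", mixotrophy=True,
                    motility=True, harmful=True, parent_genus="G3"),
    ]
    return TraitTable.from_records(recs)


def _obs(sample, taxon, biomass, max_dim=8.0, cells=1.0, unit="cell", biovol=523.598775):
    return CountingUnitObservation(
        sample_id=sample, taxon_id=taxon, unit_type=unit, units_per_litre=100.0,
        cells_per_unit=cells, biovolume_per_unit=biovol, biomass=biomass,
        max_dimension=max_dim,
    )


def test_exactly_27_canonical_columns():
    obs = [_obs("S1", "NFIX", 10.0), _obs("S1", "DIAT", 5.0)]
    matrix = build_responses(obs, _table())
    assert list(matrix.columns) == list(RESPONSE_COLUMNS)
    assert len(RESPONSE_COLUMNS) == 27


def test_single_carrier_community_degenerate_shares():
    matrix = build_responses([_obs("S1", "NFIX", 10.0)], _table())
    row = matrix.iloc[0]
    assert row["Nfix share"] == pytest.approx(1.0)
    assert row["nonNfix share"] == pytest.approx(0.0)
    assert row["Buo share"] == pytest.approx(1.0)


def test_hab_three_way_partition_arithmetic():
    # 30 µg/L harmful cyanobacterium + 70 µg/L plain diatom
    obs = [_obs("S1", "NFIX", 30.0), _obs("S1", "DIAT", 70.0)]
    row = build_responses(obs, _table()).iloc[0]
    assert row["HABcyano share"] == pytest.approx(0.3)
    assert row["nonHAB share"] == pytest.approx(0.7)
    assert row["HABalg share"] == pytest.approx(0.0)
    assert row["HABcyano biom"] + row["HABalg biom"] + row["nonHAB biom"] == pytest.approx(100.0)


def test_row_order_invariance():
    obs = [_obs("S1", "NFIX", 30.0), _obs("S1", "FLAG", 20.0), _obs("S2", "DIAT", 7.0)]
    a = build_responses(obs, _table())
    b = build_responses(list(reversed(obs)), _table())
    assert np.allclose(a.to_numpy(), b.to_numpy())
    assert list(a.index) == list(b.index)


def test_zero_total_biomass_sample_dropped(caplog):
    obs = [_obs("S1", "DIAT", 0.0), _obs("S2", "DIAT", 5.0)]
    with caplog.at_level("WARNING"):
        matrix = build_responses(obs, _table())
    assert list(matrix.index) == ["S2"]


@seed(20240901)
@given(
    biomasses=st.lists(
        st.tuples(st.sampled_from(["NFIX", "DIAT", "FLAG"]), st.floats(0.01, 1e4)),
        min_size=1,
        max_size=12,
    )
)
@settings(max_examples=60, deadline=None)
def test_partition_invariants_random_communities(biomasses):
    """Complement pairs sum to total; shares sum to one; HAB is three-way."""
    obs = [_obs("S1", t, b, max_dim=4.0 if t == "FLAG" else 25.0) for t, b in biomasses]
    row = build_responses(obs, _table()).iloc[0]
    total = sum(b for _, b in biomasses)
    for pair in (("Nfix", "nonNfix"), ("Buo", "nonBuo"), ("Mot", "nonMot"), ("MX", "AU"),
                 ("Small", "Large")):
        assert row[f"{pair[0]} biom"] + row[f"{pair[1]} biom"] == pytest.approx(
            total, abs=1e-9, rel=1e-9
        )
        assert row[f"{pair[0]} share"] + row[f"{pair[1]} share"] == pytest.approx(
            1.0, abs=1e-12
        )
    assert row["HABalg biom"] + row["HABcyano biom"] + row["nonHAB biom"] == pytest.approx(
        total, abs=1e-9, rel=1e-9
    )
    assert 0.0 <= row["Nfix share"] <= 1.0


def test_boxcox_lambda_recovers_log_family():
    rng = np.random.default_rng(101)
    lognormal = np.exp(rng.normal(size=500))
    assert -0.15 <= boxcox_lambda(lognormal) <= 0.15
    normal = rng.normal(loc=10.0, scale=3.0, size=500)
    assert 0.7 <= boxcox_lambda(normal) <= 1.3


def test_boxcox_degenerate_inputs():
    with pytest.raises(ResponseError):
        boxcox_lambda(np.full(10, 3.0))
    with pytest.raises(ResponseError):
        boxcox_lambda(np.array([0.0, 1.0, 2.0]))


def test_boxcox_transform_reference_points():
    assert boxcox_transform(np.array([np.e]), 0.0)[0] == pytest.approx(1.0)
    assert boxcox_transform(np.array([5.0]), 1.0)[0] == pytest.approx(4.0)


@given(
    lam=st.floats(-2, 2),
    shift=st.floats(0, 5),
    values=st.lists(st.floats(0.01, 1e3), min_size=1, max_size=20),
)
@settings(max_examples=80, deadline=None)
def test_boxcox_round_trip(lam, shift, values):
    y = np.array(values)
    z = boxcox_transform(y, lam, shift)
    back = boxcox_inverse(z, lam, shift)
    # strongly negative lambda compresses large values toward 1/|lambda|,
    # so the inverse amplifies rounding error; tolerance reflects that
    assert np.allclose(back, y, rtol=1e-6, atol=1e-8)


def test_positivity_shift_half_smallest_positive():
    assert positivity_shift(np.array([0.0, 4.0, 2.0])) == pytest.approx(1.0)
    assert positivity_shift(np.array([1.0, 2.0])) == 0.0


def test_transform_matrix_metadata(small_result):
    transformed, meta = transform_matrix(small_result.response_matrix)
    assert set(meta) == set(RESPONSE_COLUMNS)
    for col, m in meta.items():
        assert -2.0 <= m["lambda"] <= 2.0
        assert m["shift"] >= 0.0
        res = fit_boxcox(small_result.response_matrix[col].to_numpy())
        assert np.allclose(res.transformed, transformed[col].to_numpy())
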