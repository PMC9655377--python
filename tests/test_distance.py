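"""Max-normalization, environment means and Minkowski distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import minkowski as scipy_minkowski

from stabselect import (
    DegenerateTraitError,
    DimensionError,
    PhenotypeTable,
    distance_table,
    env_means,
    minkowski_distance,
    normalize_by_max,
)

from conftest import build_phenotype_df

vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=7
)


# ---------------------------------------------------------------- minkowski
def test_minkowski_unit_vector_cases():
    x, y = (1, 0, 0), (0, 1, 0)
    assert minkowski_distance(x, x, 1) == 0.0
    assert minkowski_distance(x, y, 1) == pytest.approx(2.0)
    assert minkowski_distance(x, y, 2) == pytest.approx(np.sqrt(2), abs=1e-12)


def test_minkowski_errors():
    with pytest.raises(DimensionError):
        minkowski_distance([1, 2], [1, 2, 3], 1)
    with pytest.raises(ValueError, match="p"):
        minkowski_distance([1], [2], 0.5)


def test_minkowski_matches_scipy_and_loop_oracle(manhattan_oracle):
    rng = np.random.default_rng(0)
    for _ in range(50):
        x, y = rng.uniform(size=7), rng.uniform(size=7)
        assert minkowski_distance(x, y, 1) == pytest.approx(
            manhattan_oracle(x, y), abs=1e-12
        )
        for p in (1, 2, 3):
            assert minkowski_distance(x, y, p) == pytest.approx(
                scipy_minkowski(x, y, p), abs=1e-12
            )


@settings(deadline=None, derandomize=True, max_examples=200)
@given(x=vectors, data=st.data(), p=st.sampled_from([1.0, 2.0, 3.0]))
def test_metric_axioms(x, data, p):
    n = len(x)
    fl = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
    y = data.draw(st.lists(fl, min_size=n, max_size=n))
    z = data.draw(st.lists(fl, min_size=n, max_size=n))
    dxy = minkowski_distance(x, y, p)
    assert dxy >= 0
    assert minkowski_distance(x, x, p) == 0
    assert dxy == minkowski_distance(y, x, p)
    assert minkowski_distance(x, z, p) <= dxy + minkowski_distance(y, z, p) + 1e-9


@settings(deadline=None, derandomize=True, max_examples=200)
@given(x=vectors, data=st.data())
def test_minkowski_non_increasing_in_p(x, data):
    fl = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
    y = data.draw(st.lists(fl, min_size=len(x), max_size=len(x)))
    d1 = minkowski_distance(x, y, 1)
    d2 = minkowski_distance(x, y, 2)
    d3 = minkowski_distance(x, y, 3)
    assert d1 >= d2 - 1e-12 >= d3 - 2e-12


# ------------------------------------------------------------ normalization
def test_normalize_by_max_column(toy_table):
    df = toy_table.data.copy()
    normalized = normalize_by_max(toy_table)
    values = normalized.data[list(toy_table.trait_names)]
    assert ((values >= 0) & (values <= 1)).all().all()
    # at least one exact 1 per trait, and the recorded maxima invert the map
    assert (values.max() == 1.0).all()
    restored = values * normalized.trait_maxima
    pd.testing.assert_frame_equal(restored, df[list(toy_table.trait_names)])


def test_normalize_simple_column_values():
    df = build_phenotype_df()
    df = df.iloc[:3].copy()
    df["replicate"] = [1, 2, 3]
    df["environment"] = "control"
    df["GERM"] = [2.0, 4.0, 8.0]
    table = PhenotypeTable(data=df, environments=("control",))
    out = normalize_by_max(table)
    assert list(out.data["GERM"]) == [0.25, 0.5, 1.0]


def test_normalize_idempotent(toy_table):
    once = normalize_by_max(toy_table)
    twice = normalize_by_max(once)
    pd.testing.assert_frame_equal(once.data, twice.data)
    assert (twice.trait_maxima == 1.0).all()


def test_normalize_all_zero_trait_errors(toy_df):
    toy_df["RDM"] = 0.0
    with pytest.raises(DegenerateTraitError, match="RDM"):
        normalize_by_max(PhenotypeTable(data=toy_df))


def test_scale_invariance_of_distances(toy_table):
    """Multiplying one raw trait by a positive constant leaves the
    distance table unchanged: the max-normalization absorbs the scale."""
    base = distance_table(env_means(normalize_by_max(toy_table)))
    scaled_df = toy_table.data.copy()
    scaled_df["SL"] = scaled_df["SL"] * 37.5
    scaled = PhenotypeTable(data=scaled_df)
    out = distance_table(env_means(normalize_by_max(scaled)))
    pd.testing.assert_frame_equal(base, out)


# -------------------------------------------------------------- env means
def test_env_means_equals_bruteforce_average(toy_table):
    normalized = normalize_by_max(toy_table)
    means = env_means(normalized)
    df = normalized.data
    for (g, env), row in means.iterrows():
        sub = df[(df["genotype"] == g) & (df["environment"] == env)]
        for trait in toy_table.trait_names:
            total = 0.0
            for v in sub[trait]:
                total += v
            assert row[trait] == pytest.approx(total / len(sub), abs=1e-12)


def test_env_means_single_replicate_identity(toy_df):
    single = toy_df[toy_df["replicate"] == 1].reset_index(drop=True)
    normalized = normalize_by_max(PhenotypeTable(data=single))
    means = env_means(normalized)
    for (g, env), row in means.iterrows():
        sub = normalized.data[
            (normalized.data["genotype"] == g) & (normalized.data["environment"] == env)
        ]
        np.testing.assert_allclose(
            row.to_numpy(), sub[list(normalized.trait_names)].iloc[0].to_numpy()
        )


def test_env_means_excludes_incomplete_genotype(toy_df):
    partial = toy_df[~((toy_df["genotype"] == "B") & (toy_df["environment"] == "drought"))]
    with pytest.warns(UserWarning):
        table = PhenotypeTable(data=partial.reset_index(drop=True))
    with pytest.warns(UserWarning, match="B"):
        means = env_means(normalize_by_max(table))
    assert set(means.index.get_level_values("genotype")) == {"A"}


# ---------------------------------------------------------- distance table
def test_distance_table_zero_distance_genotype(toy_df):
    stress_factors = {
        "A": {"saline": 1.0, "drought": 1.0},
        "B": {"saline": 0.7, "drought": 0.6},
    }
    df = build_phenotype_df(stress_factors=stress_factors)
    table = PhenotypeTable(data=df)
    dist = distance_table(env_means(normalize_by_max(table)))
    assert dist.loc["A", "ds"] == 0.0
    assert dist.loc["A", "dd"] == 0.0
    assert dist.loc["A", "rank_ds"] == 1
    assert dist.loc["A", "rank_dd"] == 1
    assert dist.loc["B", "ds"] > 0


def test_normalize_then_average_equals_average_then_normalize(toy_table):
    """The normalization map is linear, so the two orders agree."""
    normalized = normalize_by_max(toy_table)
    means_after = env_means(normalized)
    raw_means = toy_table.raw_env_means()
    maxima = toy_table.data[list(toy_table.trait_names)].max()
    means_before = raw_means / maxima
    pd.testing.assert_frame_equal(means_after, means_before)


def test_distance_table_ranks_are_permutation(toy_table):
    dist = distance_table(env_means(normalize_by_max(toy_table)))
    assert sorted(dist["rank_ds"]) == list(range(1, len(dist) + 1))
    assert sorted(dist["rank_dd"]) == list(range(1, len(dist) + 1))
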