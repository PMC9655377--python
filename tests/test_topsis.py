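"""TOPSIS scoring: oracle equivalence, invariances, errors and ties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabselect import (
    DegenerateMatrixError,
    TopsisError,
    WeightError,
    rank_alternatives,
    topsis_score,
)


def random_matrix(rng, m=None, n=None):
    m = m or rng.integers(2, 9)
    n = n or rng.integers(1, 5)
    return rng.uniform(0.05, 10.0, size=(int(m), int(n)))


def random_weights(rng, n):
    w = rng.uniform(0.05, 1.0, size=n)
    return w / w.sum()


# ------------------------------------------------------------- basic cases
def test_dominant_alternative_gets_extreme_scores():
    X = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["A", "B"])
    res = topsis_score(X, weights=[0.5, 0.5], orientations="cost")
    assert res.ci["A"] == pytest.approx(1.0)
    assert res.ci["B"] == pytest.approx(0.0)
    assert list(res.scores["rank"]) == [1, 2]


def test_proportional_columns_order_and_oracle(topsis_oracle):
    matrix = [[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]
    res = topsis_score(pd.DataFrame(matrix), weights=[0.5, 0.5])
    expected = topsis_oracle(matrix, [0.5, 0.5], cost=True)
    np.testing.assert_allclose(res.ci.to_numpy(), expected, atol=1e-12)
    assert (np.diff(res.ci.to_numpy()) < 0).all()  # cost: smaller rows win


def test_oracle_equivalence_random_matrices(topsis_oracle):
    rng = np.random.default_rng(20240101)
    for _ in range(200):
        X = random_matrix(rng)
        w = random_weights(rng, X.shape[1])
        res = topsis_score(pd.DataFrame(X), weights=w)
        expected = topsis_oracle(X.tolist(), list(w), cost=True)
        np.testing.assert_allclose(res.ci.to_numpy(), expected, atol=1e-12)
        assert ((res.ci >= 0) & (res.ci <= 1)).all()


def test_benefit_orientation_swaps_ideals():
    X = pd.DataFrame([[1.0], [2.0], [3.0]], index=list("abc"))
    cost = topsis_score(X, weights=[1.0], orientations="cost")
    benefit = topsis_score(X, weights=[1.0], orientations="benefit")
    assert rank_alternatives(cost) == ["a", "b", "c"]
    assert rank_alternatives(benefit) == ["c", "b", "a"]


# ----------------------------------------------------------------- errors
@pytest.mark.parametrize(
    "X, w, error",
    [
        ([[1.0, 2.0]], [0.5, 0.5], DegenerateMatrixError),          # m < 2
        ([[1.0, 0.0], [2.0, 0.0]], [0.5, 0.5], DegenerateMatrixError),  # zero col
        ([[1.0, 2.0], [2.0, 1.0]], [0.6, 0.6], WeightError),        # sum != 1
        ([[1.0, 2.0], [2.0, 1.0]], [-0.5, 1.5], WeightError),       # negative
        ([[1.0, -2.0], [2.0, 1.0]], [0.5, 0.5], TopsisError),       # negative entry
    ],
)
def test_invalid_inputs_raise(X, w, error):
    with pytest.raises(error):
        topsis_score(pd.DataFrame(X), weights=w)


def test_weight_normalization_is_opt_in():
    X = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(WeightError):
        topsis_score(X, weights=[1.0, 1.0])
    res = topsis_score(X, weights=[1.0, 1.0], normalize_weights=True)
    np.testing.assert_allclose(res.weights, [0.5, 0.5])


def test_bad_orientation_rejected():
    X = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(TopsisError, match="orientations"):
        topsis_score(X, weights=[0.5, 0.5], orientations=("cost", "upward"))


# -------------------------------------------------------------- tie policy
def test_identical_alternatives_score_half_with_warning():
    X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]], index=list("cab"))
    with pytest.warns(UserWarning, match="identical"):
        res = topsis_score(X, weights=[0.5, 0.5])
    assert (res.ci == 0.5).all()
    assert (res.scores["rank"] == 1).all()  # competition ranking: all tied
    assert rank_alternatives(res) == ["a", "b", "c"]  # lexicographic order


# ------------------------------------------------------------- invariances
@settings(deadline=None, derandomize=True, max_examples=100)
@given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100.0))
def test_column_scale_invariance(seed, scale):
    rng = np.random.default_rng(seed)
    X = random_matrix(rng)
    w = random_weights(rng, X.shape[1])
    base = topsis_score(pd.DataFrame(X), weights=w).ci
    scaled = X.copy()
    scaled[:, 0] *= scale
    out = topsis_score(pd.DataFrame(scaled), weights=w).ci
    np.testing.assert_allclose(out.to_numpy(), base.to_numpy(), atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(seed=st.integers(0, 10_000))
def test_permutation_equivariance(seed):
    rng = np.random.default_rng(seed)
    X = random_matrix(rng)
    w = random_weights(rng, X.shape[1])
    labels = [f"alt{i}" for i in range(X.shape[0])]
    base = topsis_score(pd.DataFrame(X, index=labels), weights=w).ci
    perm = rng.permutation(X.shape[0])
    permuted = topsis_score(
        pd.DataFrame(X[perm], index=[labels[i] for i in perm]), weights=w
    ).ci
    np.testing.assert_allclose(
        permuted.sort_index().to_numpy(), base.sort_index().to_numpy(), atol=1e-12
    )


@settings(deadline=None, derandomize=True, max_examples=100)
@given(seed=st.integers(0, 10_000))
def test_single_cost_criterion_orders_by_raw_value(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.1, 5.0, size=rng.integers(2, 8))
    labels = [f"g{i}" for i in range(len(values))]
    res = topsis_score(
        pd.DataFrame({"d": values}, index=labels), weights=[1.0]
    )
    expected = [labels[i] for i in sorted(range(len(values)), key=lambda i: (values[i], labels[i]))]
    assert rank_alternatives(res) == expected


def test_rank_alternatives_bruteforce_sort():
    rng = np.random.default_rng(9)
    X = random_matrix(rng, m=10, n=3)
    w = random_weights(rng, 3)
    labels = [f"g{i:02d}" for i in range(10)]
    res = topsis_score(pd.DataFrame(X, index=labels), weights=w)
    brute = sorted(labels, key=lambda lab: (-res.ci[lab], lab))
    assert rank_alternatives(res) == brute
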