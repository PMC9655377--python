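"""Shared fixtures: tiny deterministic phenotype tables and step-by-step
reference implementations kept independent of the package internals."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from stabselect import DEFAULT_TRAITS, PhenotypeTable

TOY_CONTROL_MEANS = {
    "A": {"GERM": 96.0, "SL": 12.0, "RL": 16.0, "TL": 28.0, "SDM": 0.15, "RDM": 0.06, "TDM": 0.21},
    "B": {"GERM": 88.0, "SL": 10.0, "RL": 14.0, "TL": 24.0, "SDM": 0.12, "RDM": 0.05, "TDM": 0.17},
}


def build_phenotype_df(
    control_means: dict[str, dict[str, float]] | None = None,
    stress_factors: dict[str, dict[str, float]] | None = None,
    n_replicates: int = 4,
    jitter: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic long-format table; stress means scale control means."""
    control_means = control_means or TOY_CONTROL_MEANS
    stress_factors = stress_factors or {
        "A": {"saline": 0.9, "drought": 0.8},
        "B": {"saline": 0.7, "drought": 0.6},
    }
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, means in control_means.items():
        for env in ("control", "saline", "drought"):
            factor = 1.0 if env == "control" else stress_factors[genotype][env]
            for rep in range(1, n_replicates + 1):
                row = {"genotype": genotype, "environment": env, "replicate": rep}
                for trait, mu in means.items():
                    value = mu * factor
                    if jitter:
                        value *= 1.0 + jitter * rng.standard_normal()
                    row[trait] = min(value, 100.0) if trait == "GERM" else value
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_df() -> pd.DataFrame:
    return build_phenotype_df()


@pytest.fixture
def toy_table(toy_df) -> PhenotypeTable:
    return PhenotypeTable(data=toy_df)


@pytest.fixture
def toy_csv(tmp_path, toy_df):
    path = tmp_path / "phenotypes.csv"
    toy_df.to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
# Independent oracles (literal transcriptions, loop-based, no numpy
# vectorization shared with the implementation under test).


def topsis_reference(matrix, weights, cost=True):
    """Literal five-step TOPSIS transcription: returns the closeness list."""
    m = len(matrix)
    n = len(matrix[0])
    r = [[0.0] * n for _ in range(m)]
    for j in range(n):
        norm = math.sqrt(sum(matrix[i][j] ** 2 for i in range(m)))
        for i in range(m):
            r[i][j] = matrix[i][j] / norm
    v = [[r[i][j] * weights[j] for j in range(n)] for i in range(m)]
    a_worst, a_best = [], []
    for j in range(n):
        col = [v[i][j] for i in range(m)]
        if cost:
            a_worst.append(max(col))
            a_best.append(min(col))
        else:
            a_worst.append(min(col))
            a_best.append(max(col))
    ci = []
    for i in range(m):
        s_iw = math.sqrt(sum((v[i][j] - a_worst[j]) ** 2 for j in range(n)))
        s_ib = math.sqrt(sum((v[i][j] - a_best[j]) ** 2 for j in range(n)))
        ci.append(s_iw / (s_iw + s_ib))
    return ci


def manhattan_reference(x, y):
    """Loop-based sum of absolute differences."""
    total = 0.0
    for a, b in zip(x, y):
        total += abs(a - b)
    return total


@pytest.fixture
def topsis_oracle():
    return topsis_reference


@pytest.fixture
def manhattan_oracle():
    return manhattan_reference
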