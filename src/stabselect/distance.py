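"""Trait-space similarity: max-normalization and Minkowski distances.

Each genotype x environment combination is a point in an n-dimensional
trait space (n = 7 by default).  Traits are made dimensionless by dividing
by their maximum over the *whole* dataset (all genotypes, environments and
replicates pooled), so that control and stress vectors share one scale.
Stability is then the Minkowski distance between a genotype's control
mean vector and its stress mean vector; p = 1 (Manhattan) is the default
because it discriminates best in higher-dimensional trait spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotype import PhenotypeTable


class DegenerateTraitError(ValueError):
    """A trait column is entirely zero, so max-normalization is undefined."""


class DimensionError(ValueError):
    """Vectors of different lengths were compared."""


@dataclass(frozen=True)
class NormalizedTable:
    """A :class:`PhenotypeTable` with traits rescaled to [0, 1].

    ``trait_maxima`` records the per-trait maxima used, so the map can be
    inverted and audited.
    """

    data: pd.DataFrame
    trait_names: tuple[str, ...]
    environments: tuple[str, ...]
    control: str
    incomplete: tuple[str, ...]
    trait_maxima: pd.Series

    def env_means(self) -> pd.DataFrame:
        """Per-genotype, per-environment mean vectors (normalized space)."""
        return env_means(self)


def normalize_by_max(table: PhenotypeTable | NormalizedTable) -> NormalizedTable:
    """Divide every trait by its dataset-wide maximum.

    The maxima pool all environments and replicates: distances compare
    environments, so both vectors must share one scale.  Idempotent: a
    normalized table has per-trait maxima of exactly 1.

    Raises
    ------
    DegenerateTraitError
        If a trait column has no strictly positive value.
    """
    df = table.data.copy()
    maxima = df[list(table.trait_names)].max()
    zero = [t for t in table.trait_names if not maxima[t] > 0]
    if zero:
        raise DegenerateTraitError(
            f"trait(s) with non-positive maximum cannot be normalized: {zero}"
        )
    df[list(table.trait_names)] = df[list(table.trait_names)] / maxima
    return NormalizedTable(
        data=df,
        trait_names=table.trait_names,
        environments=table.environments,
        control=table.control,
        incomplete=table.incomplete,
        trait_maxima=maxima,
    )


def env_means(table: NormalizedTable) -> pd.DataFrame:
    """Average replicates into one vector per (genotype, environment).

    Genotypes flagged as incomplete (missing an environment) are excluded
    with a warning rather than imputed.
    """
    df = table.data
    if table.incomplete:
        warnings.warn(
            f"excluding incomplete genotype(s): {', '.join(table.incomplete)}",
            stacklevel=2,
        )
        df = df[~df["genotype"].isin(table.incomplete)]
    return df.groupby(["genotype", "environment"], sort=True)[
        list(table.trait_names)
    ].mean()


def minkowski_distance(x, y, p: float = 1.0) -> float:
    """Minkowski distance ``(sum_i |x_i - y_i|**p) ** (1/p)``.

    ``p = 1`` is the Manhattan (city-block) distance, ``p = 2`` Euclidean.

    Raises
    ------
    DimensionError
        If ``x`` and ``y`` differ in length.
    ValueError
        If ``p < 1`` (not a metric).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(f"shape mismatch: {x.shape} vs {y.shape}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


def distance_table(
    means: pd.DataFrame,
    control: str = "control",
    stresses: tuple[str, str] = ("saline", "drought"),
    p: float = 1.0,
) -> pd.DataFrame:
    """Control-to-stress distances per genotype: the TOPSIS decision matrix.

    Parameters
    ----------
    means : pandas.DataFrame
        Output of :func:`env_means`: one normalized mean vector per
        (genotype, environment).
    control : str
        Reference environment label.
    stresses : (str, str)
        The two stress environments; the first fills ``ds``, the second
        ``dd``.
    p : float
        Minkowski order (1 = Manhattan).

    Returns
    -------
    pandas.DataFrame
        Indexed by genotype with columns ``ds``, ``dd``, ``rank_ds``,
        ``rank_dd``.  Ranks are ascending-distance competition ranks
        (ties share the smallest position); listing order breaks ties by
        genotype label.
    """
    required = (control, *stresses)
    genotypes = sorted(
        g
        for g, sub in means.groupby(level="genotype", sort=True)
        if set(required) <= set(sub.index.get_level_values("environment"))
    )
    dropped = sorted(set(means.index.get_level_values("genotype")) - set(genotypes))
    if dropped:
        warnings.warn(
            f"genotype(s) lacking {required} excluded: {', '.join(map(str, dropped))}",
            stacklevel=2,
        )
    if not genotypes:
        raise ValueError("no genotype has vectors for the control and both stresses")

    rows = {}
    for g in genotypes:
        x_control = means.loc[(g, control)].to_numpy(dtype=float)
        rows[g] = [
            minkowski_distance(x_control, means.loc[(g, env)].to_numpy(dtype=float), p)
            for env in stresses
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["ds", "dd"])
    out.index.name = "genotype"
    out["rank_ds"] = out["ds"].rank(method="min").astype(int)
    out["rank_dd"] = out["dd"].rank(method="min").astype(int)
    out.attrs["p"] = p
    out.attrs["control"] = control
    out.attrs["stresses"] = tuple(stresses)
    return out
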