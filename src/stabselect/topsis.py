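"""TOPSIS: Technique for Order Preference by Similarity to Ideal Solution.

Ranks m alternatives described by n criteria by their relative closeness
to an ideal point in weighted, vector-normalized criterion space:

1. vector-normalize each criterion column, r_ij = x_ij / sqrt(sum_i x_ij^2);
2. weight, v_ij = r_ij * w_j with sum_j w_j = 1;
3. take the ideal (best) and anti-ideal (worst) points per column — for a
   cost criterion (smaller is better, e.g. a distance) the ideal is the
   column minimum and the anti-ideal the maximum; swapped for benefit
   criteria;
4. Euclidean separations S_ib (from best) and S_iw (from worst);
5. closeness C_i = S_iw / (S_iw + S_ib), ranked descending.

C_i = 1 means the alternative coincides with the ideal point, C_i = 0 with
the anti-ideal.  The default orientation is *cost*, matching the use here:
the criteria are distances from an unstressed control, so smaller is
better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

WEIGHT_TOL = 1e-9


class TopsisError(ValueError):
    """Base class for decision-matrix and scoring errors."""


class DegenerateMatrixError(TopsisError):
    """Fewer than two alternatives, or a criterion column is all zero."""


class WeightError(TopsisError):
    """Weights are negative or do not sum to one."""


@dataclass(frozen=True)
class TopsisResult:
    """Scores and separations for every alternative.

    Attributes
    ----------
    scores : pandas.DataFrame
        Indexed by alternative label; columns ``Siw`` (separation from the
        anti-ideal), ``Sib`` (separation from the ideal), ``Ci`` (closeness,
        in [0, 1]) and ``rank`` (descending-Ci competition rank).
    ideal_best, ideal_worst : pandas.Series
        The ideal and anti-ideal points in weighted normalized space.
    weights : numpy.ndarray
    orientations : tuple of str
        ``"cost"`` or ``"benefit"`` per criterion.
    """

    scores: pd.DataFrame
    ideal_best: pd.Series
    ideal_worst: pd.Series
    weights: np.ndarray
    orientations: tuple[str, ...]

    @property
    def ci(self) -> pd.Series:
        return self.scores["Ci"]


def _check_matrix(X: pd.DataFrame) -> None:
    values = X.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DegenerateMatrixError(
            f"need at least 2 alternatives, got {X.shape[0]}"
        )
    if X.shape[1] < 1:
        raise DegenerateMatrixError("need at least 1 criterion")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise TopsisError("decision matrix entries must be finite and >= 0")
    zero_cols = [c for c, norm in zip(X.columns, np.linalg.norm(values, axis=0)) if norm == 0]
    if zero_cols:
        raise DegenerateMatrixError(
            f"criterion column(s) entirely zero cannot be normalized: {zero_cols}"
        )


def _check_weights(
    w: Sequence[float], n: int, normalize: bool
) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise WeightError(f"expected {n} weights, got shape {w.shape}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise WeightError("weights must be finite and non-negative")
    total = w.sum()
    if abs(total - 1.0) > WEIGHT_TOL:
        if not normalize:
            raise WeightError(
                f"weights sum to {total!r}, not 1 (pass normalize_weights=True "
                "to rescale explicitly)"
            )
        if total == 0:
            raise WeightError("weights sum to zero; cannot normalize")
        w = w / total
    return w


def topsis_score(
    X: pd.DataFrame | np.ndarray,
    weights: Sequence[float],
    orientations: str | Sequence[str] = "cost",
    labels: Sequence[str] | None = None,
    normalize_weights: bool = False,
) -> TopsisResult:
    """Score alternatives by relative closeness to the ideal solution.

    Parameters
    ----------
    X : DataFrame or 2-D array
        Decision matrix, m alternatives x n criteria, non-negative.
    weights : sequence of n floats
        Criterion weights summing to 1 (within 1e-9).  Weights that do not
        sum to 1 are an error unless ``normalize_weights=True``; silent
        renormalization hides bugs.
    orientations : str or sequence of str
        ``"cost"`` (smaller is better; the default — the criteria here are
        distances) or ``"benefit"``, one value per criterion or a single
        value applied to all.
    labels : sequence, optional
        Alternative labels when ``X`` is a bare array.

    Returns
    -------
    TopsisResult

    Notes
    -----
    If every alternative coincides in weighted normalized space, all
    closeness values are defined as 0.5 (with a warning) rather than 0/0.
    """
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
        index = list(labels) if labels is not None else list(range(X.shape[0]))
        X = pd.DataFrame(X, index=index)
    _check_matrix(X)
    m, n = X.shape
    w = _check_weights(weights, n, normalize_weights)

    if isinstance(orientations, str):
        orientations = (orientations,) * n
    orientations = tuple(orientations)
    if len(orientations) != n or any(o not in ("cost", "benefit") for o in orientations):
        raise TopsisError(
            f"orientations must be 'cost'/'benefit' per criterion, got {orientations}"
        )

    values = X.to_numpy(dtype=float)
    r = values / np.linalg.norm(values, axis=0)          # step 1
    v = r * w                                            # step 2
    is_cost = np.array([o == "cost" for o in orientations])
    col_max, col_min = v.max(axis=0), v.min(axis=0)
    a_worst = np.where(is_cost, col_max, col_min)        # step 3
    a_best = np.where(is_cost, col_min, col_max)
    s_iw = np.sqrt(((v - a_worst) ** 2).sum(axis=1))     # step 4
    s_ib = np.sqrt(((v - a_best) ** 2).sum(axis=1))
    denom = s_iw + s_ib
    if np.all(denom == 0):
        warnings.warn(
            "all alternatives identical in weighted space; closeness set to 0.5",
            stacklevel=2,
        )
        ci = np.full(m, 0.5)
    else:
        # a single coincident pair cannot make denom zero unless all rows
        # coincide, since a_best != a_worst in at least one column
        ci = s_iw / denom                                # step 5

    scores = pd.DataFrame(
        {"Siw": s_iw, "Sib": s_ib, "Ci": ci}, index=X.index
    )
    scores.index.name = "alternative" if X.index.name is None else X.index.name
    scores["rank"] = scores["Ci"].rank(ascending=False, method="min").astype(int)
    return TopsisResult(
        scores=scores,
        ideal_best=pd.Series(a_best, index=X.columns),
        ideal_worst=pd.Series(a_worst, index=X.columns),
        weights=w,
        orientations=orientations,
    )


def rank_alternatives(result: TopsisResult) -> list:
    """Alternative labels ordered by descending closeness.

    Ties are broken lexicographically by label so the ordering is
    deterministic; tied alternatives share the same ``rank`` value
    (competition ranking) in ``result.scores``.
    """
    scores = result.scores
    order = sorted(scores.index, key=lambda lab: (-scores.at[lab, "Ci"], str(lab)))
    return list(order)
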