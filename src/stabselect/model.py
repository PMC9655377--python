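"""Genotype-stability selection model: normalize -> means -> distances -> TOPSIS.

The model treats each genotype's seven-trait phenotype as a point in a
normalized trait space.  Stability under a stress environment is the
Manhattan distance between the genotype's control mean vector and its
stress mean vector; the two stress distances (saline ``ds``, drought
``dd``) form a 2-criterion cost decision matrix that TOPSIS fuses into a
single closeness score per genotype.  High closeness = small distances in
both stresses = a stable genotype.

Usage::

    model = GenotypeStabilityModel.from_csv("phenotypes.csv")
    res = model.fit(weights=(0.5, 0.5))
    print(res.summary())
    res.weight_sweep().selection_frequency
    res.percent_change()
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import distance as _distance
from . import topsis as _topsis
from .phenotype import PhenotypeTable, read_phenotypes
from .topsis import TopsisResult

logger = logging.getLogger(__name__)

#: Weight pairs (w_s, w_d) for the robustness sweep.
DEFAULT_WEIGHT_GRID: tuple[tuple[float, float], ...] = (
    (0.1, 0.9),
    (0.3, 0.7),
    (0.5, 0.5),
    (0.7, 0.3),
    (0.9, 0.1),
)

#: Decimal places used in printed summaries (not in stored values).
SUMMARY_PRECISION = 4


class GenotypeStabilityModel:
    """Multi-environment stability selection from a phenotype table.

    Parameters
    ----------
    table : PhenotypeTable
        Replicated trait measurements for a control and two stress
        environments.
    control : str
        Label of the reference environment.
    stresses : (str, str)
        The two stress environments; the first maps to criterion ``ds``,
        the second to ``dd``.
    p : float
        Minkowski order of the trait-space distance; 1 (Manhattan) by
        default.
    """

    def __init__(
        self,
        table: PhenotypeTable,
        control: str = "control",
        stresses: tuple[str, str] = ("saline", "drought"),
        p: float = 1.0,
    ) -> None:
        self.table = table
        self.control = control
        self.stresses = tuple(stresses)
        self.p = float(p)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        column_map: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "GenotypeStabilityModel":
        trait_names = kwargs.pop("trait_names", None)
        read_kwargs = {}
        if trait_names is not None:
            read_kwargs["trait_names"] = trait_names
        table = read_phenotypes(path, column_map=column_map, **read_kwargs)
        return cls(table, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GenotypeStabilityModel":
        trait_names = kwargs.pop("trait_names", None)
        table_kwargs = {}
        if trait_names is not None:
            table_kwargs["trait_names"] = tuple(trait_names)
        table = PhenotypeTable(data=df.reset_index(drop=True), **table_kwargs)
        return cls(table, **kwargs)

    # ------------------------------------------------------------------
    def distances(self) -> pd.DataFrame:
        """Per-genotype control-to-stress distances (the decision matrix)."""
        normalized = _distance.normalize_by_max(self.table)
        logger.info(
            "normalization maxima: %s",
            normalized.trait_maxima.round(SUMMARY_PRECISION).to_dict(),
        )
        means = _distance.env_means(normalized)
        return _distance.distance_table(
            means, control=self.control, stresses=self.stresses, p=self.p
        )

    def fit(
        self, weights: tuple[float, float] = (0.5, 0.5)
    ) -> "GenotypeStabilityResults":
        """Run the full pipeline and score genotypes by TOPSIS closeness."""
        dist = self.distances()
        result = _topsis.topsis_score(
            dist[["ds", "dd"]], weights=list(weights), orientations="cost"
        )
        logger.info(
            "ideal best %s / worst %s",
            result.ideal_best.round(SUMMARY_PRECISION).to_dict(),
            result.ideal_worst.round(SUMMARY_PRECISION).to_dict(),
        )
        return GenotypeStabilityResults(
            model=self, weights=tuple(weights), distances=dist, topsis=result
        )


@dataclass(frozen=True)
class SweepResult:
    """TOPSIS runs over a grid of criterion-weight pairs.

    Attributes
    ----------
    entries : tuple of (w_s, w_d, TopsisResult)
    k : int
        Size of the per-pair top lists.
    top_k : dict
        ``(w_s, w_d) -> list of the k highest-closeness genotypes``.
    selection_frequency : pandas.Series
        Fraction of grid points at which each genotype enters the top-k.
    """

    entries: tuple[tuple[float, float, TopsisResult], ...]
    k: int
    top_k: dict[tuple[float, float], list[str]] = field(default_factory=dict)
    selection_frequency: pd.Series = field(default_factory=pd.Series)

    def to_frame(self) -> pd.DataFrame:
        """Long table: w_s, w_d, genotype, Ci, rank."""
        frames = []
        for w_s, w_d, res in self.entries:
            frame = res.scores.reset_index().rename(
                columns={res.scores.index.name or "index": "genotype"}
            )
            frame.insert(0, "w_d", w_d)
            frame.insert(0, "w_s", w_s)
            frames.append(frame[["w_s", "w_d", "genotype", "Ci", "rank"]])
        return pd.concat(frames, ignore_index=True)


class GenotypeStabilityResults:
    """Fitted stability selection: distances, TOPSIS scores and reports."""

    def __init__(
        self,
        model: GenotypeStabilityModel,
        weights: tuple[float, float],
        distances: pd.DataFrame,
        topsis: TopsisResult,
    ) -> None:
        self.model = model
        self.weights = weights
        self.distances = distances
        self.topsis = topsis

    # ------------------------------------------------------------------
    @property
    def scores(self) -> pd.DataFrame:
        """Per-genotype ds, dd, separations, closeness and rank."""
        merged = self.distances[["ds", "dd"]].join(self.topsis.scores)
        merged.index.name = "genotype"
        return merged

    @property
    def ci(self) -> pd.Series:
        return self.topsis.scores["Ci"]

    def ranking(self) -> list[str]:
        """Genotypes ordered from most to least stable."""
        return _topsis.rank_alternatives(self.topsis)

    def top(self, k: int = 10) -> list[str]:
        return self.ranking()[:k]

    def summary(self, top: int = 10) -> str:
        """Readable report of the top genotypes, statsmodels-style."""
        counts = self.model.table.counts()
        head = self.scores.loc[self.top(top)].round(SUMMARY_PRECISION)
        lines = [
            "Genotype stability selection (Minkowski distance + TOPSIS)",
            "=" * 62,
            f"genotypes: {counts['genotypes']}   environments: "
            f"{counts['environments']}   replicates: {counts['replicates']}",
            f"control: {self.model.control!r}   stresses: {self.model.stresses}",
            f"distance order p: {self.model.p}   criterion weights "
            f"(ds, dd): {self.weights}",
            "-" * 62,
            head.to_string(),
            "-" * 62,
            "Ci: closeness to the ideal (stable) genotype; higher is better.",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - convenience only
        best = self.ranking()[0]
        return (
            f"<GenotypeStabilityResults: {len(self.scores)} genotypes, "
            f"best={best!r}>"
        )

    # ------------------------------------------------------------------
    def weight_sweep(
        self,
        grid: Sequence[tuple[float, float]] = DEFAULT_WEIGHT_GRID,
        k: int = 10,
    ) -> SweepResult:
        """Re-run TOPSIS over a grid of (w_s, w_d) pairs.

        Distances are fixed; only the criterion weights change.  Genotypes
        that stay in the top-k across the whole grid are robust to the
        saline-vs-drought trade-off.  Degenerate pairs (1, 0) / (0, 1) are
        allowed but flagged, since they reduce TOPSIS to a single-criterion
        ranking.
        """
        entries = []
        top_k: dict[tuple[float, float], list[str]] = {}
        for w_s, w_d in grid:
            if w_s < 0 or w_d < 0 or abs(w_s + w_d - 1.0) > 1e-9:
                raise _topsis.WeightError(
                    f"grid pair ({w_s}, {w_d}) must be non-negative and sum to 1"
                )
            if 0.0 in (w_s, w_d):
                warnings.warn(
                    f"degenerate weight pair ({w_s}, {w_d}): TOPSIS reduces to a "
                    "single-criterion ranking",
                    stacklevel=2,
                )
            res = _topsis.topsis_score(
                self.distances[["ds", "dd"]], weights=[w_s, w_d], orientations="cost"
            )
            entries.append((w_s, w_d, res))
            top_k[(w_s, w_d)] = _topsis.rank_alternatives(res)[:k]
        counts = pd.Series(
            [g for sel in top_k.values() for g in sel], dtype=object
        ).value_counts()
        freq = (
            counts.reindex(self.scores.index, fill_value=0).astype(float) / len(grid)
        )
        freq.name = "selection_frequency"
        return SweepResult(
            entries=tuple(entries),
            k=k,
            top_k=top_k,
            selection_frequency=freq,
        )

    def percent_change(self) -> pd.DataFrame:
        """Percentage trait change under stress, on the raw scales.

        ``pct = 100 * (control_mean - stress_mean) / control_mean`` per
        genotype, comparison and trait; positive = decrease under stress,
        negative = increase.  A zero control mean leaves that cell NaN
        (flagged with a warning) rather than dividing by zero.
        """
        table = self.model.table
        raw = table.raw_env_means()
        rows = []
        undefined = []
        for g in self.scores.index:
            control = raw.loc[(g, self.model.control)]
            for env in self.model.stresses:
                stress = raw.loc[(g, env)]
                comparison = f"Control/{env.capitalize()}"
                for trait in table.trait_names:
                    c = control[trait]
                    if c > 0:
                        pct = 100.0 * (c - stress[trait]) / c
                    else:
                        pct = np.nan
                        undefined.append((g, comparison, trait))
                    rows.append(
                        {
                            "genotype": g,
                            "comparison": comparison,
                            "trait": trait,
                            "pct": pct,
                        }
                    )
        if undefined:
            warnings.warn(
                f"zero control mean; percentage change undefined for: {undefined}",
                stacklevel=2,
            )
        return pd.DataFrame(rows)

    def plot_scores(self, ax=None, top: int | None = None):
        """Horizontal bar chart of closeness scores (optional diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(self.scores))))
        order = self.ranking()
        if top is not None:
            order = order[:top]
        ci = self.ci.loc[order][::-1]
        ax.barh(ci.index, ci.to_numpy())
        ax.set_xlabel("TOPSIS closeness $C_i$")
        ax.set_ylabel("genotype")
        ax.set_xlim(0, 1)
        return ax


# ----------------------------------------------------------------------
# Functional pipeline surface (thin wrappers over the model objects).


def run_selection(
    table: PhenotypeTable,
    weights: tuple[float, float] = (0.5, 0.5),
    p: float = 1.0,
) -> tuple[pd.DataFrame, TopsisResult]:
    """Full pipeline: returns the distance table and the TOPSIS result."""
    res = GenotypeStabilityModel(table, p=p).fit(weights=weights)
    return res.distances, res.topsis


def weight_sweep(
    table: PhenotypeTable,
    grid: Sequence[tuple[float, float]] = DEFAULT_WEIGHT_GRID,
    p: float = 1.0,
    k: int = 10,
) -> SweepResult:
    """Weight-robustness sweep over a fresh fit of ``table``."""
    return GenotypeStabilityModel(table, p=p).fit().weight_sweep(grid=grid, k=k)


def percent_change(table: PhenotypeTable, p: float = 1.0) -> pd.DataFrame:
    """Raw-scale percentage change report for every genotype."""
    return GenotypeStabilityModel(table, p=p).fit().percent_change()
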