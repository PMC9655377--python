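"""Replicated multi-environment phenotype tables.

The canonical on-disk layout is long format: one row per
genotype x environment x replicate, with one column per trait.  A tidy
layout (``trait``/``value`` columns) is pivoted to the canonical layout
on read.  All downstream stages consume :class:`PhenotypeTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Default trait list: germination (%), shoot/root/total seedling length (cm),
#: shoot/root/total seedling dry matter (g).
DEFAULT_TRAITS: tuple[str, ...] = ("GERM", "SL", "RL", "TL", "SDM", "RDM", "TDM")

#: Default environment labels; the first is the non-stressed control.
DEFAULT_ENVIRONMENTS: tuple[str, ...] = ("control", "saline", "drought")

ID_COLUMNS: tuple[str, ...] = ("genotype", "environment", "replicate")

#: Traits measured on a percentage scale, bounded above by 100.
PERCENT_TRAITS: frozenset[str] = frozenset({"GERM"})


class PhenotypeError(ValueError):
    """Base class for phenotype-table errors."""


class SchemaError(PhenotypeError):
    """A required column is missing or the file layout is unrecognised."""


class ValidationError(PhenotypeError):
    """Row-level contents violate a table invariant."""


@dataclass(frozen=True)
class PhenotypeTable:
    """Validated replicated trait measurements per genotype x environment.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format table with columns ``genotype``, ``environment``,
        ``replicate`` and one numeric column per trait.  Row order is
        preserved as given.
    trait_names : tuple of str
        Ordered trait labels (columns of ``data``).
    environments : tuple of str
        Ordered environment labels; must include ``control``.
    control : str
        Label of the non-stressed reference environment.
    incomplete : tuple of str
        Genotypes missing at least one environment; they are kept in
        ``data`` but flagged so comparisons can exclude them.
    """

    data: pd.DataFrame
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    environments: tuple[str, ...] = DEFAULT_ENVIRONMENTS
    control: str = "control"
    incomplete: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        _validate(self.data, self.trait_names, self.environments, self.control)
        flagged = _incomplete_genotypes(self.data, self.environments)
        object.__setattr__(self, "incomplete", tuple(flagged))
        if flagged:
            warnings.warn(
                "genotypes missing one or more environments (flagged, "
                f"excluded from comparisons): {', '.join(flagged)}",
                stacklevel=3,
            )

    # ------------------------------------------------------------------
    @property
    def genotypes(self) -> tuple[str, ...]:
        seen = pd.unique(self.data["genotype"])
        return tuple(str(g) for g in seen)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def complete_genotypes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genotypes if g not in self.incomplete)

    def counts(self) -> dict[str, int]:
        """Counts of genotypes, environments and replicates in the table."""
        return {
            "genotypes": self.data["genotype"].nunique(),
            "environments": self.data["environment"].nunique(),
            "replicates": int(
                self.data.groupby(["genotype", "environment"])["replicate"]
                .nunique()
                .max()
            ),
            "records": len(self.data),
        }

    def raw_env_means(self) -> pd.DataFrame:
        """Per-genotype, per-environment trait means on the raw scales."""
        return (
            self.data.groupby(["genotype", "environment"], sort=True)[
                list(self.trait_names)
            ].mean()
        )

    def to_csv(self, path: str | Path) -> None:
        write_table(self.data, path)


def _validate(
    df: pd.DataFrame,
    trait_names: Sequence[str],
    environments: Sequence[str],
    control: str,
) -> None:
    missing = [c for c in (*ID_COLUMNS, *trait_names) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if control not in environments:
        raise ValidationError(
            f"control environment {control!r} not in environments {tuple(environments)}"
        )
    unknown = set(df["environment"].unique()) - set(environments)
    if unknown:
        raise ValidationError(f"unknown environment label(s): {sorted(unknown)}")

    reps = pd.to_numeric(df["replicate"], errors="coerce")
    bad_rep = df.index[reps.isna() | (reps < 1) | (reps != reps.round())]
    if len(bad_rep):
        raise ValidationError(
            f"replicate must be a positive integer; offending rows: {list(bad_rep[:10])}"
        )

    for trait in trait_names:
        values = pd.to_numeric(df[trait], errors="coerce")
        bad = df.index[values.isna() | ~np.isfinite(values) | (values < 0)]
        if len(bad):
            raise ValidationError(
                f"trait {trait!r} must be finite and >= 0; "
                f"offending rows: {list(bad[:10])}"
            )
        if trait in PERCENT_TRAITS:
            over = df.index[values > 100]
            if len(over):
                raise ValidationError(
                    f"trait {trait!r} is a percentage and must be <= 100; "
                    f"offending rows: {list(over[:10])}"
                )

    dup = df.duplicated(subset=list(ID_COLUMNS), keep=False)
    if dup.any():
        rows = list(df.index[dup][:10])
        raise ValidationError(
            f"duplicate (genotype, environment, replicate) triples; rows: {rows}"
        )


def _incomplete_genotypes(
    df: pd.DataFrame, environments: Sequence[str]
) -> list[str]:
    present = df.groupby("genotype")["environment"].agg(lambda s: set(s))
    required = set(environments)
    return sorted(str(g) for g, envs in present.items() if not required <= envs)


def read_phenotypes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_names: Sequence[str] = DEFAULT_TRAITS,
    environments: Sequence[str] = DEFAULT_ENVIRONMENTS,
    control: str = "control",
) -> PhenotypeTable:
    """Read a phenotype CSV and return a validated :class:`PhenotypeTable`.

    Parameters
    ----------
    path : path-like
        CSV file (UTF-8, comma-delimited, ``.`` decimal separator).
    column_map : mapping, optional
        Maps file column names to canonical names (``genotype``,
        ``environment``, ``replicate`` and the trait labels).
    trait_names, environments, control
        Expected trait and environment labels.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If any row violates a table invariant (negative trait, GERM > 100,
        duplicated replicate triple, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "trait" in df.columns and "value" in df.columns and not set(
        trait_names
    ) <= set(df.columns):
        # tidy layout: one row per measurement; pivot to canonical long format
        df = (
            df.pivot_table(
                index=list(ID_COLUMNS), columns="trait", values="value", sort=False
            )
            .reset_index()
        )
        df.columns.name = None
    df["genotype"] = df["genotype"].astype(str)
    df["environment"] = df["environment"].astype(str)
    return PhenotypeTable(
        data=df.reset_index(drop=True),
        trait_names=tuple(trait_names),
        environments=tuple(environments),
        control=control,
    )


def write_table(rows: pd.DataFrame | PhenotypeTable, path: str | Path) -> None:
    """Write a tabular result as CSV with a stable column order.

    Values are written at full precision so that a read-back is
    value-identical.  Refuses to create a file from an empty input.
    """
    if isinstance(rows, PhenotypeTable):
        rows = rows.data
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    if rows.empty:
        raise ValueError("refusing to write an empty table")
    out = rows.reset_index() if rows.index.name or isinstance(
        rows.index, pd.MultiIndex
    ) else rows
    out.to_csv(path, index=False)
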