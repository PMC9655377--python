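"""Synthetic replicated phenotype tables with known stability ordering.

The generator emulates the structure of a multi-environment germination
trial: each genotype has a control mean per trait, and each stress
environment shifts that mean multiplicatively according to a
genotype-specific sensitivity in [0, 1],

    stress_mean = control_mean * (1 - direction * max_effect_fraction * sensitivity)

with ``direction = +1`` when stress decreases the trait (the usual case)
and ``-1`` when it increases it (e.g. root growth stimulated by mild
osmotic stress).  Replicates perturb the mean with multiplicative Gaussian
noise of a given coefficient of variation, truncated at zero (and capped
at 100 for percentage traits).  Because sensitivities are known, the true
stability ordering is known, which makes the whole
distance-plus-TOPSIS pipeline testable for parameter recovery without any
external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotype import (
    DEFAULT_ENVIRONMENTS,
    DEFAULT_TRAITS,
    PERCENT_TRAITS,
    PhenotypeTable,
)

#: Control-mean ranges per trait: plausible values for 14-day soybean
#: germination-roll assays (GERM %, lengths cm, dry matter g).
DEFAULT_BASELINE_RANGES: dict[str, tuple[float, float]] = {
    "GERM": (80.0, 100.0),
    "SL": (8.0, 14.0),
    "RL": (12.0, 20.0),
    "TL": (20.0, 34.0),
    "SDM": (0.10, 0.18),
    "RDM": (0.04, 0.08),
    "TDM": (0.14, 0.26),
}


class ConfigError(ValueError):
    """The synthetic-data configuration violates an invariant."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic multi-environment trial.

    Attributes
    ----------
    n_genotypes, n_replicates : int
        Trial dimensions (defaults 70 genotypes x 4 replicates, matching
        the screening design the defaults emulate).
    trait_baseline_ranges : mapping
        Per-trait ``(low, high)`` for the uniform draw of control means.
    sensitivity_saline, sensitivity_drought : sequence of float or None
        Per-genotype stress sensitivities in [0, 1].  ``None`` draws them
        uniformly on [0, 1] from the seed (deterministically).
    trait_response_direction : mapping
        Per-trait sign: +1 stress decreases the trait (default), -1
        increases it.
    max_effect_fraction : float
        Mean shift of a fully sensitive genotype, as a fraction of the
        control mean (default 0.8).
    replicate_cv : float
        Coefficient of variation of the multiplicative replicate noise
        (default 0.05).
    seed : int
        Single seed from which all randomness flows.
    """

    n_genotypes: int = 70
    n_replicates: int = 4
    trait_baseline_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RANGES)
    )
    sensitivity_saline: Sequence[float] | None = None
    sensitivity_drought: Sequence[float] | None = None
    trait_response_direction: Mapping[str, int] = field(default_factory=dict)
    max_effect_fraction: float = 0.8
    replicate_cv: float = 0.05
    seed: int = 0

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.trait_baseline_ranges)

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.n_replicates < 1:
            raise ConfigError("n_genotypes and n_replicates must be positive")
        if not 0 < self.max_effect_fraction <= 1:
            raise ConfigError(
                f"max_effect_fraction must be in (0, 1], got {self.max_effect_fraction}"
            )
        if self.replicate_cv < 0:
            raise ConfigError(f"replicate_cv must be >= 0, got {self.replicate_cv}")
        for trait, (low, high) in self.trait_baseline_ranges.items():
            if not 0 <= low <= high:
                raise ConfigError(f"invalid baseline range for {trait!r}: {(low, high)}")
        for trait, d in self.trait_response_direction.items():
            if trait not in self.trait_baseline_ranges:
                raise ConfigError(f"direction given for unknown trait {trait!r}")
            if d not in (-1, 1):
                raise ConfigError(f"direction for {trait!r} must be +1 or -1, got {d}")
        for name in ("sensitivity_saline", "sensitivity_drought"):
            s = getattr(self, name)
            if s is None:
                continue
            s = np.asarray(s, dtype=float)
            if s.shape != (self.n_genotypes,):
                raise ConfigError(
                    f"{name} must have length n_genotypes={self.n_genotypes}"
                )
            if np.any(s < 0) or np.any(s > 1):
                raise ConfigError(f"{name} values must lie in [0, 1]")

    def genotype_labels(self) -> tuple[str, ...]:
        width = len(str(self.n_genotypes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genotypes))

    def resolve(self) -> "SyntheticConfig":
        """Return a config with explicit sensitivity vectors.

        Unspecified sensitivities are drawn U(0, 1) from a dedicated
        stream seeded by ``[seed, 1]``, so the resolution is identical
        whether it happens here, in :func:`simulate_phenotypes`, or in
        :func:`ground_truth_ranking`.
        """
        self.validate()
        if self.sensitivity_saline is not None and self.sensitivity_drought is not None:
            return self
        rng = np.random.default_rng([self.seed, 1])
        saline = (
            np.asarray(self.sensitivity_saline, dtype=float)
            if self.sensitivity_saline is not None
            else rng.uniform(0.0, 1.0, self.n_genotypes)
        )
        drought = (
            np.asarray(self.sensitivity_drought, dtype=float)
            if self.sensitivity_drought is not None
            else rng.uniform(0.0, 1.0, self.n_genotypes)
        )
        return replace(
            self,
            sensitivity_saline=tuple(saline),
            sensitivity_drought=tuple(drought),
        )

    def truth_frame(self) -> pd.DataFrame:
        """Genotype, sensitivity_saline, sensitivity_drought — the ground truth."""
        cfg = self.resolve()
        return pd.DataFrame(
            {
                "genotype": cfg.genotype_labels(),
                "sensitivity_saline": np.asarray(cfg.sensitivity_saline, dtype=float),
                "sensitivity_drought": np.asarray(cfg.sensitivity_drought, dtype=float),
            }
        )


def control_means(config: SyntheticConfig) -> pd.DataFrame:
    """Per-genotype control trait means, drawn from the baseline ranges.

    Drawn from a dedicated stream seeded by ``[seed, 0]`` so they are
    reproducible independently of the noise draws.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    traits = config.trait_names
    values = np.column_stack(
        [
            rng.uniform(*config.trait_baseline_ranges[t], config.n_genotypes)
            for t in traits
        ]
    )
    return pd.DataFrame(values, index=config.genotype_labels(), columns=traits)


def expected_env_means(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Noise-free per-environment means implied by the config.

    The closed form behind the generator: an oracle for what replicate
    averages converge to, used to derive expected distances in tests.
    """
    cfg = config.resolve()
    base = control_means(cfg)
    directions = np.array(
        [cfg.trait_response_direction.get(t, 1) for t in cfg.trait_names], dtype=float
    )
    out = {"control": base}
    for env, sens in (
        ("saline", np.asarray(cfg.sensitivity_saline, dtype=float)),
        ("drought", np.asarray(cfg.sensitivity_drought, dtype=float)),
    ):
        factor = 1.0 - directions[None, :] * cfg.max_effect_fraction * sens[:, None]
        out[env] = base * factor
    return out


def simulate_phenotypes(config: SyntheticConfig) -> PhenotypeTable:
    """Generate a replicated three-environment phenotype table.

    Produces ``n_genotypes x 3 environments x n_replicates`` records.
    Identical config and seed yield a byte-identical table.
    """
    cfg = config.resolve()
    means = expected_env_means(cfg)
    noise_rng = np.random.default_rng([cfg.seed, 2])
    traits = cfg.trait_names
    labels = cfg.genotype_labels()

    frames = []
    for env in DEFAULT_ENVIRONMENTS:
        mu = means[env].to_numpy()  # (n_genotypes, n_traits)
        for rep in range(1, cfg.n_replicates + 1):
            noise = noise_rng.standard_normal(mu.shape)
            values = mu * (1.0 + cfg.replicate_cv * noise)
            values = np.maximum(values, 0.0)
            frame = pd.DataFrame(values, columns=traits)
            for t in traits:
                if t in PERCENT_TRAITS:
                    frame[t] = frame[t].clip(upper=100.0)
            frame.insert(0, "replicate", rep)
            frame.insert(0, "environment", env)
            frame.insert(0, "genotype", labels)
            frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return PhenotypeTable(
        data=data,
        trait_names=traits,
        environments=DEFAULT_ENVIRONMENTS,
        control="control",
    )


def ground_truth_ranking(
    config: SyntheticConfig, weights: tuple[float, float] = (0.5, 0.5)
) -> list[str]:
    """Genotypes ordered by ascending weighted combined sensitivity.

    ``w_s * sensitivity_saline + w_d * sensitivity_drought``, most stable
    first; the recovery target for pipeline tests.  Ties break by label.
    """
    w_s, w_d = weights
    if w_s < 0 or w_d < 0:
        raise ConfigError("weights must be non-negative")
    if abs(w_s + w_d - 1.0) > 1e-9:
        raise ConfigError(f"weights must sum to 1, got {w_s + w_d}")
    truth = config.resolve().truth_frame()
    combined = (
        w_s * truth["sensitivity_saline"] + w_d * truth["sensitivity_drought"]
    )
    order = truth.assign(combined=combined).sort_values(
        ["combined", "genotype"], kind="mergesort"
    )
    return list(order["genotype"])
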