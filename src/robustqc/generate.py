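"""Synthetic indicator data with controlled mean, skewness and contamination.

Quality indicators that count rare adverse events are right-skewed; a Gamma
distribution with shape ``alpha`` and scale ``beta`` captures the whole range
from near-normal (large ``alpha``) to heavily skewed (small ``alpha``), with

    mean     mu    = alpha * beta
    skewness gamma = 2 / sqrt(alpha)

This module generates such samples, optionally zero-inflated (a point mass at
zero heavy enough to collapse robust scale estimates, as happens for rare-event
indicators in practice), and plants gross outliers drawn from a normal
distribution far above the bulk, mimicking data-entry errors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .sample import IndicatorSample

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma(shape, scale) parameterisation with its implied mean and skewness."""

    shape_alpha: float
    scale_beta: float
    mean: float
    skewness: float

    def __post_init__(self) -> None:
        if self.shape_alpha <= 0 or self.scale_beta <= 0:
            raise ValueError("Gamma shape and scale must be positive")
        if not np.isclose(self.mean, self.shape_alpha * self.scale_beta):
            raise ValueError("mean must equal shape * scale")
        if not np.isclose(self.skewness, 2.0 / np.sqrt(self.shape_alpha)):
            raise ValueError("skewness must equal 2 / sqrt(shape)")


@dataclass(frozen=True)
class DistributionSpec:
    """A generating distribution: gamma, normal, or zero-inflated gamma.

    Use the :meth:`gamma`, :meth:`normal` and :meth:`zero_inflated_gamma`
    constructors; they enforce that exactly the fields required by ``kind``
    are present.
    """

    kind: str
    gamma_spec: GammaSpec | None = None
    normal_mean: float | None = None
    normal_sd: float | None = None
    zero_probability: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "gamma":
            ok = (
                self.gamma_spec is not None
                and self.normal_mean is None
                and self.normal_sd is None
                and self.zero_probability is None
            )
        elif self.kind == "normal":
            ok = (
                self.gamma_spec is None
                and self.normal_mean is not None
                and self.normal_sd is not None
                and self.normal_sd > 0
                and self.zero_probability is None
            )
        elif self.kind == "zero_inflated_gamma":
            ok = (
                self.gamma_spec is not None
                and self.normal_mean is None
                and self.normal_sd is None
                and self.zero_probability is not None
                and 0.0 <= self.zero_probability < 1.0
            )
        else:
            raise ValueError(f"unknown distribution kind: {self.kind!r}")
        if not ok:
            raise ValueError(f"malformed spec for kind {self.kind!r}")

    @classmethod
    def gamma(cls, spec: GammaSpec) -> "DistributionSpec":
        return cls(kind="gamma", gamma_spec=spec)

    @classmethod
    def normal(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls(kind="normal", normal_mean=mean, normal_sd=sd)

    @classmethod
    def zero_inflated_gamma(
        cls, zero_probability: float, spec: GammaSpec
    ) -> "DistributionSpec":
        return cls(
            kind="zero_inflated_gamma",
            gamma_spec=spec,
            zero_probability=zero_probability,
        )


@dataclass(frozen=True)
class PlantSpec:
    """Gross outliers to plant: ``count_m`` draws from Normal(mean, variance)."""

    count_m: int
    outlier_mean: float = 60.0
    outlier_variance: float = 9.0 / 4.0

    def __post_init__(self) -> None:
        if self.count_m < 0:
            raise ValueError("count_m must be nonnegative")
        if self.outlier_variance <= 0:
            raise ValueError("outlier_variance must be positive")


def gamma_params_from_skewness(
    target_mean: float, target_skewness: float
) -> GammaSpec:
    """Gamma spec with the requested mean and skewness.

    Inverts mu = alpha*beta and gamma = 2/sqrt(alpha):
    alpha = (2/gamma)^2, beta = mu/alpha.

    Raises
    ------
    ValueError
        If ``target_skewness <= 0`` — no Gamma has zero skewness; use a
        normal spec (``DistributionSpec.normal``) for that case.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    if target_skewness <= 0:
        raise ValueError(
            "a Gamma distribution cannot have skewness <= 0; "
            "use DistributionSpec.normal for the symmetric case"
        )
    alpha = (2.0 / target_skewness) ** 2
    beta = target_mean / alpha
    return GammaSpec(
        shape_alpha=alpha,
        scale_beta=beta,
        mean=target_mean,
        skewness=target_skewness,
    )


def simulate_indicator(spec: DistributionSpec, n: int, seed) -> IndicatorSample:
    """Draw ``n`` observations from ``spec``; a pure function of (spec, n, seed)."""
    if n <= 0:
        raise ValueError("n must be a positive integer")
    if not isinstance(spec, DistributionSpec):
        raise ValueError("spec must be a DistributionSpec")
    rng = _rng(seed)
    if spec.kind == "normal":
        values = rng.normal(spec.normal_mean, spec.normal_sd, n)
    elif spec.kind == "gamma":
        g = spec.gamma_spec
        values = rng.gamma(g.shape_alpha, g.scale_beta, n)
    else:  # zero_inflated_gamma
        g = spec.gamma_spec
        zero_mask = rng.random(n) < spec.zero_probability
        values = rng.gamma(g.shape_alpha, g.scale_beta, n)
        values[zero_mask] = 0.0
    return IndicatorSample(values=values)


def plant_outliers(
    clean: IndicatorSample, plant: PlantSpec, seed
) -> IndicatorSample:
    """Insert ``plant.count_m`` gross outliers at random positions.

    The planted values are drawn from Normal(outlier_mean, outlier_variance)
    and interleaved uniformly at random among the clean observations; the
    returned sample carries truth labels marking them. The multiset of
    non-planted values is exactly the input.
    """
    if clean.truth_labels is not None:
        raise ValueError("input sample already carries truth labels")
    m = plant.count_m
    rng = _rng(seed)
    n = len(clean)
    if m == 0:
        return IndicatorSample(
            values=clean.values.copy(),
            unit_ids=None if clean.unit_ids is None else clean.unit_ids.copy(),
            truth_labels=np.zeros(n, dtype=bool),
        )
    planted = rng.normal(plant.outlier_mean, np.sqrt(plant.outlier_variance), m)
    values = np.concatenate([clean.values, planted])
    labels = np.concatenate([np.zeros(n, dtype=bool), np.ones(m, dtype=bool)])
    order = rng.permutation(n + m)
    unit_ids = None
    if clean.unit_ids is not None:
        planted_ids = np.array([f"planted-{i + 1}" for i in range(m)], dtype=object)
        unit_ids = np.concatenate([clean.unit_ids.astype(object), planted_ids])[order]
    return IndicatorSample(
        values=values[order], unit_ids=unit_ids, truth_labels=labels[order]
    )


def write_sample_csv(samples: Mapping[str, IndicatorSample], path) -> None:
    """Write samples as tidy CSV: unit_id, indicator, value, is_planted.

    Units without explicit identifiers get ``u0001``-style ids so the file
    round-trips through the tabular reader.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id", "indicator", "value", "is_planted"])
        for indicator, sample in samples.items():
            ids = sample.unit_ids
            if ids is None:
                ids = [f"u{i + 1:04d}" for i in range(len(sample))]
            labels = sample.truth_labels
            if labels is None:
                labels = np.zeros(len(sample), dtype=bool)
            for uid, value, planted in zip(ids, sample.values, labels):
                writer.writerow([uid, indicator, repr(float(value)), int(planted)])
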