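"""Synthetic inputs with the statistical structure the model assumes.

Two generators:

* :func:`sample_loci` draws multilocus parameter collections — dominance,
  selection, mutation and component-effect values independently distributed
  across loci — for validating the genome-level approximations against the
  exact per-locus sums and the recursion oracle.
* :func:`sample_rmu_table` builds mock tables of published male-to-female
  mutation-rate ratio estimates with the structure real compilations have:
  grouped by lineage, multiple estimates per species, interval bounds, and
  occasional extreme outliers.

Everything is deterministic given the spec's seed; the same spec and seed
produce byte-identical output files.

Defaults mirror empirically supported values: mean dominance 0.25 on
(0, 0.5) (mutation-accumulation meta-analyses place h_bar near 0.25 with a
plausible range of roughly 0.18-0.36; only the moments are constrained by
data, so the scaled-beta family is this package's choice), per-site
mutation rate 1e-6 per locus unit, homozygous selection 0.02, and component
effect 0.3 typical of egg-to-adult viability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .load_model import LociCollection, LocusParams, ModelDomainError

__all__ = [
    "LocusDistributionSpec",
    "RmuGroupSpec",
    "RmuTableSpec",
    "sample_loci",
    "sample_rmu_table",
    "RMU_COLUMNS",
]


@dataclass(frozen=True)
class LocusDistributionSpec:
    """Distributional spec for a multilocus parameter draw.

    Dominance is drawn as ``h = h_max * Beta(a, b)`` with moments set so the
    mean is ``h_mean`` and the spread is controlled by ``h_concentration``
    (larger = tighter; a point mass is obtained with
    ``h_concentration = inf`` or ``h_sd = 0`` semantics via
    ``degenerate=True``). Selection, mutation and component effects default
    to point masses; lognormal selection is available through
    ``s_cv > 0`` (coefficient of variation). The ``beta`` coupling sets
    ``s_m = beta * s_f`` and, when ``enforce_viability_constraint`` is on,
    ``alpha_m = alpha_f / beta`` so that ``alpha_f*s_f = alpha_m*s_m``
    (mutations affect viability equally in the sexes). Disabling the
    constraint gives an independent-sexes mode for sex-limited studies.
    """

    n_loci: int
    h_mean: float = 0.25
    h_max: float = 0.5
    h_concentration: float = 20.0
    degenerate: bool = False
    s_mean: float = 0.02
    s_cv: float = 0.0
    mu_f: float = 1e-6
    mu_m: float = 1e-6
    alpha_f_mean: float = 0.3
    beta: float = 1.0
    enforce_viability_constraint: bool = True
    alpha_m_mean: float | None = None  # used only when the constraint is off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ModelDomainError("n_loci must be >= 1")
        if not (0.0 < self.h_max <= 1.0):
            raise ModelDomainError(f"h_max={self.h_max!r} must be in (0, 1]")
        if not (0.0 < self.h_mean < self.h_max) and not self.degenerate:
            raise ModelDomainError(
                f"h_mean={self.h_mean!r} must lie strictly inside (0, {self.h_max})"
            )
        if self.degenerate and not (0.0 <= self.h_mean <= 1.0):
            raise ModelDomainError("degenerate h_mean outside [0, 1]")
        if self.h_concentration <= 0:
            raise ModelDomainError("h_concentration must be positive")
        if not (0.0 < self.s_mean <= 1.0):
            raise ModelDomainError(f"s_mean={self.s_mean!r} must be in (0, 1]")
        if self.s_cv < 0:
            raise ModelDomainError("s_cv must be >= 0")
        if self.beta <= 0:
            raise ModelDomainError("beta must be positive")
        if not (0.0 <= self.alpha_f_mean <= 1.0):
            raise ModelDomainError("alpha_f_mean outside [0, 1]")


def sample_loci(spec: LocusDistributionSpec) -> LociCollection:
    """Draw a deterministic-given-seed loci collection from the spec.

    The achieved summary statistics (h_bar, var_h, alpha means, U_linked)
    are available from ``LociCollection.summary()``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_loci

    if spec.degenerate:
        h = np.full(n, spec.h_mean)
    else:
        m = spec.h_mean / spec.h_max
        a = spec.h_concentration * m
        b = spec.h_concentration * (1.0 - m)
        h = spec.h_max * rng.beta(a, b, size=n)

    if spec.s_cv > 0:
        sigma2 = np.log1p(spec.s_cv**2)
        mu_log = np.log(spec.s_mean) - sigma2 / 2.0
        s_f = rng.lognormal(mean=mu_log, sigma=np.sqrt(sigma2), size=n)
        s_f = np.clip(s_f, 1e-12, 1.0)
    else:
        s_f = np.full(n, spec.s_mean)

    s_m = np.clip(spec.beta * s_f, 0.0, 1.0)

    alpha_f = np.full(n, spec.alpha_f_mean)
    if spec.enforce_viability_constraint:
        alpha_m = np.clip(alpha_f / spec.beta, 0.0, 1.0)
    else:
        target = (
            spec.alpha_m_mean if spec.alpha_m_mean is not None else spec.alpha_f_mean
        )
        alpha_m = np.full(n, float(target))

    loci = [
        LocusParams(
            mu_f=spec.mu_f,
            mu_m=spec.mu_m,
            s_f=float(s_f[i]),
            s_m=float(s_m[i]),
            h=float(h[i]),
            alpha_f=float(alpha_f[i]),
            alpha_m=float(alpha_m[i]),
            locus_id=f"L{i:06d}",
        )
        for i in range(n)
    ]
    return LociCollection.from_loci(loci)


# ---------------------------------------------------------------------------
# mock Rmu estimate tables

RMU_COLUMNS = [
    "species",
    "lineage_group",
    "estimate",
    "ci_low",
    "ci_high",
    "method",
    "source",
    "species_level",
]


@dataclass(frozen=True)
class RmuGroupSpec:
    """Per-lineage-group generation parameters for mock Rmu estimates.

    Species-level ratios are lognormal about ``mean`` (arithmetic mean is
    matched, not the log-mean) with log-scale spread ``sigma``; each species
    contributes ``estimates_per_species`` noisy replicate estimates, and
    ``outliers`` lists extreme point values each injected as one extra
    single-estimate species.
    """

    n_species: int
    mean: float
    sigma: float = 0.15
    estimates_per_species: int = 1
    replicate_sigma: float = 0.05
    ci_rel_halfwidth: float = 0.2
    outliers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ModelDomainError("n_species must be >= 0")
        if self.mean <= 0:
            raise ModelDomainError("group mean Rmu must be positive")
        if self.sigma < 0 or self.replicate_sigma < 0:
            raise ModelDomainError("sigma values must be >= 0")
        if any(v <= 0 for v in self.outliers):
            raise ModelDomainError("outlier values must be positive")


@dataclass(frozen=True)
class RmuTableSpec:
    """Spec for a mock compilation of sex-biased mutation-rate estimates."""

    groups: Mapping[str, RmuGroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ModelDomainError("at least one group is required")


def sample_rmu_table(spec: RmuTableSpec) -> pd.DataFrame:
    """Generate a mock Rmu estimate table with the standard schema.

    Column order and dtypes are fixed so that identical specs and seeds
    serialize to identical bytes.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in sorted(spec.groups):
        g = spec.groups[group]
        sigma2 = g.sigma**2
        species_means = g.mean * np.exp(
            rng.normal(0.0, g.sigma, size=g.n_species) - sigma2 / 2.0
        )
        for i, m in enumerate(species_means):
            species = f"{group}_sp{i:03d}"
            for j in range(g.estimates_per_species):
                est = float(
                    m
                    * np.exp(
                        rng.normal(0.0, g.replicate_sigma)
                        - g.replicate_sigma**2 / 2.0
                    )
                )
                rows.append(
                    {
                        "species": species,
                        "lineage_group": group,
                        "estimate": est,
                        "ci_low": est * (1.0 - g.ci_rel_halfwidth),
                        "ci_high": est * (1.0 + g.ci_rel_halfwidth),
                        "method": "molecular-evolutionary (synthetic)",
                        "source": f"synthetic:{group}:{i}:{j}",
                        "species_level": True,
                    }
                )
        for j, value in enumerate(g.outliers):
            rows.append(
                {
                    "species": f"{group}_outlier{j}",
                    "lineage_group": group,
                    "estimate": float(value),
                    "ci_low": float(value) * (1.0 - g.ci_rel_halfwidth),
                    "ci_high": float(value) * (1.0 + g.ci_rel_halfwidth),
                    "method": "molecular-evolutionary (synthetic)",
                    "source": f"synthetic:{group}:outlier:{j}",
                    "species_level": True,
                }
            )
    return pd.DataFrame(rows, columns=RMU_COLUMNS)


def write_rmu_table(df: pd.DataFrame, path: str | Path) -> None:
    """Serialize with fixed float formatting for byte-stable output."""
    df.to_csv(path, index=False, float_format="%.10g")
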