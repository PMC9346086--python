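"""Closed-form model of sex-linked mutation load.

Deleterious alleles at X-linked (or Z-linked) loci are held at
mutation-selection balance. Because the heterogametic sex carries a single
copy of the sex chromosome, partially recessive mutations are fully exposed
in that sex, producing a sex difference in mean survival or longevity — the
"unguarded X" effect. This module provides the per-locus equilibrium
frequency, exact genome-wide multiplicative loads, and the family of
closed-form approximations for the homogametic/heterogametic survival
ratio, including variants for sex-differential purifying selection,
sex-limited fitness effects, and absent dosage compensation.

Conventions
-----------
All ratios are *homogametic over heterogametic* (females/males under XY,
males/females under ZW). Three percent renderings of a ratio ``r`` are
exposed because the literature mixes them:

``excess``
    ``100 * (r - 1)`` — percent by which the homogametic sex exceeds the
    heterogametic sex.
``deficit``
    ``100 * (1 - 1/r)`` — percent reduction of the heterogametic sex
    relative to the homogametic sex.
``log_pct``
    ``100 * ln(r)`` — symmetric log-scale percent difference.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusParams",
    "LociCollection",
    "LoadResult",
    "DominanceSummary",
    "ModelDomainError",
    "WeakSelectionWarning",
    "STRONG_SELECTION_FACTOR",
    "percent_conventions",
    "equilibrium_frequency",
    "locus_component_means",
    "genome_loads_exact",
    "ratio_simplified",
    "ratio_baseline",
    "ratio_sexdiff",
    "ratio_sex_limited",
    "ratio_no_dosage_comp",
]


class ModelDomainError(ValueError):
    """Raised when parameters leave the domain where the model is defined."""


class WeakSelectionWarning(UserWarning):
    """Mutation pressure is not small relative to selection; the
    mutation-selection-balance approximation may be inaccurate."""


#: The equilibrium-frequency formula assumes mutation pressure is small
#: relative to selection (2*mu_f + mu_m << 2*h*s_f + s_m). We warn when the
#: ratio of the two exceeds this factor; the deterministic recursion in
#: :mod:`unguardedx.oracle` quantifies the approximation error outside it.
STRONG_SELECTION_FACTOR = 0.01


def _check_unit_interval(name: str, value: float, *, upper: float = 1.0) -> None:
    if not (0.0 <= value <= upper):
        raise ModelDomainError(f"{name}={value!r} outside [0, {upper}]")


@dataclass(frozen=True)
class LocusParams:
    """Per-locus mutation, selection, dominance and component-effect
    parameters for one X-linked (or Z-linked) biallelic locus.

    Parameters
    ----------
    mu_f, mu_m
        Per-generation deleterious mutation probabilities in eggs and sperm.
    s_f
        Selection coefficient against mutant homozygotes in the
        homogametic sex.
    s_m
        Selection coefficient against mutant hemizygotes in the
        heterogametic sex.
    h
        Dominance coefficient of the mutation in heterozygotes
        (``h < 0.5`` means partially recessive).
    alpha_f, alpha_m
        Fraction of each sex's fitness effect that acts through the focal
        fitness component (survival or longevity); 1 means pure viability
        selection, 0 pure fecundity selection.
    """

    mu_f: float
    mu_m: float
    s_f: float
    s_m: float
    h: float
    alpha_f: float = 1.0
    alpha_m: float = 1.0
    locus_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("mu_f", "mu_m"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ModelDomainError(f"{name}={v!r} outside [0, 1)")
        for name in ("s_f", "s_m", "h", "alpha_f", "alpha_m"):
            _check_unit_interval(name, getattr(self, name))

    @property
    def mutation_pressure(self) -> float:
        """Total mutational input per X copy triplet, ``2*mu_f + mu_m``."""
        return 2.0 * self.mu_f + self.mu_m

    @property
    def selection_denominator(self) -> float:
        """Effective strength of purifying selection, ``2*h*s_f + s_m``."""
        return 2.0 * self.h * self.s_f + self.s_m

    @property
    def strong_selection_ok(self) -> bool:
        """Whether mutation pressure is negligible relative to selection."""
        denom = self.selection_denominator
        return denom > 0 and self.mutation_pressure <= STRONG_SELECTION_FACTOR * denom

    def _label(self) -> str:
        return self.locus_id if self.locus_id is not None else repr(self)


_CSV_COLUMNS = ["locus_id", "mu_f", "mu_m", "s_f", "s_m", "h", "alpha_f", "alpha_m"]


@dataclass(frozen=True)
class LociCollection:
    """Ordered collection of loci; ``n_X`` is the number of sex-linked loci."""

    loci: tuple[LocusParams, ...]

    def __post_init__(self) -> None:
        if len(self.loci) == 0:
            raise ModelDomainError("a loci collection must contain at least one locus")

    @property
    def n_X(self) -> int:
        return len(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[LocusParams]:
        return iter(self.loci)

    @classmethod
    def from_loci(cls, loci: Iterable[LocusParams]) -> "LociCollection":
        return cls(tuple(loci))

    def arrays(self) -> dict[str, np.ndarray]:
        """Columnar view of the per-locus parameters (float64 arrays)."""
        out: dict[str, np.ndarray] = {}
        for name in ("mu_f", "mu_m", "s_f", "s_m", "h", "alpha_f", "alpha_m"):
            out[name] = np.array([getattr(l, name) for l in self.loci], dtype=float)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, locus in enumerate(self.loci):
            rows.append(
                {
                    "locus_id": locus.locus_id or f"L{i:06d}",
                    "mu_f": locus.mu_f,
                    "mu_m": locus.mu_m,
                    "s_f": locus.s_f,
                    "s_m": locus.s_m,
                    "h": locus.h,
                    "alpha_f": locus.alpha_f,
                    "alpha_m": locus.alpha_m,
                }
            )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LociCollection":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ModelDomainError(f"loci table missing columns: {missing}")
        loci = [
            LocusParams(
                mu_f=float(r.mu_f),
                mu_m=float(r.mu_m),
                s_f=float(r.s_f),
                s_m=float(r.s_m),
                h=float(r.h),
                alpha_f=float(r.alpha_f),
                alpha_m=float(r.alpha_m),
                locus_id=str(r.locus_id),
            )
            for r in df.itertuples()
        ]
        return cls.from_loci(loci)

    def summary(self) -> dict[str, float]:
        """Achieved genome-level summaries (h_bar, var_h, alpha means, U)."""
        a = self.arrays()
        return {
            "n_X": float(self.n_X),
            "h_bar": float(a["h"].mean()),
            "var_h": float(a["h"].var()),
            "alpha_f_bar": float(a["alpha_f"].mean()),
            "alpha_m_bar": float(a["alpha_m"].mean()),
            "U_linked": float((2.0 * a["mu_f"] + a["mu_m"]).sum() / 3.0),
        }


def percent_conventions(ratio: float) -> dict[str, float]:
    """The three named percent renderings of a survival ratio."""
    if ratio <= 0:
        raise ModelDomainError(f"ratio must be positive, got {ratio!r}")
    return {
        "excess": 100.0 * (ratio - 1.0),
        "deficit": 100.0 * (1.0 - 1.0 / ratio),
        "log_pct": 100.0 * math.log(ratio),
    }


@dataclass(frozen=True)
class LoadResult:
    """Mean fitness-component values of each sex and their ratio.

    ``w_hom`` is the homogametic sex's mean survival/longevity factor
    (females under XY, males under ZW); ``w_het`` the heterogametic sex's.
    """

    w_hom: float
    w_het: float
    system: str = "XY"
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.w_hom <= 1.0) or not (0.0 < self.w_het <= 1.0):
            raise ModelDomainError(
                f"mean survival factors must be in (0, 1]; got "
                f"w_hom={self.w_hom!r}, w_het={self.w_het!r}"
            )

    @property
    def ratio(self) -> float:
        return self.w_hom / self.w_het

    @property
    def pct(self) -> dict[str, float]:
        return percent_conventions(self.ratio)

    def to_dict(self) -> dict:
        pct = self.pct
        return {
            "system": self.system,
            "w_hom": self.w_hom,
            "w_het": self.w_het,
            "ratio": self.ratio,
            "pct_excess": pct["excess"],
            "pct_deficit": pct["deficit"],
            "pct_log": pct["log_pct"],
            "conventions": {
                "pct_excess": "100*(ratio-1)",
                "pct_deficit": "100*(1-1/ratio)",
                "pct_log": "100*ln(ratio)",
            },
            "notes": dict(self.notes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class DominanceSummary:
    """Mean and variance of dominance coefficients across loci."""

    h_bar: float
    var_h: float = 0.0

    def __post_init__(self) -> None:
        _check_unit_interval("h_bar", self.h_bar)
        if self.var_h < 0:
            raise ModelDomainError(f"var_h={self.var_h!r} must be >= 0")
        bound = self.h_bar * (1.0 - self.h_bar)
        if self.var_h > bound + 1e-12:
            raise ModelDomainError(
                f"var_h={self.var_h!r} exceeds the maximum {bound!r} possible "
                f"for a distribution on [0, 1] with mean {self.h_bar!r}"
            )


# ---------------------------------------------------------------------------
# per-locus quantities


def equilibrium_frequency(locus: LocusParams) -> float:
    """Deterministic mutation-selection-balance frequency of the deleterious
    allele at one sex-linked locus.

    Returns ``(2*mu_f + mu_m) / (2*h*s_f + s_m)``, valid when selection is
    strong relative to mutation. A :class:`WeakSelectionWarning` is emitted
    when the strong-selection guard fails; a locus neutral in both sexes
    (zero denominator) is an error because no balance exists.
    """
    denom = locus.selection_denominator
    if denom <= 0.0:
        raise ModelDomainError(
            f"locus {locus._label()}: selection denominator 2*h*s_f + s_m is "
            "zero — the allele is effectively neutral and has no "
            "mutation-selection equilibrium"
        )
    if not locus.strong_selection_ok:
        warnings.warn(
            f"locus {locus._label()}: mutation pressure {locus.mutation_pressure:g} "
            f"is not small relative to selection {denom:g}; the equilibrium "
            "frequency approximation may be inaccurate",
            WeakSelectionWarning,
            stacklevel=2,
        )
    return locus.mutation_pressure / denom


def locus_component_means(locus: LocusParams, freq: float) -> tuple[float, float]:
    """Contribution of one locus to mean survival of each sex.

    ``w_f = 1 - 2*h*s_f*alpha_f*freq`` (heterozygous females dominate at low
    frequency) and ``w_m = 1 - s_m*alpha_m*freq`` (hemizygous males fully
    express the allele). Factors that are not strictly positive indicate the
    linear approximation has broken down and raise an error.
    """
    if not (0.0 <= freq <= 1.0):
        raise ModelDomainError(f"freq={freq!r} outside [0, 1]")
    w_f = 1.0 - 2.0 * locus.h * locus.s_f * locus.alpha_f * freq
    w_m = 1.0 - locus.s_m * locus.alpha_m * freq
    if w_f <= 0.0 or w_m <= 0.0:
        raise ModelDomainError(
            f"locus {locus._label()}: mean survival factor is non-positive "
            f"(w_f={w_f:g}, w_m={w_m:g}); the linearized per-locus model is "
            "invalid for these parameters"
        )
    return w_f, w_m


# ---------------------------------------------------------------------------
# genome-wide loads


def genome_loads_exact(loci: LociCollection) -> LoadResult:
    """Exact multiplicative genome-wide loads from per-locus equilibria.

    Assuming multiplicative fitness-component effects across loci, the mean
    component value of each sex is ``exp(-sum_i effect_i * p_hat_i)`` where
    ``p_hat_i`` is the per-locus equilibrium frequency. Sums are accumulated
    in log space so that 1e4-1e6 tiny per-locus terms do not lose precision.
    """
    a = loci.arrays()
    denom = 2.0 * a["h"] * a["s_f"] + a["s_m"]
    if np.any(denom <= 0.0):
        bad = int(np.argmax(denom <= 0.0))
        raise ModelDomainError(
            f"locus index {bad}: zero selection denominator (neutral locus)"
        )
    pressure = 2.0 * a["mu_f"] + a["mu_m"]
    if np.any(pressure > STRONG_SELECTION_FACTOR * denom):
        n_bad = int(np.sum(pressure > STRONG_SELECTION_FACTOR * denom))
        warnings.warn(
            f"{n_bad} loci violate the strong-selection guard; genome loads "
            "may be inaccurate there",
            WeakSelectionWarning,
            stacklevel=2,
        )
    p_hat = pressure / denom
    log_w_hom = -float(np.sum(2.0 * a["h"] * a["s_f"] * a["alpha_f"] * p_hat))
    log_w_het = -float(np.sum(a["s_m"] * a["alpha_m"] * p_hat))
    return LoadResult(w_hom=math.exp(log_w_hom), w_het=math.exp(log_w_het))


def _check_ratio_domain(U: float, h_bar: float, alpha_bar: float) -> None:
    if U < 0:
        raise ModelDomainError(f"U={U!r} must be >= 0")
    _check_unit_interval("alpha_bar", alpha_bar)
    _check_unit_interval("h_bar", h_bar)
    if h_bar > 0.5:
        warnings.warn(
            f"h_bar={h_bar:g} > 0.5: mutations are on average dominant, which "
            "is outside the empirically supported regime; the predicted ratio "
            "will be <= 1",
            UserWarning,
            stacklevel=3,
        )


def ratio_simplified(U_X: float, h_bar: float, alpha_bar: float) -> float:
    """Baseline survival ratio with partially recessive mutations.

    ``exp(3*U_X*alpha_bar*(1-2*h_bar)/(1+2*h_bar))`` — the variance-in-h
    term is neglected, appropriate when 0 < h < 0.5 across loci. At
    ``h_bar = 0, alpha_bar = 1`` this reaches the upper limit ``exp(3*U_X)``.
    """
    _check_ratio_domain(U_X, h_bar, alpha_bar)
    # fraction computed first so the variant formulas reduce to this one
    # bitwise exactly at their degenerate parameter values
    frac = (1.0 - 2.0 * h_bar) / (1.0 + 2.0 * h_bar)
    return math.exp(3.0 * U_X * alpha_bar * frac)


def ratio_baseline(U_X: float, dom: DominanceSummary, alpha_bar: float) -> float:
    """Second-order survival ratio retaining the variance of dominance.

    ``exp(3*U_X*alpha_bar*[(1-2*h_bar)/(1+2*h_bar) + 8*var_h/(1+2*h_bar)^3])``,
    from a Taylor expansion of the exact per-locus sum to second order in
    ``h_i - h_bar``. Reduces to :func:`ratio_simplified` at ``var_h = 0``.
    """
    _check_ratio_domain(U_X, dom.h_bar, alpha_bar)
    one_plus = 1.0 + 2.0 * dom.h_bar
    bracket = (1.0 - 2.0 * dom.h_bar) / one_plus + 8.0 * dom.var_h / one_plus**3
    return math.exp(3.0 * U_X * alpha_bar * bracket)


def _frac_sexdiff(h_bar: float, beta: float) -> float:
    return (1.0 - 2.0 * h_bar) / (beta + 2.0 * h_bar)


def ratio_sexdiff(
    U_sexlinked: float,
    h_bar: float,
    alpha_hom: float,
    beta_het_over_hom: float,
) -> float:
    """Survival ratio under sex-differential purifying selection.

    Mutations affect viability equally in the two sexes
    (``alpha_het * s_het = alpha_hom * s_hom``) but total-fitness selection
    is ``beta_het_over_hom``-fold stronger in the heterogametic sex. Returns
    ``exp(3*U*alpha_hom*(1-2*h_bar)/(beta + 2*h_bar))``. Under XY, beta is
    s_m/s_f and alpha_hom is the female component effect; under ZW the sex
    labels reverse, so beta is s_f/s_m and alpha_hom is the male component
    effect. ``beta = 1`` recovers :func:`ratio_simplified`.
    """
    if beta_het_over_hom <= 0:
        raise ModelDomainError(
            f"beta_het_over_hom={beta_het_over_hom!r} must be positive"
        )
    _check_ratio_domain(U_sexlinked, h_bar, alpha_hom)
    return math.exp(
        3.0 * U_sexlinked * alpha_hom * _frac_sexdiff(h_bar, beta_het_over_hom)
    )


def ratio_sex_limited(
    U_X: float, alpha_f_bar: float, alpha_m_bar: float
) -> LoadResult:
    """Survival loads when half the loci have strictly female-limited and
    half strictly male-limited fitness effects.

    Dominance drops out entirely: ``W_f = exp(-1.5*U_X*alpha_f_bar)``,
    ``W_m = exp(-1.5*U_X*alpha_m_bar)``, so the ratio is
    ``exp(1.5*U_X*(alpha_m_bar - alpha_f_bar))`` — equal component effects
    abolish the unguarded X, and ``alpha_m_bar < alpha_f_bar`` reverses it.
    """
    if U_X < 0:
        raise ModelDomainError(f"U_X={U_X!r} must be >= 0")
    _check_unit_interval("alpha_f_bar", alpha_f_bar)
    _check_unit_interval("alpha_m_bar", alpha_m_bar)
    w_f = math.exp(-1.5 * U_X * alpha_f_bar)
    w_m = math.exp(-1.5 * U_X * alpha_m_bar)
    return LoadResult(
        w_hom=w_f,
        w_het=w_m,
        notes={"model": "sex-limited fitness effects (half female-, half male-limited loci)"},
    )


def ratio_no_dosage_comp(
    U_X: float, h_bar: float, alpha_bar: float, k: float
) -> float:
    """Survival ratio when absent dosage compensation scales hemizygous
    effects by ``k`` in (0, 1].

    Hemizygous selection and survival effects become ``k*s`` and
    ``k*s*alpha`` while homozygous female effects are unchanged, giving
    ``exp(3*U_X*alpha_bar*(k-2*h_bar)/(k+2*h_bar))``. The effect is dampened
    for every ``k < 1`` unless mutations are fully recessive (``h_bar = 0``),
    and reverses sign when ``h_bar > k/2``.
    """
    if not (0.0 < k <= 1.0):
        raise ModelDomainError(f"k={k!r} must be in (0, 1]")
    _check_ratio_domain(U_X, h_bar, alpha_bar)
    frac = (k - 2.0 * h_bar) / (k + 2.0 * h_bar)
    return math.exp(3.0 * U_X * alpha_bar * frac)


# ---------------------------------------------------------------------------
# component loads for scenario reporting


def component_loads_sexdiff(
    U: float, h_bar: float, alpha_hom: float, beta_het_over_hom: float
) -> tuple[float, float]:
    """Per-sex mean component values under the sex-differential model.

    ``w_hom = exp(-6*U*alpha_hom*h_bar/(beta+2*h_bar))``,
    ``w_het = exp(-3*U*alpha_hom/(beta+2*h_bar))``; their ratio equals
    :func:`ratio_sexdiff`.
    """
    if beta_het_over_hom <= 0:
        raise ModelDomainError("beta_het_over_hom must be positive")
    denom = beta_het_over_hom + 2.0 * h_bar
    w_hom = math.exp(-6.0 * U * alpha_hom * h_bar / denom)
    w_het = math.exp(-3.0 * U * alpha_hom / denom)
    return w_hom, w_het


def component_loads_baseline(
    U: float, dom: DominanceSummary, alpha_bar: float
) -> tuple[float, float]:
    """Per-sex mean component values to second order in ``h - h_bar``.

    The heterogametic load expands ``E[1/(1+2h)]`` and the homogametic load
    ``E[2h/(1+2h)]`` about ``h_bar``; the ratio equals :func:`ratio_baseline`.
    """
    one_plus = 1.0 + 2.0 * dom.h_bar
    e_het = 1.0 / one_plus + 4.0 * dom.var_h / one_plus**3
    e_hom = 2.0 * dom.h_bar / one_plus - 4.0 * dom.var_h / one_plus**3
    w_hom = math.exp(-3.0 * U * alpha_bar * e_hom)
    w_het = math.exp(-3.0 * U * alpha_bar * e_het)
    return w_hom, w_het


def component_loads_no_dosage_comp(
    U: float, h_bar: float, alpha_bar: float, k: float
) -> tuple[float, float]:
    """Per-sex component values with hemizygous effects scaled by ``k``."""
    if not (0.0 < k <= 1.0):
        raise ModelDomainError(f"k={k!r} must be in (0, 1]")
    denom = k + 2.0 * h_bar
    w_hom = math.exp(-6.0 * U * alpha_bar * h_bar / denom)
    w_het = math.exp(-3.0 * U * alpha_bar * k / denom)
    return w_hom, w_het
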