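"""Exact deterministic recursion for an X-linked locus under two-sex
viability selection and recurrent mutation.

This is the brute-force check on the closed-form equilibrium frequency and
on the genome-level load approximations. One generation is:

1. zygote formation — females from random egg x sperm union, males from
   eggs (the X of a male comes from his mother);
2. viability selection — female genotype fitnesses 1, 1 - h*s_f, 1 - s_f;
   male hemizygote fitnesses 1, 1 - s_m;
3. gametogenesis — surviving females make eggs, surviving males sperm;
4. one-way mutation A -> a at rate mu_f in eggs, mu_m in sperm.

The census is at zygotes, selection precedes gametogenesis, and there is
no back-mutation — the standard conventions under which the closed-form
``(2*mu_f + mu_m) / (2*h*s_f + s_m)`` equilibrium is derived. The pooled
X frequency weights females' two copies: ``p_X = (2*p_egg + p_sperm)/3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .load_model import (
    LociCollection,
    LocusParams,
    ModelDomainError,
    equilibrium_frequency,
    genome_loads_exact,
    ratio_baseline,
    ratio_simplified,
    DominanceSummary,
)

__all__ = [
    "EquilibriumState",
    "recursion_step",
    "solve_equilibrium",
    "solve_equilibria",
    "validate_genome",
    "GenomeValidationReport",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]

DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 1_000_000


@dataclass(frozen=True)
class EquilibriumState:
    """Allele-frequency state of the recursion.

    ``p_egg`` and ``p_sperm`` are deleterious-allele frequencies among the
    gametes that will form the next generation; ``p_X`` pools them over X
    copies (females carry two).
    """

    p_egg: float
    p_sperm: float
    n_iter: int = 0
    converged: bool = False
    delta: float = math.inf

    def __post_init__(self) -> None:
        for name, v in (("p_egg", self.p_egg), ("p_sperm", self.p_sperm)):
            if not (0.0 <= v <= 1.0):
                raise ModelDomainError(f"{name}={v!r} outside [0, 1]")

    @property
    def p_X(self) -> float:
        return (2.0 * self.p_egg + self.p_sperm) / 3.0


def recursion_step(state: EquilibriumState, locus: LocusParams) -> EquilibriumState:
    """Advance the exact two-sex recursion by one generation."""
    pe, ps = state.p_egg, state.p_sperm
    # female zygotes from random egg x sperm union, then viability selection
    f_aa = pe * ps * (1.0 - locus.s_f)
    f_het = (pe * (1.0 - ps) + ps * (1.0 - pe)) * (1.0 - locus.h * locus.s_f)
    f_AA = (1.0 - pe) * (1.0 - ps)
    w_f = f_aa + f_het + f_AA
    if w_f <= 0.0:
        raise ModelDomainError(
            f"locus {locus._label()}: mean female fitness is zero; the "
            "recursion is undefined"
        )
    p_f = (f_aa + 0.5 * f_het) / w_f
    # male zygotes carry their mother's egg X; hemizygous selection
    p_m = pe * (1.0 - locus.s_m) / (1.0 - pe * locus.s_m)
    # one-way mutation in gametes
    pe_next = p_f + (1.0 - p_f) * locus.mu_f
    ps_next = p_m + (1.0 - p_m) * locus.mu_m
    delta = max(abs(pe_next - pe), abs(ps_next - ps))
    return EquilibriumState(
        p_egg=pe_next,
        p_sperm=ps_next,
        n_iter=state.n_iter + 1,
        converged=False,
        delta=delta,
    )


def solve_equilibrium(
    locus: LocusParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    warm_start: bool = True,
) -> EquilibriumState:
    """Iterate the recursion to its mutation-selection fixed point.

    By default the iteration starts at the closed-form approximation (warm
    start); a cold start from zero frequency is available for independence
    checks. Non-convergence is flagged on the returned state rather than
    raised, so callers can inspect the partial result.
    """
    if tol <= 0:
        raise ModelDomainError(f"tol={tol!r} must be positive")
    if warm_start and locus.selection_denominator > 0:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p0 = min(equilibrium_frequency(locus), 1.0)
    else:
        p0 = 0.0
    state = EquilibriumState(p_egg=p0, p_sperm=p0)
    for _ in range(max_iter):
        state = recursion_step(state, locus)
        if state.delta < tol:
            return replace(state, converged=True)
    return state


def solve_equilibria(
    loci: LociCollection,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized warm-started equilibria for a whole loci collection.

    Returns ``(p_egg, p_sperm, converged)`` arrays. Identical dynamics to
    :func:`recursion_step`, advanced for all loci simultaneously until every
    locus has per-generation change below ``tol``.
    """
    a = loci.arrays()
    mu_f, mu_m = a["mu_f"], a["mu_m"]
    s_f, s_m, h = a["s_f"], a["s_m"], a["h"]
    denom = 2.0 * h * s_f + s_m
    if np.any(denom <= 0.0):
        raise ModelDomainError("all loci must be under selection in at least one sex")
    p0 = np.minimum((2.0 * mu_f + mu_m) / denom, 1.0)
    pe = p0.copy()
    ps = p0.copy()
    active = np.ones(len(pe), dtype=bool)
    converged = np.zeros(len(pe), dtype=bool)
    for _ in range(max_iter):
        f_aa = pe * ps * (1.0 - s_f)
        f_het = (pe * (1.0 - ps) + ps * (1.0 - pe)) * (1.0 - h * s_f)
        f_AA = (1.0 - pe) * (1.0 - ps)
        w_f = f_aa + f_het + f_AA
        p_f = (f_aa + 0.5 * f_het) / w_f
        p_m = pe * (1.0 - s_m) / (1.0 - pe * s_m)
        pe_next = p_f + (1.0 - p_f) * mu_f
        ps_next = p_m + (1.0 - p_m) * mu_m
        delta = np.maximum(np.abs(pe_next - pe), np.abs(ps_next - ps))
        pe, ps = pe_next, ps_next
        newly = delta < tol
        converged |= newly
        active = ~converged
        if not active.any():
            break
    return pe, ps, converged


@dataclass(frozen=True)
class GenomeValidationReport:
    """Comparison of recursion-based loads against the closed forms."""

    ratio_oracle: float
    ratio_exact_sum: float
    ratio_taylor: float
    ratio_meanfield: float
    max_rel_log_error_exact: float
    max_rel_log_error_taylor: float
    n_loci: int
    n_unconverged: int

    @property
    def all_converged(self) -> bool:
        return self.n_unconverged == 0

    def to_dict(self) -> dict:
        return {
            "ratio_oracle": self.ratio_oracle,
            "ratio_exact_sum": self.ratio_exact_sum,
            "ratio_taylor": self.ratio_taylor,
            "ratio_meanfield": self.ratio_meanfield,
            "rel_log_error_exact_sum": self.max_rel_log_error_exact,
            "rel_log_error_taylor": self.max_rel_log_error_taylor,
            "n_loci": self.n_loci,
            "n_unconverged": self.n_unconverged,
        }


def validate_genome(
    loci: LociCollection,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> GenomeValidationReport:
    """Compare genome-wide loads computed from recursion equilibria against
    the closed-form exact sum, the second-order Taylor ratio, and the
    mean-parameter simplification.

    Oracle loads use the pooled equilibrium frequency of each locus:
    ``W_hom = exp(sum log(1 - 2*h*s_f*alpha_f*p))`` and
    ``W_het = exp(sum log(1 - s_m*alpha_m*p))``. Relative errors are on
    log-ratios.
    """
    a = loci.arrays()
    pe, ps, converged = solve_equilibria(loci, tol=tol, max_iter=max_iter)
    p_X = (2.0 * pe + ps) / 3.0
    arg_hom = 1.0 - 2.0 * a["h"] * a["s_f"] * a["alpha_f"] * p_X
    arg_het = 1.0 - a["s_m"] * a["alpha_m"] * p_X
    if np.any(arg_hom <= 0.0) or np.any(arg_het <= 0.0):
        raise ModelDomainError("oracle survival factor non-positive at some locus")
    log_hom = float(np.sum(np.log(arg_hom)))
    log_het = float(np.sum(np.log(arg_het)))
    log_ratio_oracle = log_hom - log_het

    exact = genome_loads_exact(loci)
    log_ratio_exact = math.log(exact.ratio)

    summ = loci.summary()
    log_ratio_taylor = math.log(
        ratio_baseline(
            summ["U_linked"],
            DominanceSummary(summ["h_bar"], summ["var_h"]),
            summ["alpha_f_bar"],
        )
    )
    log_ratio_mean = math.log(
        ratio_simplified(summ["U_linked"], summ["h_bar"], summ["alpha_f_bar"])
    )

    def rel_err(x: float) -> float:
        if log_ratio_oracle == 0.0:
            return abs(x)
        return abs(x - log_ratio_oracle) / abs(log_ratio_oracle)

    return GenomeValidationReport(
        ratio_oracle=math.exp(log_ratio_oracle),
        ratio_exact_sum=exact.ratio,
        ratio_taylor=math.exp(log_ratio_taylor),
        ratio_meanfield=math.exp(log_ratio_mean),
        max_rel_log_error_exact=rel_err(log_ratio_exact),
        max_rel_log_error_taylor=rel_err(log_ratio_taylor),
        n_loci=loci.n_X,
        n_unconverged=int(np.sum(~converged)),
    )
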