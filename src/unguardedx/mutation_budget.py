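"""Sex-chromosome deleterious mutation budgets.

The per-chromosome deleterious mutation rate of the X or Z follows from
three quantities: the haploid genomic deleterious rate ``U_H`` (defined at
the autosomal average, where the sexes' mutation rates receive equal
weight), the fraction of the haploid genome that is sex-linked
(``P_X`` or ``P_Z``), and the male-to-female per-site mutation-rate ratio
``R_mu``. An X spends two thirds of its time in females, a Z two thirds in
males, so male-biased mutation (``R_mu > 1``) dampens X-linked rates and
inflates Z-linked ones, with limits ``(2/3)*U_H*P_X`` and ``(4/3)*U_H*P_Z``
as ``R_mu`` grows without bound.

Haplodiploid taxa are handled as an X system with ``P_X = 1``: males are
haploid genome-wide, so the entire haploid genome behaves like one large X.
"""

from __future__ import annotations

from dataclasses import dataclass

from .load_model import ModelDomainError

__all__ = ["MutationBudget", "ux_rate", "uz_rate", "linked_rate", "SYSTEMS"]

SYSTEMS = ("XY", "ZW", "haplodiploid")


def _check(U_H: float, P_linked: float, R_mu: float) -> None:
    if U_H < 0:
        raise ModelDomainError(f"U_H={U_H!r} must be >= 0")
    if not (0.0 < P_linked <= 1.0):
        raise ModelDomainError(f"P_linked={P_linked!r} must be in (0, 1]")
    if R_mu <= 0:
        raise ModelDomainError(f"R_mu={R_mu!r} must be positive")


def ux_rate(U_H: float, P_X: float, R_mu: float = 1.0) -> float:
    """X-linked deleterious mutation rate per generation.

    ``U_X = [2*(2 + R_mu) / (3*(1 + R_mu))] * U_H * P_X``. Equals
    ``U_H * P_X`` at ``R_mu = 1`` and decreases monotonically toward
    ``(2/3)*U_H*P_X`` as male bias grows.
    """
    _check(U_H, P_X, R_mu)
    return 2.0 * (2.0 + R_mu) / (3.0 * (1.0 + R_mu)) * U_H * P_X


def uz_rate(U_H: float, P_Z: float, R_mu: float = 1.0) -> float:
    """Z-linked deleterious mutation rate per generation.

    ``U_Z = [2*(1 + 2*R_mu) / (3*(1 + R_mu))] * U_H * P_Z``. Equals
    ``U_H * P_Z`` at ``R_mu = 1`` and increases monotonically toward
    ``(4/3)*U_H*P_Z`` as male bias grows.
    """
    _check(U_H, P_Z, R_mu)
    return 2.0 * (1.0 + 2.0 * R_mu) / (3.0 * (1.0 + R_mu)) * U_H * P_Z


def linked_rate(U_H: float, P_linked: float, R_mu: float, system: str) -> float:
    """Dispatch to the X or Z budget by sex-chromosome system."""
    if system not in SYSTEMS:
        raise ModelDomainError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    if system == "ZW":
        return uz_rate(U_H, P_linked, R_mu)
    return ux_rate(U_H, P_linked, R_mu)


@dataclass(frozen=True)
class MutationBudget:
    """A computed sex-linked mutation budget with its inputs."""

    U_H: float
    P_linked: float
    R_mu: float
    system: str
    U_linked: float

    @classmethod
    def compute(
        cls, U_H: float, P_linked: float, R_mu: float = 1.0, system: str = "XY"
    ) -> "MutationBudget":
        return cls(
            U_H=U_H,
            P_linked=P_linked,
            R_mu=R_mu,
            system=system,
            U_linked=linked_rate(U_H, P_linked, R_mu, system),
        )
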