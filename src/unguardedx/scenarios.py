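"""Named taxon parameterizations and parameter sweeps.

A :class:`GenomeScenario` bundles the genome-level parameters that set the
size of the unguarded-X effect for a taxon: haploid genomic deleterious
rate, sex-linked genome fraction, sex bias in mutation, mean dominance,
component effect, and sex bias in purifying selection. :func:`predict`
chains the mutation budget through the load model and returns the
homogametic/heterogametic survival ratio with all percent conventions;
:func:`sweep` evaluates a grid of scenarios for dose-response curves over
mean dominance and component effect.

Builtin scenarios use published point estimates: a Drosophila-like genome
(U_H = 0.5, P_X = 0.2, R_mu = 1), a mammal-like genome taking humans as
representative (U_H = 1.1, P_X = 0.05), a bird-like ZW genome at the upper
end of Z sizes (U_H = 1.1, P_Z = 0.1) with and without male-biased mutation
(R_mu = 4) and stronger male selection (beta = 1.5), and a haplodiploid
genome where the entire haploid complement is hemizygous in males.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .load_model import (
    DominanceSummary,
    LoadResult,
    ModelDomainError,
    component_loads_baseline,
    component_loads_no_dosage_comp,
    component_loads_sexdiff,
)
from .mutation_budget import SYSTEMS, linked_rate

__all__ = [
    "GenomeScenario",
    "SweepGrid",
    "BUILTIN_SCENARIOS",
    "get_scenario",
    "predict",
    "sweep",
    "scenario_from_config",
]


@dataclass(frozen=True)
class GenomeScenario:
    """Genome-level parameterization of the unguarded-X model.

    ``beta`` is always expressed as the male/female selection-coefficient
    ratio (s_m/s_f) regardless of system; the ZW label reversal and the
    corresponding beta inversion are handled inside :func:`predict`.
    ``dosage_k`` scales hemizygous effects for taxa without dosage
    compensation and is only meaningful at ``beta = 1``.
    """

    name: str
    system: str  # XY | ZW | haplodiploid
    U_H: float
    P_linked: float
    R_mu: float = 1.0
    h_bar: float = 0.25
    var_h: float = 0.0
    alpha_hom: float = 0.3
    beta: float = 1.0
    dosage_k: float = 1.0

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ModelDomainError(
                f"unknown system {self.system!r}; expected one of {SYSTEMS}"
            )
        if self.beta <= 0:
            raise ModelDomainError(f"beta={self.beta!r} must be positive")
        if not (0.0 < self.dosage_k <= 1.0):
            raise ModelDomainError(f"dosage_k={self.dosage_k!r} must be in (0, 1]")
        # remaining field domains are validated by the downstream model calls

    @property
    def U_linked(self) -> float:
        return linked_rate(self.U_H, self.P_linked, self.R_mu, self.system)

    @property
    def beta_het_over_hom(self) -> float:
        """Selection ratio heterogametic/homogametic for the load model."""
        return self.beta if self.system != "ZW" else 1.0 / self.beta

    def to_dict(self) -> dict:
        return asdict(self)


BUILTIN_SCENARIOS: dict[str, GenomeScenario] = {
    s.name: s
    for s in (
        GenomeScenario(
            name="drosophila_baseline",
            system="XY",
            U_H=0.5,
            P_linked=0.2,
            R_mu=1.0,
            h_bar=0.25,
            alpha_hom=0.3,
            beta=1.0,
        ),
        GenomeScenario(
            name="drosophila_sexdiff",
            system="XY",
            U_H=0.5,
            P_linked=0.2,
            R_mu=1.0,
            h_bar=0.25,
            alpha_hom=0.1,
            beta=1.5,
        ),
        GenomeScenario(
            name="mammal_baseline",
            system="XY",
            U_H=1.1,
            P_linked=0.05,
            R_mu=1.0,
            h_bar=0.25,
            alpha_hom=0.3,
            beta=1.0,
        ),
        GenomeScenario(
            name="bird_baseline",
            system="ZW",
            U_H=1.1,
            P_linked=0.1,
            R_mu=1.0,
            h_bar=0.25,
            alpha_hom=0.3,
            beta=1.0,
        ),
        GenomeScenario(
            name="bird_sexdiff",
            system="ZW",
            U_H=1.1,
            P_linked=0.1,
            R_mu=4.0,
            h_bar=0.25,
            alpha_hom=0.3,
            beta=1.5,
        ),
        GenomeScenario(
            name="haplodiploid",
            system="haplodiploid",
            U_H=0.5,
            P_linked=1.0,
            R_mu=1.0,
            h_bar=0.25,
            alpha_hom=0.3,
            beta=1.0,
        ),
    )
}


def get_scenario(name: str) -> GenomeScenario:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        available = ", ".join(sorted(BUILTIN_SCENARIOS))
        raise KeyError(
            f"unknown scenario {name!r}; available scenarios: {available}"
        ) from None


def predict(scenario: GenomeScenario) -> LoadResult:
    """Predicted survival loads for one scenario.

    Chains the mutation budget into the load model. ``dosage_k != 1``
    routes through the no-dosage-compensation variant and is only defined
    at ``beta = 1`` (the combination of sex-differential selection with
    absent dosage compensation is rejected rather than guessed);
    ``var_h > 0`` likewise requires ``beta = 1``.
    """
    U = scenario.U_linked
    notes = {
        "scenario": scenario.name,
        "system": scenario.system,
        "U_linked": f"{U:.6g}",
    }
    if scenario.dosage_k != 1.0:
        if scenario.beta != 1.0:
            raise ModelDomainError(
                "combining sex-differential selection (beta != 1) with absent "
                "dosage compensation (dosage_k != 1) is not defined; set one "
                "of them to 1"
            )
        w_hom, w_het = component_loads_no_dosage_comp(
            U, scenario.h_bar, scenario.alpha_hom, scenario.dosage_k
        )
        notes["model"] = "no dosage compensation (hemizygous effects scaled by k)"
    elif scenario.beta != 1.0:
        if scenario.var_h != 0.0:
            raise ModelDomainError(
                "var_h > 0 is only supported in the beta = 1 baseline model"
            )
        w_hom, w_het = component_loads_sexdiff(
            U, scenario.h_bar, scenario.alpha_hom, scenario.beta_het_over_hom
        )
        notes["model"] = "sex-differential purifying selection"
    else:
        w_hom, w_het = component_loads_baseline(
            U, DominanceSummary(scenario.h_bar, scenario.var_h), scenario.alpha_hom
        )
        notes["model"] = "baseline (equal-sex selection)"
    return LoadResult(w_hom=w_hom, w_het=w_het, system=scenario.system, notes=notes)


@dataclass(frozen=True)
class SweepGrid:
    """Result of a scenario sweep: a tidy table, one row per evaluation."""

    table: pd.DataFrame
    h_bar_values: tuple[float, ...]
    alpha_values: tuple[float, ...]
    scenario_names: tuple[str, ...]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def sweep(
    scenarios: Sequence[GenomeScenario],
    h_bar_values: Sequence[float],
    alpha_values: Sequence[float],
) -> SweepGrid:
    """Evaluate :func:`predict` over scenarios x h_bar x alpha.

    Each scenario's own ``h_bar`` and ``alpha_hom`` are overridden by the
    grid axes; all other fields are kept. Rows are ordered scenario-major,
    then h_bar, then alpha.
    """
    if len(scenarios) == 0 or len(h_bar_values) == 0 or len(alpha_values) == 0:
        raise ModelDomainError("sweep grid must be non-empty on every axis")
    for h in h_bar_values:
        if not (0.0 <= h <= 0.5):
            raise ModelDomainError(f"sweep h_bar={h!r} outside [0, 0.5]")
    for a in alpha_values:
        if not (0.0 <= a <= 1.0):
            raise ModelDomainError(f"sweep alpha={a!r} outside [0, 1]")
    rows = []
    for sc in scenarios:
        for h in h_bar_values:
            for a in alpha_values:
                variant = GenomeScenario(
                    name=sc.name,
                    system=sc.system,
                    U_H=sc.U_H,
                    P_linked=sc.P_linked,
                    R_mu=sc.R_mu,
                    h_bar=float(h),
                    var_h=sc.var_h,
                    alpha_hom=float(a),
                    beta=sc.beta,
                    dosage_k=sc.dosage_k,
                )
                res = predict(variant)
                pct = res.pct
                rows.append(
                    {
                        "scenario": sc.name,
                        "system": sc.system,
                        "h_bar": float(h),
                        "alpha": float(a),
                        "U_linked": variant.U_linked,
                        "ratio": res.ratio,
                        "pct_excess": pct["excess"],
                        "pct_log": pct["log_pct"],
                    }
                )
    return SweepGrid(
        table=pd.DataFrame(rows),
        h_bar_values=tuple(float(h) for h in h_bar_values),
        alpha_values=tuple(float(a) for a in alpha_values),
        scenario_names=tuple(sc.name for sc in scenarios),
    )


def plot_sweep(grid: SweepGrid, ax=None):
    """Minimal line-plot helper: ratio vs h_bar, one line per scenario/alpha.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (name, a), sub in grid.table.groupby(["scenario", "alpha"]):
        ax.plot(sub["h_bar"], sub["ratio"], label=f"{name} (alpha={a:g})")
    ax.axhline(1.0, color="0.6", lw=0.8)
    ax.set_xlabel("mean dominance coefficient")
    ax.set_ylabel("homogametic / heterogametic survival ratio")
    ax.legend(fontsize="small")
    return ax


# ---------------------------------------------------------------------------
# config files

_SCENARIO_FIELDS = {
    "name",
    "system",
    "U_H",
    "P_linked",
    "R_mu",
    "h_bar",
    "var_h",
    "alpha_hom",
    "beta",
    "dosage_k",
}


def scenario_from_config(path: str | Path) -> GenomeScenario:
    """Load one scenario from a YAML or JSON mapping of scenario fields."""
    raw = _load_mapping(path)
    unknown = set(raw) - _SCENARIO_FIELDS
    if unknown:
        raise ModelDomainError(
            f"unknown scenario fields in {path}: {sorted(unknown)}"
        )
    missing = {"name", "system", "U_H", "P_linked"} - set(raw)
    if missing:
        raise ModelDomainError(
            f"scenario config {path} missing required fields: {sorted(missing)}"
        )
    return GenomeScenario(**raw)


def scenarios_from_config(path: str | Path) -> list[GenomeScenario]:
    """Load a list of scenarios (a config with a top-level ``scenarios`` list,
    or a single scenario mapping)."""
    raw = _load_mapping(path, allow_list_key="scenarios")
    if isinstance(raw, list):
        out = []
        for entry in raw:
            if isinstance(entry, str):
                out.append(get_scenario(entry))
            else:
                out.append(GenomeScenario(**entry))
        return out
    return [GenomeScenario(**raw)]


def _load_mapping(path: str | Path, allow_list_key: str | None = None):
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ModelDomainError(f"config {path} must contain a mapping")
    if allow_list_key and allow_list_key in data:
        return data[allow_list_key]
    return data
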