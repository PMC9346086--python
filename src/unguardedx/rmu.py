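"""Reading, cleaning, and summarizing tables of published sex-biased
mutation-rate estimates (the male/female per-site ratio, Rmu).

Compilations of Rmu estimates from the literature typically carry several
estimates for well-studied species, occasional implausible outliers, and a
mixture of species-level and multi-species (lineage-group) estimates. The
curation pipeline implemented here is: (1) load and validate the table,
(2) apply exclusions (named records and/or an upper threshold on the
estimate), (3) average multiple estimates within species, (4) summarize per
lineage group. Exclusions are applied *before* species averaging so an
excluded extreme estimate cannot contaminate its species' mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .load_model import ModelDomainError

__all__ = [
    "RMU_REQUIRED_COLUMNS",
    "RmuLoadResult",
    "load_rmu",
    "species_average",
    "apply_exclusions",
    "group_summary",
    "curate",
]

RMU_REQUIRED_COLUMNS = [
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
class RmuLoadResult:
    """Validated records plus a row-level rejection report."""

    records: pd.DataFrame
    rejected: pd.DataFrame  # columns: line, reason

    @property
    def n_loaded(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def load_rmu(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> RmuLoadResult:
    """Load a delimited Rmu table, validating schema and row invariants.

    ``column_map`` renames dialect column names onto the standard schema
    (``{"file column": "standard column"}``). Rows with a non-positive or
    unparseable estimate, or with bounds that do not bracket the estimate,
    are diverted to the rejection report with their 1-based data line
    number; they never raise. Missing interval bounds are permitted.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in RMU_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ModelDomainError(
            f"Rmu table {path} is missing required columns: {missing}"
        )
    df = df[RMU_REQUIRED_COLUMNS].copy()
    df["estimate"] = pd.to_numeric(df["estimate"], errors="coerce")
    df["ci_low"] = pd.to_numeric(df["ci_low"], errors="coerce")
    df["ci_high"] = pd.to_numeric(df["ci_high"], errors="coerce")
    df["species_level"] = df["species_level"].astype(bool)

    reasons = pd.Series("", index=df.index, dtype=object)
    bad_est = df["estimate"].isna() | (df["estimate"] <= 0)
    reasons[bad_est] = "estimate missing, unparseable, or <= 0"
    has_bounds = df["ci_low"].notna() & df["ci_high"].notna()
    bad_bounds = has_bounds & ~(
        (df["ci_low"] <= df["estimate"]) & (df["estimate"] <= df["ci_high"])
    )
    reasons[bad_bounds & ~bad_est] = "interval bounds do not bracket the estimate"

    bad = reasons != ""
    rejected = pd.DataFrame(
        {
            "line": (df.index[bad] + 2).astype(int),  # header is line 1
            "reason": reasons[bad].to_numpy(),
        }
    )
    return RmuLoadResult(
        records=df[~bad].reset_index(drop=True), rejected=rejected
    )


def apply_exclusions(
    records: pd.DataFrame,
    exclude_species: Sequence[str] = (),
    exclude_sources: Sequence[str] = (),
    threshold: float | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove named records and/or estimates above a threshold.

    Returns the filtered table and an audit log listing every removal with
    its reason. Naming an absent species or source warns via the audit log
    (an entry with ``n_removed = 0``) rather than raising.
    """
    out = records.copy()
    audit: list[dict] = []
    for sp in exclude_species:
        mask = out["species"] == sp
        audit.append(
            {"rule": f"exclude species {sp!r}", "n_removed": int(mask.sum())}
        )
        out = out[~mask]
    for src in exclude_sources:
        mask = out["source"] == src
        audit.append(
            {"rule": f"exclude source {src!r}", "n_removed": int(mask.sum())}
        )
        out = out[~mask]
    if threshold is not None:
        mask = out["estimate"] >= threshold
        removed = out[mask]
        audit.append(
            {
                "rule": f"exclude estimates >= {threshold}",
                "n_removed": int(mask.sum()),
                "removed_species": sorted(removed["species"].unique().tolist()),
            }
        )
        out = out[~mask]
    return out.reset_index(drop=True), audit


def species_average(records: pd.DataFrame) -> pd.DataFrame:
    """One row per species: the arithmetic mean of its estimates.

    Only species-level records are averaged (multi-species lineage-group
    estimates are dropped). The lineage-group label of the species' first
    record is carried through. Idempotent: averaging an already-averaged
    table returns it unchanged.
    """
    sub = records[records["species_level"]]
    if len(sub) == 0:
        return pd.DataFrame(
            columns=["species", "lineage_group", "estimate", "n_estimates"]
        )
    grouped = (
        sub.groupby("species", sort=True)
        .agg(
            lineage_group=("lineage_group", "first"),
            estimate=("estimate", "mean"),
            n_estimates=("estimate", "size"),
        )
        .reset_index()
    )
    return grouped


def group_summary(per_species: pd.DataFrame, central: float = 0.90) -> pd.DataFrame:
    """Per-lineage-group count, mean, median, and central range.

    ``central`` sets the central quantile mass of the reported range
    (default the 5th-95th percentile band).
    """
    if len(per_species) == 0:
        raise ModelDomainError("group_summary requires a non-empty table")
    lo_q = (1.0 - central) / 2.0
    hi_q = 1.0 - lo_q
    out = (
        per_species.groupby("lineage_group", sort=True)["estimate"]
        .agg(
            n="size",
            mean="mean",
            median="median",
            range_low=lambda s: float(np.quantile(s, lo_q)),
            range_high=lambda s: float(np.quantile(s, hi_q)),
        )
        .reset_index()
    )
    return out


def curate(
    load_result: RmuLoadResult,
    exclude_species: Sequence[str] = (),
    exclude_sources: Sequence[str] = (),
    threshold: float | None = None,
) -> dict:
    """Full curation pipeline: exclusions -> species averaging -> summary.

    Returns a dict with the per-species table, the per-group summary, and
    an audit log covering rejected rows and exclusions.
    """
    filtered, audit = apply_exclusions(
        load_result.records,
        exclude_species=exclude_species,
        exclude_sources=exclude_sources,
        threshold=threshold,
    )
    per_species = species_average(filtered)
    summary = group_summary(per_species) if len(per_species) else None
    return {
        "per_species": per_species,
        "group_summary": summary,
        "n_species_level_estimates": int(len(per_species)),
        "audit": {
            "rows_rejected_on_load": load_result.rejected.to_dict("records"),
            "exclusions": audit,
        },
    }
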