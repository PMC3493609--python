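"""Enzyme-activity indices from NEFA product:substrate ratios.

Plasma product-to-substrate concentration ratios proxy desaturase,
elongase and peroxisomal chain-shortening activities: SCD (stearoyl-CoA
desaturase) from 16:1n7/16:0 and 18:1n9/18:0, D6D (delta-6 desaturase)
from 18:3n6/18:2n6 and 20:3n3/20:4n6, ELOVL2 (elongase of very long chain
fatty acids 2) from 22:4n6/20:4n6 and 22:5n3/20:5n3, and the composite
ELOVL2/D6D/SPCS axis (Sprecher-pathway chain shortening) from
22:5n6/22:4n6 and 22:6n3/22:5n3.

A composite index value for one subject is the arithmetic mean of that
subject's component ratios; group summaries (GM, range, percent change in
GM, Mann-Whitney p) are then computed exactly as for a metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortTable, ValidationError
from .univariate import UnivariateResult, _compare_groups, bh_fdr

__all__ = [
    "ActivityIndexDef",
    "ActivityIndexResult",
    "builtin_index_defs",
    "compute_ratio",
    "compute_index",
    "summarize_indices",
]


@dataclass(frozen=True)
class ActivityIndexDef:
    """A named activity index built from product:substrate ratio(s)."""

    name: str
    component_ratios: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.component_ratios:
            raise ValidationError(f"index {self.name!r} needs >= 1 component ratio")


@dataclass
class ActivityIndexResult:
    """Summary of one index (or one component ratio) across the cohort."""

    name: str
    values: pd.Series
    summary: UnivariateResult
    components: list["ActivityIndexResult"] = field(default_factory=list)

    @property
    def delta_gm_pct(self) -> float:
        return self.summary.delta_gm_pct

    @property
    def fdr_significant(self) -> bool:
        return self.summary.fdr_significant


def builtin_index_defs() -> list[ActivityIndexDef]:
    """The four composite NEFA activity indices."""
    return [
        ActivityIndexDef("SCD", (("16:1n7", "16:0"), ("18:1n9", "18:0"))),
        ActivityIndexDef("D6D", (("18:3n6", "18:2n6"), ("20:3n3", "20:4n6"))),
        ActivityIndexDef("ELOVL2", (("22:4n6", "20:4n6"), ("22:5n3", "20:5n3"))),
        ActivityIndexDef(
            "ELOVL2/D6D/SPCS", (("22:5n6", "22:4n6"), ("22:6n3", "22:5n3"))
        ),
    ]


def compute_ratio(table: CohortTable, product: str, substrate: str) -> pd.Series:
    """Per-subject product/substrate ratio; missing either value -> NaN."""
    for m in (product, substrate):
        if m not in table.concentrations.columns:
            raise ValidationError(f"metabolite {m!r} not in the cohort table")
    return (table.concentrations[product] / table.concentrations[substrate]).rename(
        f"{product}/{substrate}"
    )


def _summarize_values(name: str, values: pd.Series, table: CohortTable, mode: str):
    g0, g1 = table.group_order
    v0 = values[table.group_mask(g0)].dropna().to_numpy(dtype=float)
    v1 = values[table.group_mask(g1)].dropna().to_numpy(dtype=float)
    if len(v0) == 0 or len(v1) == 0:
        raise ValidationError(f"index {name!r} has an empty group after masking")
    summary = _compare_groups(name, v0, v1, mode)
    return summary


def compute_index(
    table: CohortTable,
    index_def: ActivityIndexDef,
    mode: str = "normal-approx",
) -> ActivityIndexResult:
    """Evaluate an activity index: component ratios plus the composite.

    The composite per-subject value is the arithmetic mean of the
    subject's component ratios; subjects missing any component are masked
    (no imputation).
    """
    components = []
    ratio_frame = {}
    for product, substrate in index_def.component_ratios:
        r = compute_ratio(table, product, substrate)
        components.append(
            ActivityIndexResult(
                name=r.name, values=r, summary=_summarize_values(r.name, r, table, mode)
            )
        )
        ratio_frame[r.name] = r
    composite = pd.DataFrame(ratio_frame).mean(axis=1, skipna=False)
    composite = composite.rename(index_def.name)
    return ActivityIndexResult(
        name=index_def.name,
        values=composite,
        summary=_summarize_values(index_def.name, composite, table, mode),
        components=components,
    )


def summarize_indices(
    table: CohortTable,
    defs: list[ActivityIndexDef] | None = None,
    q: float = 0.1,
    mode: str = "normal-approx",
) -> list[ActivityIndexResult]:
    """Evaluate all indices with joint FDR over composites and components."""
    defs = builtin_index_defs() if defs is None else defs
    results = [compute_index(table, d, mode=mode) for d in defs]
    flat: list[UnivariateResult] = []
    for r in results:
        flat.append(r.summary)
        flat.extend(c.summary for c in r.components)
    rejected = bh_fdr([s.p_value for s in flat], q=q)
    for s, rej in zip(flat, rejected):
        s.fdr_significant = bool(rej)
    return results


def indices_to_frame(results: list[ActivityIndexResult]) -> pd.DataFrame:
    """Flat report table: composite rows followed by their components."""
    from .univariate import results_to_frame

    flat = []
    for r in results:
        flat.append(r.summary)
        flat.extend(c.summary for c in r.components)
    return results_to_frame(flat)
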