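"""Geometric-mean summaries, Mann-Whitney U tests and BH-FDR control.

The cohort comparison is nonparametric throughout: per-metabolite group
geometric means (GM) with observed ranges, the percent change in GM
between groups, a two-sided Mann-Whitney U test, and Benjamini-Hochberg
step-up FDR control at q = 0.1 across the whole tested family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CohortTable, ValidationError

__all__ = [
    "UnivariateResult",
    "geometric_mean",
    "delta_gm",
    "mann_whitney_u",
    "bh_fdr",
    "summarize_cohort",
    "results_to_frame",
]


def geometric_mean(values) -> float:
    """Geometric mean: exp of the arithmetic mean of natural logs."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("geometric mean of an empty sample is undefined")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValidationError("geometric mean requires finite positive values")
    return float(np.exp(np.mean(np.log(v))))


def delta_gm(gm0: float, gm1: float) -> float:
    """Percent change in geometric mean, 100 * (gm1 - gm0) / gm0."""
    if gm0 <= 0:
        raise ValidationError("reference geometric mean must be positive")
    return 100.0 * (gm1 - gm0) / gm0


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x from midrank sums."""
    n1 = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y, mode: str = "normal-approx") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks for ties.

    ``mode="exact"`` enumerates the full null permutation distribution of
    U over group labelings (feasible for n1 + n2 <= 20 and valid under
    ties); ``mode="normal-approx"`` uses the tie-corrected normal
    approximation with continuity correction.  Returns ``(U, p)`` with U
    referenced to the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    if mode == "normal-approx":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if mode != "exact":
        raise ValidationError(f"unknown mode {mode!r}")
    if n1 + n2 > 20:
        raise ValidationError("exact enumeration is limited to n1 + n2 <= 20")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


def bh_fdr(p_values, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection vector at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class UnivariateResult:
    """Per-variable group comparison (one row of a cohort summary table)."""

    metabolite: str
    gm_group0: float
    gm_group1: float
    range_group0: tuple[float, float]
    range_group1: tuple[float, float]
    delta_gm_pct: float
    u_statistic: float
    p_value: float
    fdr_significant: bool = False
    degenerate: bool = False
    n_group0: int = 0
    n_group1: int = 0


def _compare_groups(name: str, v0: np.ndarray, v1: np.ndarray, mode: str):
    gm0, gm1 = geometric_mean(v0), geometric_mean(v1)
    if np.ptp(v0) == 0 and np.ptp(v1) == 0 and v0[0] == v1[0]:
        u, p, degen = len(v0) * len(v1) / 2.0, 1.0, True
    else:
        u, p = mann_whitney_u(v0, v1, mode=mode)
        degen = False
    return UnivariateResult(
        metabolite=name,
        gm_group0=gm0,
        gm_group1=gm1,
        range_group0=(float(v0.min()), float(v0.max())),
        range_group1=(float(v1.min()), float(v1.max())),
        delta_gm_pct=delta_gm(gm0, gm1),
        u_statistic=u,
        p_value=p,
        degenerate=degen,
        n_group0=len(v0),
        n_group1=len(v1),
    )


def summarize_cohort(
    table: CohortTable,
    q: float = 0.1,
    include_class_sums: bool = True,
    mode: str = "normal-approx",
) -> list[UnivariateResult]:
    """One result per metabolite plus per-class totals, FDR'ed jointly.

    Class totals are computed per subject (sum of observed class members,
    requiring a complete set and uniform units) before any GM is taken,
    since the GM of sums is not the sum of GMs.  Benjamini-Hochberg FDR at
    level ``q`` is applied across every hypothesis tested in the call.
    """
    g0, g1 = table.group_order
    results: list[UnivariateResult] = []
    for m in table.metabolites:
        v0, v1 = table.group_values(m, g0), table.group_values(m, g1)
        if len(v0) == 0 or len(v1) == 0:
            continue
        results.append(_compare_groups(m, v0, v1, mode))

    if include_class_sums:
        conc = table.concentrations
        for cls in table.panel.classes:
            members = [m for m in table.panel.members(cls) if m in conc.columns]
            if len(members) < 2:
                continue
            units = {table.panel[m].unit for m in members}
            if len(units) != 1:
                raise ValidationError(
                    f"class {cls!r} mixes units {sorted(units)}; cannot sum"
                )
            total = conc[members].sum(axis=1, skipna=False)
            v0 = total[table.group_mask(g0)].dropna().to_numpy()
            v1 = total[table.group_mask(g1)].dropna().to_numpy()
            if len(v0) == 0 or len(v1) == 0:
                continue
            results.append(_compare_groups(f"Σ {cls} (computed)", v0, v1, mode))

    rejected = bh_fdr([r.p_value for r in results], q=q)
    for r, rej in zip(results, rejected):
        r.fdr_significant = bool(rej)
    return results


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def results_to_frame(results: list[UnivariateResult], rounded: bool = True):
    """Report table mirroring the cohort summary layout.

    GMs are rounded to 3 significant figures and the percent change in GM
    to the nearest integer, matching conventional reporting.
    """
    import pandas as pd

    rows = []
    for r in results:
        gm0, gm1 = r.gm_group0, r.gm_group1
        dgm: float = r.delta_gm_pct
        if rounded:
            gm0, gm1 = _round_sig(gm0), _round_sig(gm1)
            dgm = int(round(dgm))
        rows.append(
            {
                "metabolite": r.metabolite,
                "gm_group0": gm0,
                "range_group0": f"[{r.range_group0[0]:g}, {r.range_group0[1]:g}]",
                "gm_group1": gm1,
                "range_group1": f"[{r.range_group1[0]:g}, {r.range_group1[1]:g}]",
                "delta_gm_pct": dgm,
                "U": r.u_statistic,
                "p": r.p_value,
                "fdr_significant": r.fdr_significant,
            }
        )
    return pd.DataFrame(rows)
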