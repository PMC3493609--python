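"""Synthetic cohort generation.

Cohorts are drawn with the statistical structure the analysis chain
assumes: per-metabolite log-normal concentrations with group-specific
geometric means (group effects enter as a location shift on the log
scale), pathway-coupled product/substrate pairs whose ratio is itself
log-normal around a group ratio GM, and Gaussian clinical covariates that
can be rank-coupled to a named metabolite via a Gaussian copula to hit a
target Spearman correlation.

``default_paper_spec`` packages a ~40-variable plasma lipid panel (NEFA,
oxylipins, N-acylethanolamides, lipoamino acids) with two groups of 12 and
43 subjects, anchored at reported cohort geometric means, so every
downstream stage can be exercised on data with realistic effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _tables
from .core import (
    CohortTable,
    MetaboliteAnnotation,
    MetabolitePanel,
    QuantRecord,
    ValidationError,
)

__all__ = [
    "MetaboliteSpec",
    "PathwayCoupling",
    "CovariateSpec",
    "CohortSpec",
    "generate_cohort",
    "generate_quant_records",
    "default_paper_spec",
    "log_sd_from_range",
]

#: The observed [min, max] of a log-normal sample is assumed to span about
#: +/- 2.5 log-scale standard deviations at the study group sizes.
RANGE_SPAN_SD = 5.0


def log_sd_from_range(lo: float, hi: float) -> float:
    """Back-calculate a log-scale sd from an observed [min, max] range."""
    if not (0 < lo < hi):
        raise ValidationError(f"invalid range [{lo}, {hi}]")
    return math.log(hi / lo) / RANGE_SPAN_SD


@dataclass(frozen=True)
class MetaboliteSpec:
    """Log-normal law for one metabolite: group GMs and a shared log-sd."""

    gm: tuple[float, float]
    log_sd: float

    def __post_init__(self) -> None:
        if min(self.gm) <= 0 or self.log_sd < 0:
            raise ValidationError("GMs must be positive and log_sd nonnegative")


@dataclass(frozen=True)
class PathwayCoupling:
    """Product generated as substrate x log-normal ratio (group ratio GMs)."""

    substrate: str
    product: str
    gm_ratio: tuple[float, float]
    ratio_log_sd: float
    enzyme: str = ""

    def __post_init__(self) -> None:
        if min(self.gm_ratio) <= 0 or self.ratio_log_sd < 0:
            raise ValidationError("ratio GMs must be positive, log_sd nonnegative")


@dataclass(frozen=True)
class CovariateSpec:
    """Gaussian clinical covariate, optionally rank-coupled to a metabolite."""

    mean: tuple[float, float]
    sd: tuple[float, float]
    rho_target: float | None = None
    anchor: str | None = None

    def __post_init__(self) -> None:
        if min(self.sd) <= 0:
            raise ValidationError("covariate sd must be positive")
        if self.rho_target is not None:
            if abs(self.rho_target) > 0.999:
                raise ValidationError("copula target |rho| > 0.999 is infeasible")
            if self.anchor is None:
                raise ValidationError("rho_target requires an anchor variable")


@dataclass
class CohortSpec:
    """Full recipe for a two-group synthetic cohort."""

    metabolite_specs: dict[str, MetaboliteSpec]
    pathway_couplings: list[PathwayCoupling] = field(default_factory=list)
    covariate_specs: dict[str, CovariateSpec] = field(default_factory=dict)
    n_per_group: tuple[int, int] = (12, 43)
    group_labels: tuple[str, str] = ("group0", "group1")
    panel: MetabolitePanel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 3:
            raise ValidationError("need at least 3 subjects per group")
        names = set(self.metabolite_specs)
        for c in self.pathway_couplings:
            if c.substrate not in names:
                raise ValidationError(f"coupling substrate {c.substrate!r} undeclared")
            if c.product in names:
                raise ValidationError(
                    f"coupled product {c.product!r} also declared independently"
                )
            names.add(c.product)
        for name, cov in self.covariate_specs.items():
            if cov.anchor is not None and cov.anchor not in names:
                raise ValidationError(
                    f"covariate {name!r} anchored to unknown variable {cov.anchor!r}"
                )

    @property
    def variable_names(self) -> list[str]:
        return list(self.metabolite_specs) + [
            c.product for c in self.pathway_couplings
        ]


def _default_panel(spec: CohortSpec) -> MetabolitePanel:
    annotations = {
        name: MetaboliteAnnotation(name, "other-oxylipin", 18, 1, "nM")
        for name in spec.variable_names
    }
    edges = [(c.substrate, c.product, c.enzyme) for c in spec.pathway_couplings]
    return MetabolitePanel(annotations=annotations, pathway_edges=edges)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortTable:
    """Draw a cohort from a :class:`CohortSpec`, reproducibly from its seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n0, n1 = spec.n_per_group
    n = n0 + n1
    group = np.array([spec.group_labels[0]] * n0 + [spec.group_labels[1]] * n1)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    gidx = [np.arange(n0), np.arange(n0, n)]

    cols: dict[str, np.ndarray] = {}
    for name, ms in spec.metabolite_specs.items():
        x = np.empty(n)
        for g, idx in enumerate(gidx):
            x[idx] = np.exp(
                math.log(ms.gm[g]) + ms.log_sd * rng.standard_normal(len(idx))
            )
        cols[name] = x
    for c in spec.pathway_couplings:
        ratio = np.empty(n)
        for g, idx in enumerate(gidx):
            ratio[idx] = np.exp(
                math.log(c.gm_ratio[g]) + c.ratio_log_sd * rng.standard_normal(len(idx))
            )
        cols[c.product] = cols[c.substrate] * ratio

    clin: dict[str, np.ndarray] = {}
    for name, cv in spec.covariate_specs.items():
        x = np.empty(n)
        for g, idx in enumerate(gidx):
            eps = rng.standard_normal(len(idx))
            if cv.rho_target is None:
                z = eps
            else:
                # Gaussian copula: convert the anchor to normal scores via
                # midranks, then mix.  The Pearson correlation of the
                # latent Gaussians that yields Spearman rho_s is
                # 2 sin(pi rho_s / 6).
                anchor = cols[cv.anchor][idx]
                ranks = pd.Series(anchor).rank().to_numpy()
                from scipy.stats import norm

                za = norm.ppf((ranks - 0.5) / len(idx))
                rp = 2.0 * math.sin(math.pi * cv.rho_target / 6.0)
                z = rp * za + math.sqrt(1.0 - rp * rp) * eps
            x[idx] = cv.mean[g] + cv.sd[g] * z
        clin[name] = x

    panel = spec.panel if spec.panel is not None else _default_panel(spec)
    return CohortTable(
        concentrations=pd.DataFrame(cols, index=subjects),
        group=pd.Series(group, index=subjects, name="group"),
        clinical=pd.DataFrame(clin, index=subjects),
        panel=panel,
        group_order=spec.group_labels,
    )


def generate_quant_records(
    n: int,
    fail_fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> list[QuantRecord]:
    """Draw QC records with prescribed expected rule-failure fractions.

    ``fail_fractions`` keys: ``"sn"`` (signal-to-noise below 2),
    ``"calibrant"`` (below lowest calibrant), ``"recovery"`` (surrogate
    recovery below 40%).  Each record fails at most one rule; fractions
    must sum to at most 1.
    """
    fail_fractions = dict(fail_fractions or {})
    unknown = set(fail_fractions) - {"sn", "calibrant", "recovery"}
    if unknown:
        raise ValidationError(f"unknown failure rules: {sorted(unknown)}")
    fracs = [fail_fractions.get(k, 0.0) for k in ("sn", "calibrant", "recovery")]
    if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValidationError("failure fractions must lie in [0,1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    cats = rng.choice(4, size=n, p=[*fracs, 1.0 - sum(fracs)])
    records = []
    for i, cat in enumerate(cats):
        sn = 10.0 * (1.0 + rng.uniform())
        raw = 5.0 * (1.0 + rng.uniform())
        recovery = 0.7 + 0.25 * rng.uniform()
        calibrant = 1.0
        if cat == 0:
            sn = 1.9 * rng.uniform()
        elif cat == 1:
            raw = calibrant * (0.05 + 0.9 * rng.uniform())
        elif cat == 2:
            recovery = 0.39 * rng.uniform()
        records.append(
            QuantRecord(
                analyte=f"analyte_{i:05d}",
                raw_concentration=raw,
                signal_to_noise=sn,
                surrogate_recovery=recovery,
                lowest_calibrant=calibrant,
            )
        )
    return records


def default_paper_spec(
    ratio_log_sd: float = 0.25, seed: int = 0
) -> CohortSpec:
    """The packaged study-cohort recipe.

    Two groups (12 non-diabetic, 43 type 2 diabetic); per-variable GMs
    equal the reported cohort geometric means; log-scale sds back-derived
    from the reported [min, max] ranges; index metabolites not reported
    individually are generated by pathway couplings at the reported
    product:substrate ratio GMs; clinical covariates follow the reported
    mean +/- sd, with fasting glucose rank-coupled to total NEFA at
    Spearman rho = 0.68.
    """
    metabolite_specs: dict[str, MetaboliteSpec] = {}
    annotations: dict[str, MetaboliteAnnotation] = {}
    for name, (cls, carbons, db, unit, gm0, r0, gm1, r1) in _tables.PANEL.items():
        log_sd = 0.5 * (log_sd_from_range(*r0) + log_sd_from_range(*r1))
        metabolite_specs[name] = MetaboliteSpec(gm=(gm0, gm1), log_sd=log_sd)
        annotations[name] = MetaboliteAnnotation(name, cls, carbons, db, unit)

    couplings = []
    for sub, prod, enz, r_nd, r_d, (cls, carbons, db, unit) in _tables.COUPLED:
        couplings.append(
            PathwayCoupling(
                substrate=sub,
                product=prod,
                gm_ratio=(r_nd, r_d),
                ratio_log_sd=ratio_log_sd,
                enzyme=enz,
            )
        )
        annotations[prod] = MetaboliteAnnotation(prod, cls, carbons, db, unit)

    covariate_specs = {
        name: CovariateSpec(mean=(m0, m1), sd=(s0, s1), rho_target=rho, anchor=anchor)
        for name, ((m0, s0), (m1, s1), _units, rho, anchor) in _tables.CLINICAL.items()
    }

    panel = MetabolitePanel(
        annotations=annotations, pathway_edges=list(_tables.PATHWAY_EDGES)
    )
    return CohortSpec(
        metabolite_specs=metabolite_specs,
        pathway_couplings=couplings,
        covariate_specs=covariate_specs,
        n_per_group=_tables.N_PER_GROUP,
        group_labels=_tables.GROUP_LABELS,
        panel=panel,
        seed=seed,
    )
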