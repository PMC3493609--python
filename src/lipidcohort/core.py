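"""Domain types, cohort table I/O and quality-control reporting filters.

The package operates on a subjects x metabolites concentration table
(``CohortTable``) accompanied by a metabolite annotation panel
(``MetabolitePanel``) that records chemical class, chain length, units and
the substrate -> product edges of the biosynthetic pathway graph.

Quality control mirrors standard targeted-lipidomics reporting practice:
raw quantification records are corrected for surrogate losses and an
analyte is unreportable when its signal-to-noise ratio falls below 2, its
calculated concentration falls below the lowest calibrant, or its
surrogate recovery falls below 40%.  All three rules are strict
inequalities: a record exactly at a threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHEM_CLASSES",
    "MetaboliteAnnotation",
    "MetabolitePanel",
    "CohortTable",
    "QuantRecord",
    "ValidationError",
    "correct_surrogate_loss",
    "apply_reporting_criteria",
    "apply_cohort_reporting",
    "read_cohort",
    "write_cohort",
    "read_annotations",
    "write_annotations",
]

#: Recognized chemical classes.  ``aggregate`` marks class-total variables
#: (e.g. total NEFA) that are carried in the table as their own columns and
#: excluded from class sums and discriminant modeling.
CHEM_CLASSES = frozenset(
    {
        "SFA",
        "MUFA",
        "PUFA",
        "trans-FA",
        "epoxide",
        "diol",
        "ketone",
        "alcohol",
        "isoprostane",
        "NAE",
        "MAG",
        "LAA",
        "other-oxylipin",
        "aggregate",
    }
)

RESERVED_COLUMNS = ("subject", "group")


class ValidationError(ValueError):
    """Raised when a table or record violates a structural contract."""


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """Per-metabolite chemical annotation.

    Parameters
    ----------
    name
        Unique metabolite identifier, e.g. ``"18:1n9"``.
    chem_class
        One of :data:`CHEM_CLASSES`.
    carbons
        Acyl chain length (drives the <20 / >=20 carbon node roles in
        connectivity networks).
    double_bonds
        Number of double bonds.
    unit
        Concentration unit, ``"uM"`` or ``"nM"``; fixed per metabolite and
        never converted silently.
    """

    name: str
    chem_class: str
    carbons: int
    double_bonds: int
    unit: str

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"unknown chemical class {self.chem_class!r} for {self.name!r}"
            )
        if self.unit not in ("uM", "nM"):
            raise ValidationError(f"unknown unit {self.unit!r} for {self.name!r}")

    @property
    def is_aggregate(self) -> bool:
        return self.chem_class == "aggregate"


@dataclass
class MetabolitePanel:
    """A set of metabolite annotations plus the biosynthetic edge list.

    ``pathway_edges`` holds ``(substrate, product, enzyme)`` triples with
    arrows pointing along the biosynthetic gradient (substrate to product).
    """

    annotations: dict[str, MetaboliteAnnotation]
    pathway_edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sub, prod, _enz in self.pathway_edges:
            for end in (sub, prod):
                if end not in self.annotations:
                    raise ValidationError(
                        f"pathway edge endpoint {end!r} is not an annotated metabolite"
                    )

    def __contains__(self, name: str) -> bool:
        return name in self.annotations

    def __getitem__(self, name: str) -> MetaboliteAnnotation:
        return self.annotations[name]

    @property
    def names(self) -> list[str]:
        return list(self.annotations)

    def members(self, chem_class: str) -> list[str]:
        """Names of non-aggregate metabolites of a chemical class."""
        return [
            a.name
            for a in self.annotations.values()
            if a.chem_class == chem_class and not a.is_aggregate
        ]

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for a in self.annotations.values():
            if not a.is_aggregate and a.chem_class not in seen:
                seen.append(a.chem_class)
        return seen


@dataclass
class CohortTable:
    """Subjects x metabolites concentrations with group labels and covariates.

    ``concentrations`` holds strictly positive values where observed and
    ``NaN`` where missing (missingness is explicit, never encoded as zero,
    since all downstream statistics are log-scale).  ``group`` must have
    exactly two levels; ``group_order`` fixes which is the reference
    (non-diseased) group.
    """

    concentrations: pd.DataFrame
    group: pd.Series
    clinical: pd.DataFrame
    panel: MetabolitePanel
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        levels = pd.unique(self.group)
        if len(levels) != 2:
            raise ValidationError(
                f"group must have exactly two levels, found {list(levels)}"
            )
        if self.group_order is None:
            self.group_order = (str(levels[0]), str(levels[1]))
        if set(self.group_order) != {str(v) for v in levels}:
            raise ValidationError("group_order does not match group labels")
        if not self.concentrations.index.equals(self.group.index):
            raise ValidationError("concentrations and group must share subjects")
        if not self.clinical.empty and not self.clinical.index.equals(
            self.concentrations.index
        ):
            raise ValidationError("clinical and concentrations must share subjects")
        if self.clinical.columns.duplicated().any():
            raise ValidationError("clinical covariate names must be unique")
        vals = self.concentrations.to_numpy(dtype=float)
        bad = (vals <= 0) & ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "nonpositive concentration for subject "
                f"{self.concentrations.index[i]!r}, metabolite "
                f"{self.concentrations.columns[j]!r}"
            )
        missing = [m for m in self.concentrations.columns if m not in self.panel]
        if missing:
            raise ValidationError(f"metabolites without annotation: {missing}")

    # -- accessors -----------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.concentrations.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.concentrations)

    def group_mask(self, label: str) -> np.ndarray:
        return (self.group == label).to_numpy()

    def group_values(self, metabolite: str, label: str) -> np.ndarray:
        """Observed (non-missing) values of one metabolite in one group."""
        col = self.concentrations.loc[self.group_mask(label), metabolite]
        return col.dropna().to_numpy(dtype=float)

    def modeling_metabolites(self) -> list[str]:
        """Metabolite columns eligible as model features (no aggregates)."""
        return [m for m in self.metabolites if not self.panel[m].is_aggregate]

    def labels01(self) -> np.ndarray:
        """Group coded 0 (reference) / 1 per ``group_order``."""
        return (self.group == self.group_order[1]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# QC records and reporting criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantRecord:
    """One raw quantification with its per-analyte QC metadata."""

    analyte: str
    raw_concentration: float
    signal_to_noise: float
    surrogate_recovery: float
    lowest_calibrant: float

    def __post_init__(self) -> None:
        for fname in (
            "raw_concentration",
            "signal_to_noise",
            "surrogate_recovery",
            "lowest_calibrant",
        ):
            v = getattr(self, fname)
            if not np.isfinite(v):
                raise ValidationError(f"{fname} must be finite, got {v!r}")
        if self.raw_concentration <= 0:
            raise ValidationError("raw_concentration must be positive")
        if self.signal_to_noise < 0:
            raise ValidationError("signal_to_noise must be nonnegative")
        if self.surrogate_recovery < 0:
            raise ValidationError("surrogate_recovery must be nonnegative")
        if self.lowest_calibrant <= 0:
            raise ValidationError("lowest_calibrant must be positive")


def correct_surrogate_loss(record: QuantRecord) -> float:
    """Correct a raw concentration for surrogate losses.

    Returns ``raw_concentration / surrogate_recovery`` so that a recovery
    of 50% doubles the reported concentration.
    """
    if record.surrogate_recovery <= 0:
        raise ZeroDivisionError(
            f"surrogate recovery for {record.analyte!r} is zero; cannot correct"
        )
    return record.raw_concentration / record.surrogate_recovery


def apply_reporting_criteria(
    records: Iterable[QuantRecord],
    sn_min: float = 2.0,
    recovery_min: float = 0.40,
) -> tuple[list[QuantRecord], list[tuple[QuantRecord, list[str]]]]:
    """Partition records into reportable and unreportable sets.

    A record is dropped iff S/N < ``sn_min``, the raw concentration is
    below the lowest calibrant, or the surrogate recovery is below
    ``recovery_min``.  All rules are strict, so records exactly at a
    threshold are kept.  Every dropped record carries the list of rules it
    violated.
    """
    if sn_min <= 0 or recovery_min <= 0:
        raise ValidationError("reporting thresholds must be positive")
    kept: list[QuantRecord] = []
    dropped: list[tuple[QuantRecord, list[str]]] = []
    for rec in records:
        reasons = []
        if rec.signal_to_noise < sn_min:
            reasons.append(f"S/N < {sn_min:g}")
        if rec.raw_concentration < rec.lowest_calibrant:
            reasons.append("below lowest calibrant")
        if rec.surrogate_recovery < recovery_min:
            reasons.append(f"recovery < {recovery_min:.0%}")
        if reasons:
            dropped.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, dropped


def apply_cohort_reporting(
    table: CohortTable,
    reportable: pd.DataFrame,
    mode: str = "exclude-metabolite",
    max_unreportable: float = 0.5,
) -> CohortTable:
    """Apply per-value reportability flags to a cohort table.

    Parameters
    ----------
    reportable
        Boolean frame aligned with ``table.concentrations``; ``False``
        marks values failing the reporting criteria.
    mode
        ``"exclude-metabolite"`` drops a metabolite panel-wide when more
        than ``max_unreportable`` of either group's values are
        unreportable (the default, mirroring an all-or-nothing reporting
        table); ``"per-subject"`` masks individual failing values instead.
    """
    if mode not in ("exclude-metabolite", "per-subject"):
        raise ValidationError(f"unknown reporting mode {mode!r}")
    reportable = reportable.reindex(
        index=table.concentrations.index, columns=table.concentrations.columns
    ).fillna(True)
    conc = table.concentrations.copy()
    if mode == "per-subject":
        conc = conc.where(reportable)
    else:
        keep_cols = []
        for m in conc.columns:
            ok = True
            for g in table.group_order:
                mask = table.group_mask(g)
                frac_bad = 1.0 - reportable.loc[mask, m].mean()
                if frac_bad > max_unreportable:
                    ok = False
            if ok:
                keep_cols.append(m)
        conc = conc[keep_cols]
    return CohortTable(
        concentrations=conc,
        group=table.group,
        clinical=table.clinical,
        panel=table.panel,
        group_order=table.group_order,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_annotations(path: str | Path) -> MetabolitePanel:
    """Read an annotation table (CSV/TSV).

    Columns: ``name, class, carbons, double_bonds, unit`` and optionally
    ``substrate, product, enzyme`` defining one pathway edge per row (rows
    with empty substrate/product carry no edge).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    required = {"name", "class", "carbons", "double_bonds", "unit"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"annotation table missing columns {sorted(required - set(df.columns))}"
        )
    annotations: dict[str, MetaboliteAnnotation] = {}
    edges: list[tuple[str, str, str]] = []
    for _, row in df.iterrows():
        name = row["name"]
        if name in annotations:
            raise ValidationError(f"duplicate annotation for {name!r}")
        annotations[name] = MetaboliteAnnotation(
            name=name,
            chem_class=row["class"],
            carbons=int(row["carbons"]),
            double_bonds=int(row["double_bonds"]),
            unit=row["unit"],
        )
        if row.get("substrate", "") and row.get("product", ""):
            edges.append((row["substrate"], row["product"], row.get("enzyme", "")))
    return MetabolitePanel(annotations=annotations, pathway_edges=edges)


def write_annotations(panel: MetabolitePanel, path: str | Path) -> None:
    path = Path(path)
    edge_by_product = {prod: (sub, enz) for sub, prod, enz in panel.pathway_edges}
    rows = []
    for a in panel.annotations.values():
        sub, enz = edge_by_product.get(a.name, ("", ""))
        rows.append(
            {
                "name": a.name,
                "class": a.chem_class,
                "carbons": a.carbons,
                "double_bonds": a.double_bonds,
                "unit": a.unit,
                "substrate": sub,
                "product": a.name if sub else "",
                "enzyme": enz,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_cohort(path: str | Path, annotation_path: str | Path) -> CohortTable:
    """Read a cohort concentration table with its annotation panel.

    The table is delimited text with a header row and one subject per row.
    ``subject`` and ``group`` columns are reserved; columns matching an
    annotation name are metabolite concentrations, all remaining columns
    are clinical covariates.
    """
    path = Path(path)
    panel = read_annotations(annotation_path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"cohort table missing required column {col!r}")
    df = df.set_index("subject")
    met_cols = [c for c in df.columns if c in panel]
    clin_cols = [c for c in df.columns if c not in panel and c != "group"]
    conc = df[met_cols].copy()
    for col in met_cols:
        try:
            conc[col] = pd.to_numeric(conc[col])
        except (ValueError, TypeError) as exc:
            bad = conc[col][pd.to_numeric(conc[col], errors="coerce").isna()
                            & conc[col].notna()]
            where = f"row {bad.index[0]!r}" if len(bad) else "unknown row"
            raise ValidationError(
                f"unparseable numeric value in column {col!r}, {where}"
            ) from exc
    clinical = df[clin_cols].apply(pd.to_numeric, errors="coerce")
    return CohortTable(
        concentrations=conc.astype(float),
        group=df["group"].astype(str),
        clinical=clinical,
        panel=panel,
    )


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table as delimited text (round-trips with read_cohort)."""
    path = Path(path)
    out = pd.concat(
        [table.group.rename("group"), table.concentrations, table.clinical], axis=1
    )
    out.index.name = "subject"
    out.to_csv(path, sep=_sep_for(path))
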