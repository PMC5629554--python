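"""Curated anticancer-drug catalog: loading, validation, and summary statistics.

The catalog couples three curated tables: one row per FDA-approved drug
(generic name, initial approval year, cytotoxic/targeted category, approved
cancer-class indications, raw target tokens, delivery mode), one row per
protein target (subcellular location, family, subfamily), and one row per
cancer class (full label plus short code).  Target cells mix HGNC gene
symbols with mechanism-of-action phrases such as "DNA synthesis";
:func:`gene_targets` is the single place where mechanism tokens are stripped
so that every downstream count of "protein targets" means the same thing.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Category",
    "Delivery",
    "Location",
    "DrugRecord",
    "TargetAnnotation",
    "CancerClass",
    "Catalog",
    "CatalogSummary",
    "CatalogError",
    "MECHANISM_TOKENS",
    "DEFAULT_PERIODS",
    "parse_target_tokens",
    "gene_targets",
    "load_catalog",
    "summarize_catalog",
    "delivery_correlation",
    "annotation_summary",
    "unique_gene_targets",
    "round_half_up",
]


class CatalogError(ValueError):
    """Raised when an input table violates the catalog schema or invariants."""


class Category(str, enum.Enum):
    """Mechanism-of-action group of a drug."""

    CYTOTOXIC = "cytotoxic"
    TARGETED = "targeted"


class Delivery(str, enum.Enum):
    """How a drug is administered: alone, only in a regimen, or both."""

    SINGLE = "single"
    COMBINATION = "combination"
    BOTH = "both"


class Location(str, enum.Enum):
    """Subcellular location of a protein target."""

    PLASMA_MEMBRANE = "plasma membrane"
    CYTOPLASM = "cytoplasm"
    NUCLEUS = "nucleus"
    EXTRACELLULAR = "extracellular space"


#: Target-cell entries that describe a mode of action rather than a protein
#: target; matched case-insensitively and excluded from gene-level analyses.
MECHANISM_TOKENS = frozenset(
    {"dna synthesis", "rna synthesis", "protein synthesis", "unknown", "biological"}
)

#: Approval-era bins used in the decade summary (closed year intervals).
DEFAULT_PERIODS: tuple[tuple[int, int], ...] = (
    (1941, 1990),
    (1991, 2000),
    (2001, 2010),
    (2011, 2014),
)


@dataclass(frozen=True)
class DrugRecord:
    name: str
    approval_year: int
    category: Category
    indications: tuple[str, ...]
    target_tokens: tuple[str, ...]
    delivery: Delivery


@dataclass(frozen=True)
class TargetAnnotation:
    gene_symbol: str
    location: Location
    family: str
    subfamily: str


@dataclass(frozen=True)
class CancerClass:
    name: str
    abbreviation: str


@dataclass(frozen=True)
class Catalog:
    """A validated drug catalog plus its cancer-class and annotation tables."""

    drugs: tuple[DrugRecord, ...]
    cancers: tuple[CancerClass, ...]
    annotations: tuple[TargetAnnotation, ...] = ()

    def __post_init__(self) -> None:
        names = [d.name for d in self.drugs]
        dup = [n for n, c in Counter(names).items() if c > 1]
        if dup:
            raise CatalogError(f"duplicate drug names: {sorted(dup)}")
        cancer_names = {c.name for c in self.cancers}
        if len(cancer_names) != len(self.cancers):
            raise CatalogError("duplicate cancer-class names")
        abbrs = {c.abbreviation for c in self.cancers}
        if len(abbrs) != len(self.cancers):
            raise CatalogError("duplicate cancer-class abbreviations")
        for d in self.drugs:
            if not d.indications:
                raise CatalogError(f"drug {d.name!r}: empty indication list")
            for ind in d.indications:
                if ind not in cancer_names:
                    raise CatalogError(
                        f"drug {d.name!r}: indication {ind!r} not in cancer table"
                    )
        genes = {a.gene_symbol for a in self.annotations}
        if len(genes) != len(self.annotations):
            raise CatalogError("duplicate gene symbols in annotation table")

    @property
    def targeted_drugs(self) -> tuple[DrugRecord, ...]:
        return tuple(d for d in self.drugs if d.category is Category.TARGETED)

    @property
    def cytotoxic_drugs(self) -> tuple[DrugRecord, ...]:
        return tuple(d for d in self.drugs if d.category is Category.CYTOTOXIC)

    def drug(self, name: str) -> DrugRecord:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)

    def cancer_by_abbreviation(self, abbr: str) -> CancerClass:
        for c in self.cancers:
            if c.abbreviation == abbr:
                return c
        raise KeyError(abbr)


@dataclass(frozen=True)
class CatalogSummary:
    n_total: int
    n_cytotoxic: int
    n_targeted: int
    counts_by_year: Mapping[int, tuple[int, int]]
    counts_by_delivery: Mapping[Delivery, int]
    counts_by_period: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        assert self.n_total == self.n_cytotoxic + self.n_targeted
        assert sum(self.counts_by_delivery.values()) == self.n_total


def parse_target_tokens(raw: str) -> list[str]:
    """Split a printed target cell on ";", trimming whitespace, keeping order."""
    return [tok.strip() for tok in raw.split(";") if tok.strip()]


def gene_targets(record: DrugRecord) -> frozenset[str]:
    """Gene-level targets of a drug: its tokens minus mechanism phrases.

    Fusion targets printed as one token (e.g. ``BCR-ABL``) stay one target.
    """
    return frozenset(
        t for t in record.target_tokens if t.lower() not in MECHANISM_TOKENS
    )


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CatalogError(f"{path}: missing column(s) {missing}")
    return frame


def _parse_enum(kind, raw: str, path, row_label: str):
    try:
        return kind(raw.strip().lower())
    except ValueError:
        allowed = [m.value for m in kind]
        raise CatalogError(
            f"{path}: row {row_label!r}: {raw!r} is not one of {allowed}"
        ) from None


def load_catalog(
    catalog_path: str | Path,
    cancer_path: str | Path,
    annotation_path: str | Path | None = None,
) -> Catalog:
    """Load and validate the drug, cancer-class, and target-annotation tables.

    ``drugs.tsv`` columns: name, approval_year, category, indications,
    targets, delivery (indications/targets ";"-delimited within the cell).
    ``cancers.tsv`` columns: name, abbreviation.
    ``target_annotations.tsv`` columns: gene_symbol, location, family,
    subfamily (optional table).

    Raises
    ------
    CatalogError
        On a missing column, an unknown category/delivery/location value, or
        an indication that does not resolve to a cancer class; the message
        names the offending row.
    """
    cancer_frame = _read_tsv(cancer_path, ["name", "abbreviation"])
    cancers = tuple(
        CancerClass(name=r["name"], abbreviation=r["abbreviation"])
        for r in cancer_frame.to_dict("records")
    )

    drug_frame = _read_tsv(
        catalog_path,
        ["name", "approval_year", "category", "indications", "targets", "delivery"],
    )
    drugs = []
    for r in drug_frame.to_dict("records"):
        name = r["name"].strip()
        try:
            year = int(r["approval_year"])
        except ValueError:
            raise CatalogError(
                f"{catalog_path}: row {name!r}: bad approval_year {r['approval_year']!r}"
            ) from None
        drugs.append(
            DrugRecord(
                name=name,
                approval_year=year,
                category=_parse_enum(Category, r["category"], catalog_path, name),
                indications=tuple(parse_target_tokens(r["indications"])),
                target_tokens=tuple(parse_target_tokens(r["targets"])),
                delivery=_parse_enum(Delivery, r["delivery"], catalog_path, name),
            )
        )

    annotations: tuple[TargetAnnotation, ...] = ()
    if annotation_path is not None:
        ann_frame = _read_tsv(
            annotation_path, ["gene_symbol", "location", "family", "subfamily"]
        )
        annotations = tuple(
            TargetAnnotation(
                gene_symbol=r["gene_symbol"].strip(),
                location=_parse_enum(
                    Location, r["location"], annotation_path, r["gene_symbol"]
                ),
                family=r["family"].strip(),
                subfamily=r["subfamily"].strip(),
            )
            for r in ann_frame.to_dict("records")
        )

    return Catalog(drugs=tuple(drugs), cancers=cancers, annotations=annotations)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), the convention of the
    printed percentages, rather than banker's rounding."""
    factor = 10.0**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) * np.sign(x) / factor)


def summarize_catalog(
    catalog: Catalog,
    periods: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
) -> CatalogSummary:
    """Counts by category, approval year, delivery mode, and approval era."""
    by_year: dict[int, tuple[int, int]] = {}
    for d in catalog.drugs:
        cyt, tar = by_year.get(d.approval_year, (0, 0))
        if d.category is Category.CYTOTOXIC:
            cyt += 1
        else:
            tar += 1
        by_year[d.approval_year] = (cyt, tar)
    by_delivery = {mode: 0 for mode in Delivery}
    for d in catalog.drugs:
        by_delivery[d.delivery] += 1
    by_period = {
        (lo, hi): sum(1 for d in catalog.drugs if lo <= d.approval_year <= hi)
        for lo, hi in periods
    }
    return CatalogSummary(
        n_total=len(catalog.drugs),
        n_cytotoxic=len(catalog.cytotoxic_drugs),
        n_targeted=len(catalog.targeted_drugs),
        counts_by_year=dict(sorted(by_year.items())),
        counts_by_delivery=by_delivery,
        counts_by_period=by_period,
    )


def _annual_series(
    catalog: Catalog, predicate
) -> np.ndarray:
    years = [d.approval_year for d in catalog.drugs]
    lo, hi = min(years), max(years)
    counts = np.zeros(hi - lo + 1, dtype=int)
    for d in catalog.drugs:
        if predicate(d):
            counts[d.approval_year - lo] += 1
    return counts


def delivery_correlation(
    catalog: Catalog, category: Category, delivery_mode: Delivery
) -> tuple[float, float]:
    """Pearson correlation between two annual approval-count series.

    One series counts drugs of ``category`` per calendar year, the other
    counts drugs with ``delivery_mode``; both cover every year from the
    earliest to the latest approval in the catalog, zero-filled for years
    without approvals.  Returns (r, two-sided p from the t transform).

    Raises
    ------
    CatalogError
        If the catalog spans fewer than 3 distinct years or either series is
        constant (the correlation is undefined).
    """
    category = Category(category)
    delivery_mode = Delivery(delivery_mode)
    if len({d.approval_year for d in catalog.drugs}) < 3:
        raise CatalogError("delivery_correlation needs >= 3 distinct approval years")
    a = _annual_series(catalog, lambda d: d.category is category)
    b = _annual_series(catalog, lambda d: d.delivery is delivery_mode)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise CatalogError("constant annual series: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def annotation_summary(
    annotations: Iterable[TargetAnnotation],
) -> dict[str, dict[str, tuple[int, int]]]:
    """Counts and whole-number percentages by location, family, subfamily.

    Returns ``{"location"|"family"|"subfamily": {label: (count, pct)}}``
    where pct is the percentage of all annotated targets rounded half-up.
    """
    annotations = list(annotations)
    if not annotations:
        raise CatalogError("annotation_summary needs a non-empty annotation set")
    total = len(annotations)
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for axis, key in (
        ("location", lambda a: a.location.value),
        ("family", lambda a: a.family),
        ("subfamily", lambda a: a.subfamily),
    ):
        counts = Counter(key(a) for a in annotations)
        out[axis] = {
            label: (n, int(round_half_up(100.0 * n / total)))
            for label, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        }
    return out


def unique_gene_targets(catalog: Catalog, category: Category | None = Category.TARGETED) -> frozenset[str]:
    """Union of gene-level targets, by default over targeted drugs only."""
    drugs = catalog.drugs if category is None else tuple(
        d for d in catalog.drugs if d.category is category
    )
    out: set[str] = set()
    for d in drugs:
        out |= gene_targets(d)
    return frozenset(out)
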