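"""Genetic characterisation of drug targets against cancer-gene sets.

Given the gene-level drug targets, a cancer-gene list (a Cancer Gene
Census-style input), and a long-form somatic-mutation table, this module

* partitions genes into four disjoint sets — targets that are cancer genes,
  targets only, cancer genes only (with mutation data), and all remaining
  genes with mutation data;
* tests the target/cancer-gene overlap with an upper-tail hypergeometric
  probability against the protein-coding background;
* computes per-gene mutation frequencies (percent of study samples with at
  least one qualifying mutation) and compares the per-gene frequency
  distributions of gene sets with two-sample K-S tests;
* compares the fraction of genes mutated above a frequency threshold
  between sets with 2x2 chi-squared tests; and
* correlates per-gene mutation frequency with the number of drugs
  targeting the gene.

The mutation-frequency denominator is the total number of study samples
(declared in the table header), not the number of samples that happen to
carry a mutation, so genes absent from a cohort dilute correctly.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats_util import KSResult, ks_test

__all__ = [
    "VariantClass",
    "MutationRecord",
    "MutationTable",
    "GeneSetPartition",
    "FrequencyProfile",
    "partition_gene_sets",
    "hypergeometric_enrichment",
    "mutation_frequency",
    "compare_frequency_sets",
    "threshold_fraction",
    "drug_count_correlation",
    "list_overlap",
    "load_mutations",
    "load_gene_list",
]


class VariantClass(str, enum.Enum):
    """The seven somatic variant classes retained for frequency statistics."""

    MISSENSE = "missense"
    SILENT = "silent"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    READTHROUGH = "readthrough"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"


ALL_VARIANT_CLASSES = frozenset(VariantClass)


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_symbol: str
    variant_class: VariantClass
    cohort: str

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene_symbol:
            raise ValueError("mutation record needs non-empty identifiers")


@dataclass(frozen=True)
class MutationTable:
    """Long-form somatic mutations plus the total study-sample count.

    ``n_samples`` may exceed the number of distinct samples carrying any
    mutation; it is the denominator of every frequency.
    """

    records: tuple[MutationRecord, ...]
    n_samples: int

    def __post_init__(self) -> None:
        observed = len({r.sample_id for r in self.records})
        if self.n_samples < observed:
            raise ValueError(
                f"n_samples={self.n_samples} < {observed} distinct sample ids"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene_symbol for r in self.records)


@dataclass(frozen=True)
class GeneSetPartition:
    target_cancer: frozenset[str]
    target_only: frozenset[str]
    cancer_only: frozenset[str]
    other: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.target_cancer, self.target_only, self.cancer_only, self.other]
        for a, b in itertools.combinations(sets, 2):
            if a & b:
                raise ValueError("partition sets must be pairwise disjoint")

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "target_cancer": self.target_cancer,
            "target_only": self.target_only,
            "cancer_only": self.cancer_only,
            "other": self.other,
        }


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-gene mutation percentages (0-100) and their set mean."""

    per_gene: Mapping[str, float]
    set_mean: float

    def values(self) -> np.ndarray:
        return np.array(list(self.per_gene.values()), dtype=float)


def partition_gene_sets(
    targets: Iterable[str],
    cancer_genes: Iterable[str],
    genes_with_data: Iterable[str],
) -> GeneSetPartition:
    """Four-way split of the gene universe.

    target_cancer = targets ∩ cancer_genes; target_only = targets minus
    cancer genes; cancer_only = cancer genes with mutation data that are not
    targets; other = genes with mutation data in none of the above.
    """
    targets = frozenset(targets)
    cancer = frozenset(cancer_genes)
    data = frozenset(genes_with_data)
    target_cancer = targets & cancer
    target_only = targets - cancer
    cancer_only = (cancer - targets) & data
    other = data - targets - cancer
    return GeneSetPartition(target_cancer, target_only, cancer_only, other)


def hypergeometric_enrichment(
    k_overlap: int, n_sample: int, K_category: int, N_population: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members in a draw of ``n_sample`` from a population of
    ``N_population`` containing ``K_category`` category members.
    """
    if not (0 <= k_overlap <= min(n_sample, K_category)):
        raise ValueError("need 0 <= k <= min(n, K)")
    if n_sample > N_population or K_category > N_population:
        raise ValueError("need n <= N and K <= N")
    return float(stats.hypergeom.sf(k_overlap - 1, N_population, K_category, n_sample))


def load_gene_list(path: str | Path) -> frozenset[str]:
    """One symbol per line; '#' starts a comment; blank lines ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.add(sym)
    return frozenset(out)


def load_mutations(path: str | Path, n_samples: int | None = None) -> MutationTable:
    """Read a MAF-like TSV: sample_id, gene_symbol, variant_class, cohort.

    An optional leading directive line ``#n_samples=<int>`` declares the
    total study-sample count; otherwise ``n_samples`` must be passed or the
    count of distinct sample ids is used.
    """
    path = Path(path)
    header_n = None
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#n_samples="):
        header_n = int(first.strip().split("=", 1)[1])
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("sample_id", "gene_symbol", "variant_class", "cohort"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    records = tuple(
        MutationRecord(
            sample_id=r["sample_id"],
            gene_symbol=r["gene_symbol"],
            variant_class=VariantClass(r["variant_class"]),
            cohort=r["cohort"],
        )
        for r in frame.to_dict("records")
    )
    total = n_samples if n_samples is not None else header_n
    if total is None:
        total = len({r.sample_id for r in records})
    return MutationTable(records=records, n_samples=total)


def mutation_frequency(
    table: MutationTable,
    genes: Iterable[str],
    include_classes: Iterable[VariantClass] = ALL_VARIANT_CLASSES,
    cohort: str | None = None,
) -> FrequencyProfile:
    """Percent of study samples with >=1 qualifying mutation, per gene.

    Duplicate records of the same (sample, gene) count once.  Genes absent
    from the table get 0%.  ``cohort`` restricts both the records and the
    denominator interpretation is left to the caller (the default uses the
    full study denominator).
    """
    include = frozenset(VariantClass(c) for c in include_classes)
    if not include:
        raise ValueError("include_classes must be non-empty")
    if table.n_samples <= 0:
        raise ValueError("table has no samples")
    genes = sorted(set(genes))
    mutated: dict[str, set[str]] = {g: set() for g in genes}
    wanted = set(genes)
    for rec in table.records:
        if rec.gene_symbol in wanted and rec.variant_class in include:
            if cohort is None or rec.cohort == cohort:
                mutated[rec.gene_symbol].add(rec.sample_id)
    per_gene = {
        g: 100.0 * len(samples) / table.n_samples for g, samples in mutated.items()
    }
    mean = float(np.mean(list(per_gene.values()))) if per_gene else 0.0
    return FrequencyProfile(per_gene=per_gene, set_mean=mean)


def compare_frequency_sets(
    profiles: Mapping[str, FrequencyProfile],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise comparison of per-gene frequency distributions.

    Returns a DataFrame with one row per unordered pair: set names, set
    means, and the two-sample K-S p-value on the per-gene frequency vectors.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    for name, prof in profiles.items():
        if not prof.per_gene:
            raise ValueError(f"profile {name!r} is empty")
    rows = []
    for (name_a, prof_a), (name_b, prof_b) in itertools.combinations(
        profiles.items(), 2
    ):
        res: KSResult = ks_test(prof_a.values(), prof_b.values(), alternative)
        rows.append(
            {
                "set_a": name_a,
                "set_b": name_b,
                "mean_a": prof_a.set_mean,
                "mean_b": prof_b.set_mean,
                "ks_statistic": res.statistic,
                "ks_p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def threshold_fraction(
    profiles: Mapping[str, FrequencyProfile],
    threshold_pct: float = 2.0,
    continuity_correction: bool = False,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-set fraction of genes with frequency >= threshold, plus pairwise
    2x2 chi-squared tests (gene above threshold yes/no x set membership)."""
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold must be a percentage in [0, 100]")
    fractions: dict[str, float] = {}
    above: dict[str, int] = {}
    totals: dict[str, int] = {}
    for name, prof in profiles.items():
        vals = prof.values()
        above[name] = int((vals >= threshold_pct).sum())
        totals[name] = int(vals.size)
        fractions[name] = above[name] / vals.size if vals.size else float("nan")
    rows = []
    for name_a, name_b in itertools.combinations(profiles, 2):
        contingency = np.array(
            [
                [above[name_a], totals[name_a] - above[name_a]],
                [above[name_b], totals[name_b] - above[name_b]],
            ]
        )
        if contingency.sum(axis=0).min() == 0:
            stat, p = float("nan"), float("nan")
        else:
            stat, p, _, _ = stats.chi2_contingency(
                contingency, correction=continuity_correction
            )
        rows.append(
            {
                "set_a": name_a,
                "set_b": name_b,
                "fraction_a": fractions[name_a],
                "fraction_b": fractions[name_b],
                "chi2": float(stat),
                "chi2_p": float(p),
            }
        )
    return fractions, pd.DataFrame(rows)


def drug_count_correlation(
    genes: Iterable[str],
    per_gene_frequency: Mapping[str, float],
    drugs_per_gene: Mapping[str, int],
) -> tuple[float, float]:
    """Pearson correlation between mutation frequency and targeting-drug
    count over a gene set; (r, two-sided p)."""
    genes = sorted(set(genes))
    if len(genes) < 3:
        raise ValueError("need >= 3 genes")
    freq = np.array([per_gene_frequency.get(g, 0.0) for g in genes])
    counts = np.array([drugs_per_gene.get(g, 0) for g in genes], dtype=float)
    if np.ptp(freq) == 0 or np.ptp(counts) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(freq, counts)
    return float(r), float(p)


def list_overlap(genes: Iterable[str], reference: Iterable[str]) -> tuple[frozenset[str], int]:
    """Intersection of a gene set with a reference list, and its size."""
    overlap = frozenset(genes) & frozenset(reference)
    return overlap, len(overlap)
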