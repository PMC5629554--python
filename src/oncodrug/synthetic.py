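"""Synthetic catalogs, mutation tables, and trial tables with known truth.

Every generator takes an explicit integer seed and drives a single
:class:`numpy.random.Generator`; identical spec + seed gives identical
output on any platform.  Entity names are deterministic templates
(``DRUG0001``, ``GENE0001``, ``CANCER01``) so serialized fixtures diff
cleanly.

Defaults mirror the curated study's scale: 150 drugs over 33 cancer classes
(about 59% targeted), approval years 1949–2014, right-skewed (shifted
geometric) indication and target counts, and a 3268-sample mutation table
whose per-set per-gene mutation rates are the four observed set means
(2.41 / 1.19 / 1.85 / 0.97 percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .catalog import Catalog, CancerClass, Category, Delivery, DrugRecord
from .genetics import MutationRecord, MutationTable, VariantClass
from .repurposing import Prediction

__all__ = [
    "CatalogSpec",
    "MutationSpec",
    "generate_catalog",
    "generate_mutation_table",
    "generate_trial_counts",
    "DEFAULT_COHORTS",
]

#: Cohort codes of the 12-cancer pan-cancer study the mutation generator emulates.
DEFAULT_COHORTS: tuple[str, ...] = (
    "BLCA", "BRCA", "COAD/READ", "GBM", "HNSC", "KIRC",
    "LAML", "LUAD", "LUSC", "OV", "UCEC", "KIRP",
)

#: Mechanism-of-action phrases sprinkled into cytotoxic target cells so that
#: synthetic catalogs exercise the mechanism-token filtering.
_MECHANISM_POOL = ("DNA synthesis", "RNA synthesis", "Unknown")


@dataclass(frozen=True)
class CatalogSpec:
    """Parameters of a synthetic drug catalog.

    ``targets_per_drug`` / ``indications_per_drug`` are (name, params)
    distribution specs; supported names: ``"geometric"`` (shifted, support
    >= 1, params {"p": ...}) and ``"constant"`` (params {"value": ...}).
    """

    n_drugs: int = 150
    n_targets: int = 102
    n_cancers: int = 33
    p_targeted: float = 89 / 150
    targets_per_drug: tuple[str, dict] = ("geometric", {"p": 0.5})
    indications_per_drug: tuple[str, dict] = ("geometric", {"p": 0.6})
    year_range: tuple[int, int] = (1949, 2014)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_targeted <= 1.0:
            raise ValueError("p_targeted must be in [0, 1]")
        if min(self.n_drugs, self.n_targets, self.n_cancers) < 1:
            raise ValueError("counts must be >= 1")
        name, params = self.indications_per_drug
        if name == "constant" and not 1 <= params["value"] <= self.n_cancers:
            raise ValueError("indications_per_drug must be within [1, n_cancers]")


@dataclass(frozen=True)
class MutationSpec:
    """Parameters of a synthetic somatic-mutation table.

    ``set_rates`` maps gene-set names to the per-sample probability that a
    given gene of the set is mutated; ``genes_per_set`` gives each set's
    size.  Set names follow the four-way partition roles.
    """

    n_samples: int = 3268
    set_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "target_cancer": 0.0241,
            "target_only": 0.0119,
            "cancer_only": 0.0185,
            "other": 0.0097,
        }
    )
    genes_per_set: Mapping[str, int] = field(
        default_factory=lambda: {
            "target_cancer": 32,
            "target_only": 70,
            "cancer_only": 537,
            "other": 2000,
        }
    )
    cohorts: tuple[str, ...] = DEFAULT_COHORTS
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in self.set_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {name!r} must be in [0, 1]")
        if set(self.set_rates) != set(self.genes_per_set):
            raise ValueError("set_rates and genes_per_set must share keys")


def _draw_count(rng: np.random.Generator, dist: tuple[str, dict], cap: int) -> int:
    name, params = dist
    if name == "constant":
        value = int(params["value"])
    elif name == "geometric":
        value = int(rng.geometric(params["p"]))  # support >= 1, right-skewed
    else:
        raise ValueError(f"unknown distribution {name!r}")
    return max(1, min(value, cap))


def generate_catalog(spec: CatalogSpec) -> Catalog:
    """A valid random catalog: passes all catalog invariants, reproducible."""
    rng = np.random.default_rng(spec.seed)
    cancers = tuple(
        CancerClass(name=f"CANCER{i:02d}", abbreviation=f"C{i:02d}")
        for i in range(1, spec.n_cancers + 1)
    )
    gene_pool = [f"GENE{i:04d}" for i in range(1, spec.n_targets + 1)]
    cancer_names = [c.name for c in cancers]
    lo, hi = spec.year_range

    drugs = []
    for i in range(1, spec.n_drugs + 1):
        targeted = rng.random() < spec.p_targeted
        n_ind = _draw_count(rng, spec.indications_per_drug, spec.n_cancers)
        indications = tuple(
            sorted(rng.choice(cancer_names, size=n_ind, replace=False).tolist())
        )
        if targeted:
            n_tgt = _draw_count(rng, spec.targets_per_drug, spec.n_targets)
            tokens = tuple(
                sorted(rng.choice(gene_pool, size=n_tgt, replace=False).tolist())
            )
        else:
            # cytotoxic cells mix mechanism phrases with occasional genes
            tokens = (str(rng.choice(_MECHANISM_POOL)),)
            if rng.random() < 0.3:
                tokens += (str(rng.choice(gene_pool)),)
        drugs.append(
            DrugRecord(
                name=f"DRUG{i:04d}",
                approval_year=int(rng.integers(lo, hi + 1)),
                category=Category.TARGETED if targeted else Category.CYTOTOXIC,
                indications=indications,
                target_tokens=tokens,
                delivery=Delivery(
                    str(rng.choice(["single", "combination", "both"], p=[0.6, 0.2, 0.2]))
                ),
            )
        )
    return Catalog(drugs=tuple(drugs), cancers=cancers)


def generate_mutation_table(
    spec: MutationSpec,
) -> tuple[MutationTable, dict[str, float]]:
    """Synthetic long-form mutation table plus the planted per-gene rates.

    For each gene, the number of mutated samples is Binomial(n_samples,
    rate) — distributionally identical to an independent Bernoulli draw per
    sample — and that many distinct samples receive one record each, with a
    uniformly drawn variant class and cohort.  Genes are named
    ``<SET>_GENE####``; the returned truth map gives each gene's rate.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"SAMPLE{i:05d}" for i in range(1, spec.n_samples + 1)]
    classes = [c.value for c in VariantClass]
    records: list[MutationRecord] = []
    truth: dict[str, float] = {}
    for set_name in sorted(spec.set_rates):
        rate = spec.set_rates[set_name]
        for j in range(1, spec.genes_per_set[set_name] + 1):
            gene = f"{set_name.upper()}_GENE{j:04d}"
            truth[gene] = rate
            n_mut = int(rng.binomial(spec.n_samples, rate))
            if n_mut == 0:
                continue
            carriers = rng.choice(sample_ids, size=n_mut, replace=False)
            for sample in carriers:
                records.append(
                    MutationRecord(
                        sample_id=str(sample),
                        gene_symbol=gene,
                        variant_class=VariantClass(str(rng.choice(classes))),
                        cohort=str(rng.choice(spec.cohorts)),
                    )
                )
    return MutationTable(records=tuple(records), n_samples=spec.n_samples), truth


def generate_trial_counts(
    predictions: Iterable[Prediction],
    p_supported: float = 116 / 133,
    count_distribution: tuple[str, dict] = ("geometric", {"p": 0.15}),
    seed: int = 0,
) -> dict[tuple[str, str], int]:
    """Random trial-count annotation: each prediction gets 0 trials with
    probability 1 - p_supported, otherwise a positive draw."""
    if not 0.0 <= p_supported <= 1.0:
        raise ValueError("p_supported must be in [0, 1]")
    rng = np.random.default_rng(seed)
    name, params = count_distribution
    table: dict[tuple[str, str], int] = {}
    for pred in sorted(predictions, key=lambda p: (p.drug, p.cancer)):
        if rng.random() >= p_supported:
            table[(pred.drug, pred.cancer)] = 0
        elif name == "geometric":
            table[(pred.drug, pred.cancer)] = int(rng.geometric(params["p"]))
        elif name == "constant":
            table[(pred.drug, pred.cancer)] = int(params["value"])
        else:
            raise ValueError(f"unknown distribution {name!r}")
    return table


def write_catalog_tsvs(catalog: Catalog, outdir) -> dict[str, str]:
    """Serialize a catalog in the same TSV schemas the loaders read."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drug_lines = ["name\tapproval_year\tcategory\tindications\ttargets\tdelivery"]
    for d in catalog.drugs:
        drug_lines.append(
            "\t".join(
                [
                    d.name,
                    str(d.approval_year),
                    d.category.value,
                    ";".join(d.indications),
                    ";".join(d.target_tokens),
                    d.delivery.value,
                ]
            )
        )
    cancer_lines = ["name\tabbreviation"] + [
        f"{c.name}\t{c.abbreviation}" for c in catalog.cancers
    ]
    paths = {
        "drugs": str(outdir / "drugs.tsv"),
        "cancers": str(outdir / "cancers.tsv"),
    }
    Path(paths["drugs"]).write_text("\n".join(drug_lines) + "\n")
    Path(paths["cancers"]).write_text("\n".join(cancer_lines) + "\n")
    return paths


def write_mutation_tsv(table: MutationTable, path) -> str:
    from pathlib import Path

    lines = [f"#n_samples={table.n_samples}", "sample_id\tgene_symbol\tvariant_class\tcohort"]
    for r in table.records:
        lines.append(f"{r.sample_id}\t{r.gene_symbol}\t{r.variant_class.value}\t{r.cohort}")
    Path(path).write_text("\n".join(lines) + "\n")
    return str(path)
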