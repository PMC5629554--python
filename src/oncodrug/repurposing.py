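"""Common-target ("guilt-by-association") drug repurposing.

If two targeted drugs share at least one gene-level target, each approved
indication of one is proposed as a candidate indication of the other unless
the pair is already approved.  Proposals are deduplicated on (drug, cancer)
with the supporting shared targets and source drugs merged.  Cytotoxic drugs
never participate: mechanism phrases such as "DNA synthesis" are not
targets, so sharing one creates no link.

Candidate pairs are then annotated with clinical-trial counts from a
transcribed trial table and tallied into supported (>=1 trial) versus
unsupported associations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .catalog import Catalog, gene_targets

__all__ = [
    "Prediction",
    "PredictionReport",
    "shared_target_index",
    "drugs_sharing_targets",
    "predict_common_target",
    "brute_force_predict",
    "evaluate_support",
    "load_trial_counts",
    "write_predictions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Prediction:
    """One proposed novel drug–cancer association."""

    drug: str
    cancer: str
    shared_targets: frozenset[str]
    source_drugs: frozenset[str]
    trial_count: int | None = None

    def __post_init__(self) -> None:
        if not self.shared_targets or not self.source_drugs:
            raise ValueError("prediction needs >=1 shared target and source drug")


@dataclass(frozen=True)
class PredictionReport:
    predictions: tuple[Prediction, ...]
    n_predictions: int
    n_drugs: int
    n_cancers: int
    n_supported: int
    n_unsupported: int
    top_association: Prediction | None
    #: trial-table pairs that are not predictions (e.g. already-approved
    #: pairs), exposed for inspection rather than silently dropped
    unmatched_trial_pairs: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        assert self.n_supported + self.n_unsupported == self.n_predictions


def shared_target_index(catalog: Catalog) -> dict[str, frozenset[str]]:
    """Map each gene-level target to the set of targeted drugs hitting it."""
    index: dict[str, set[str]] = {}
    for drug in catalog.targeted_drugs:
        for gene in gene_targets(drug):
            index.setdefault(gene, set()).add(drug.name)
    return {g: frozenset(ds) for g, ds in index.items()}


def drugs_sharing_targets(catalog: Catalog) -> frozenset[str]:
    """Targeted drugs whose gene-target set intersects another drug's."""
    index = shared_target_index(catalog)
    return frozenset(
        name for drugs in index.values() if len(drugs) > 1 for name in drugs
    )


def predict_common_target(catalog: Catalog) -> frozenset[Prediction]:
    """All novel (drug, cancer) candidates from shared-target transfer.

    For every ordered pair (A, B) of distinct targeted drugs with
    overlapping gene targets and every indication D of B with (A, D) not
    approved, A–D is proposed.  Duplicates are merged on (drug, cancer),
    pooling shared targets and source drugs.
    """
    targeted = catalog.targeted_drugs
    genes = {d.name: gene_targets(d) for d in targeted}
    indications = {d.name: d.indications for d in targeted}
    approved = {(d.name, ind) for d in catalog.drugs for ind in d.indications}

    index = shared_target_index(catalog)
    partners: dict[str, set[str]] = {d.name: set() for d in targeted}
    for drugs in index.values():
        for name in drugs:
            partners[name] |= drugs - {name}

    merged: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for a in targeted:
        for b_name in partners[a.name]:
            shared = genes[a.name] & genes[b_name]
            for cancer in indications[b_name]:
                if (a.name, cancer) in approved:
                    continue
                targets_acc, sources_acc = merged.setdefault(
                    (a.name, cancer), (set(), set())
                )
                targets_acc |= shared
                sources_acc |= {b_name}
    return frozenset(
        Prediction(
            drug=drug,
            cancer=cancer,
            shared_targets=frozenset(t),
            source_drugs=frozenset(s),
        )
        for (drug, cancer), (t, s) in merged.items()
    )


def brute_force_predict(catalog: Catalog) -> frozenset[tuple[str, str]]:
    """Oracle: exhaustive triple loop over drug pairs and indications, with
    plain set-membership checks and no indexing shortcuts."""
    if len(catalog.drugs) > 200:
        raise ValueError("brute_force_predict is an oracle for catalogs <= 200 drugs")
    approved = {(d.name, ind) for d in catalog.drugs for ind in d.indications}
    targeted = catalog.targeted_drugs
    out: set[tuple[str, str]] = set()
    for a in targeted:
        for b in targeted:
            if a.name == b.name:
                continue
            if not (gene_targets(a) & gene_targets(b)):
                continue
            for cancer in b.indications:
                if (a.name, cancer) not in approved:
                    out.add((a.name, cancer))
    return frozenset(out)


def load_trial_counts(
    path: str | Path, catalog: Catalog
) -> dict[tuple[str, str], int]:
    """Read ``trial_counts.tsv`` (drug, cancer_abbreviation, n_trials).

    Cancer abbreviations resolve through the catalog's cancer table.  Drug
    names resolve case-insensitively, falling back to a unique prefix match
    so that short generic names (e.g. "Sorafenib") find their full catalog
    entries ("Sorafenib tosylate").
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug", "cancer_abbreviation", "n_trials"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    by_lower = {d.name.lower(): d.name for d in catalog.drugs}
    names = sorted(by_lower)

    def resolve_drug(raw: str) -> str:
        key = raw.strip().lower()
        if key in by_lower:
            return by_lower[key]
        hits = [n for n in names if n.startswith(key)]
        if len(hits) == 1:
            return by_lower[hits[0]]
        raise ValueError(f"{path}: cannot resolve drug name {raw!r} (hits: {hits})")

    table: dict[tuple[str, str], int] = {}
    for row in frame.to_dict("records"):
        drug = resolve_drug(row["drug"])
        cancer = catalog.cancer_by_abbreviation(row["cancer_abbreviation"].strip()).name
        count = int(row["n_trials"])
        if count < 0:
            raise ValueError(f"{path}: negative trial count for {drug!r}/{cancer!r}")
        table[(drug, cancer)] = table.get((drug, cancer), 0) + count
    return table


def evaluate_support(
    predictions: Iterable[Prediction],
    trial_table: Mapping[tuple[str, str], int],
) -> PredictionReport:
    """Attach trial counts to predictions and tally support.

    A prediction absent from the table gets 0 trials with a warning; table
    pairs that are not predictions are reported in
    ``unmatched_trial_pairs`` for inspection.
    """
    annotated: list[Prediction] = []
    missing: list[tuple[str, str]] = []
    for pred in sorted(predictions, key=lambda p: (p.drug, p.cancer)):
        key = (pred.drug, pred.cancer)
        if key not in trial_table:
            missing.append(key)
        count = int(trial_table.get(key, 0))
        annotated.append(
            Prediction(
                drug=pred.drug,
                cancer=pred.cancer,
                shared_targets=pred.shared_targets,
                source_drugs=pred.source_drugs,
                trial_count=count,
            )
        )
    if missing and trial_table:
        msg = f"{len(missing)} prediction(s) missing from trial table, counted as 0: {missing}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    predicted_pairs = {(p.drug, p.cancer) for p in annotated}
    unmatched = tuple(
        sorted(
            (drug, cancer, count)
            for (drug, cancer), count in trial_table.items()
            if (drug, cancer) not in predicted_pairs
        )
    )
    supported = [p for p in annotated if p.trial_count and p.trial_count >= 1]
    top = max(annotated, key=lambda p: p.trial_count or 0, default=None)
    return PredictionReport(
        predictions=tuple(annotated),
        n_predictions=len(annotated),
        n_drugs=len({p.drug for p in annotated}),
        n_cancers=len({p.cancer for p in annotated}),
        n_supported=len(supported),
        n_unsupported=len(annotated) - len(supported),
        top_association=top,
        unmatched_trial_pairs=unmatched,
    )


def write_predictions(predictions: Iterable[Prediction], path: str | Path) -> Path:
    """Write predictions as TSV: drug, cancer, shared_targets, source_drugs,
    n_trials (empty when unannotated)."""
    path = Path(path)
    rows = []
    for p in sorted(predictions, key=lambda p: (-(p.trial_count or 0), p.drug, p.cancer)):
        rows.append(
            {
                "drug": p.drug,
                "cancer": p.cancer,
                "shared_targets": ";".join(sorted(p.shared_targets)),
                "source_drugs": ";".join(sorted(p.source_drugs)),
                "n_trials": "" if p.trial_count is None else p.trial_count,
            }
        )
    pd.DataFrame(
        rows, columns=["drug", "cancer", "shared_targets", "source_drugs", "n_trials"]
    ).to_csv(path, sep="\t", index=False)
    return path
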