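"""Access to the packaged curated tables.

Four TSVs ship with the package: the 150-drug catalog, the 33 cancer
classes, the 102 target annotations, and the 133-pair clinical-trial table.
The drug, cancer, and trial tables are verbatim transcriptions of the
published curation; the per-gene annotation table is a reconstruction whose
location/family/subfamily marginal counts match the published
classification exactly (the publication reports only the category counts,
not per-gene assignments).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .catalog import Catalog, load_catalog
from .repurposing import load_trial_counts

__all__ = [
    "fixture_path",
    "load_packaged_catalog",
    "load_packaged_trial_counts",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file (e.g. ``"drugs.tsv"``)."""
    with resources.as_file(resources.files("oncodrug") / "data" / name) as p:
        return Path(p)


def load_packaged_catalog() -> Catalog:
    """The validated 150-drug catalog with annotations."""
    return load_catalog(
        fixture_path("drugs.tsv"),
        fixture_path("cancers.tsv"),
        fixture_path("target_annotations.tsv"),
    )


def load_packaged_trial_counts(catalog: Catalog | None = None) -> dict[tuple[str, str], int]:
    """The transcribed trial-count table keyed by (drug name, cancer name)."""
    if catalog is None:
        catalog = load_packaged_catalog()
    return load_trial_counts(fixture_path("trial_counts.tsv"), catalog)
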