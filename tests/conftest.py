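import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from oncodrug import (
    CancerClass,
    Catalog,
    Category,
    Delivery,
    DrugRecord,
    load_packaged_catalog,
    load_packaged_trial_counts,
)


@pytest.fixture(scope="session")
def catalog():
    """The packaged 150-drug catalog with cancer classes and annotations."""
    return load_packaged_catalog()


@pytest.fixture(scope="session")
def trial_table(catalog):
    return load_packaged_trial_counts(catalog)


def make_drug(
    name,
    year=2000,
    category=Category.TARGETED,
    indications=("CANCER01",),
    targets=("GENE0001",),
    delivery=Delivery.SINGLE,
):
    return DrugRecord(
        name=name,
        approval_year=year,
        category=Category(category),
        indications=tuple(indications),
        target_tokens=tuple(targets),
        delivery=Delivery(delivery),
    )


def make_catalog(drugs, n_cancers=5):
    cancers = tuple(
        CancerClass(name=f"CANCER{i:02d}", abbreviation=f"C{i:02d}")
        for i in range(1, n_cancers + 1)
    )
    return Catalog(drugs=tuple(drugs), cancers=cancers)


@pytest.fixture
def toy_catalog():
    """Two targeted drugs sharing a target plus one cytotoxic drug."""
    return make_catalog(
        [
            make_drug("A", 1995, indications=("CANCER01",), targets=("GENE0001", "GENE0002")),
            make_drug("B", 2005, indications=("CANCER02",), targets=("GENE0001",)),
            make_drug(
                "C",
                2010,
                category=Category.CYTOTOXIC,
                indications=("CANCER01", "CANCER03"),
                targets=("DNA synthesis",),
                delivery=Delivery.COMBINATION,
            ),
        ]
    )
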