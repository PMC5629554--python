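"""Gene-set partition, enrichment, and mutation-frequency statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oncodrug import (
    FrequencyProfile,
    MutationRecord,
    MutationTable,
    MutationSpec,
    VariantClass,
    compare_frequency_sets,
    drug_count_correlation,
    generate_mutation_table,
    hypergeometric_enrichment,
    list_overlap,
    load_mutations,
    mutation_frequency,
    partition_gene_sets,
    threshold_fraction,
)
from oncodrug.genetics import ALL_VARIANT_CLASSES
from oncodrug.synthetic import write_mutation_tsv

GENE = st.sampled_from([f"G{i}" for i in range(30)])


@settings(max_examples=50, deadline=None)
@given(
    targets=st.frozensets(GENE, max_size=15),
    cancer=st.frozensets(GENE, max_size=15),
    data=st.frozensets(GENE, max_size=25),
)
def test_partition_matches_set_algebra(targets, cancer, data):
    part = partition_gene_sets(targets, cancer, data)
    assert part.target_cancer == targets & cancer
    assert part.target_only == targets - cancer
    assert part.cancer_only == (cancer - targets) & data
    assert part.other == data - targets - cancer
    sets = [part.target_cancer, part.target_only, part.cancer_only, part.other]
    assert sum(map(len, sets)) == len(frozenset().union(*sets))
    # targets always land in the first two sets
    assert targets == part.target_cancer | part.target_only


def test_partition_disjoint_inputs():
    part = partition_gene_sets({"A"}, {"B"}, {"A", "B", "C"})
    assert part.target_cancer == frozenset()
    assert part.target_only == {"A"}
    assert part.cancer_only == {"B"}
    assert part.other == {"C"}


def test_partition_reproduces_published_study_sizes():
    # universe shaped like the curated study: 102 targets of which 32 are
    # cancer genes, a 594-gene census with 537 non-target members carrying
    # mutation data, and 20,308 remaining genes with data
    targets = {f"T{i}" for i in range(70)} | {f"TC{i}" for i in range(32)}
    census = {f"TC{i}" for i in range(32)} | {f"C{i}" for i in range(562)}
    data = (
        targets
        | {f"C{i}" for i in range(537)}  # 25 census genes lack mutation data
        | {f"O{i}" for i in range(20308)}
    )
    part = partition_gene_sets(targets, census, data)
    sizes = {k: len(v) for k, v in part.as_dict().items()}
    assert sizes == {
        "target_cancer": 32,
        "target_only": 70,
        "cancer_only": 537,
        "other": 20308,
    }


def _hypergeom_brute(k, n, K, N):
    """P(X >= k) by exhaustive summation of the mass function."""
    total = 0.0
    for i in range(k, min(n, K) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


def test_hypergeometric_small_case_oracle():
    assert hypergeometric_enrichment(2, 3, 4, 10) == pytest.approx(
        _hypergeom_brute(2, 3, 4, 10), rel=1e-12
    )


def test_hypergeometric_zero_overlap_is_one():
    assert hypergeometric_enrichment(0, 10, 5, 100) == 1.0


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_hypergeometric_matches_exhaustive_sum(data):
    N = data.draw(st.integers(2, 50))
    K = data.draw(st.integers(1, N))
    n = data.draw(st.integers(1, N))
    k = data.draw(st.integers(0, min(n, K)))
    assert hypergeometric_enrichment(k, n, K, N) == pytest.approx(
        _hypergeom_brute(k, n, K, N), rel=1e-10
    )


def test_hypergeometric_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeometric_enrichment(5, 3, 10, 100)
    with pytest.raises(ValueError):
        hypergeometric_enrichment(1, 3, 200, 100)


def _toy_table():
    recs = [
        MutationRecord("S1", "G", VariantClass.MISSENSE, "BRCA"),
        MutationRecord("S2", "G", VariantClass.SILENT, "GBM"),
        MutationRecord("S2", "G", VariantClass.MISSENSE, "GBM"),  # same sample twice
        MutationRecord("S1", "H", VariantClass.NONSENSE, "BRCA"),
    ]
    return MutationTable(records=tuple(recs), n_samples=3)


def test_mutation_frequency_toy_counts():
    prof = mutation_frequency(_toy_table(), {"G", "H", "ABSENT"})
    assert prof.per_gene["G"] == pytest.approx(200 / 3)
    assert prof.per_gene["H"] == pytest.approx(100 / 3)
    assert prof.per_gene["ABSENT"] == 0.0


def test_mutation_frequency_duplicate_records_count_once():
    prof = mutation_frequency(_toy_table(), {"G"})
    doubled = MutationTable(records=_toy_table().records * 2, n_samples=3)
    assert mutation_frequency(doubled, {"G"}).per_gene == prof.per_gene


def test_mutation_frequency_class_filter():
    prof = mutation_frequency(
        _toy_table(), {"G"}, include_classes=ALL_VARIANT_CLASSES - {VariantClass.SILENT}
    )
    # S2's remaining record is missense, so both samples still count
    assert prof.per_gene["G"] == pytest.approx(200 / 3)
    only_silent = mutation_frequency(_toy_table(), {"G"}, include_classes={VariantClass.SILENT})
    assert only_silent.per_gene["G"] == pytest.approx(100 / 3)


def test_mutation_frequency_empty_classes_raise():
    with pytest.raises(ValueError):
        mutation_frequency(_toy_table(), {"G"}, include_classes=frozenset())


def test_planted_rate_recovery_within_binomial_ci():
    # a gene mutated at 6.2% in a 3268-sample study is recovered within the
    # binomial 95% CI of the planted rate
    spec = MutationSpec(
        n_samples=3268,
        set_rates={"hot": 0.062},
        genes_per_set={"hot": 1},
        seed=11,
    )
    table, truth = generate_mutation_table(spec)
    prof = mutation_frequency(table, set(truth))
    (freq,) = prof.per_gene.values()
    half_width = 1.96 * math.sqrt(0.062 * (1 - 0.062) / 3268) * 100
    assert abs(freq - 6.2) < half_width


def test_compare_frequency_sets_identical_profiles():
    prof = FrequencyProfile(per_gene={"A": 1.0, "B": 2.0}, set_mean=1.5)
    frame = compare_frequency_sets({"x": prof, "y": prof})
    assert frame.loc[0, "ks_p"] == 1.0
    assert frame.loc[0, "ks_statistic"] == 0.0


def test_compare_frequency_sets_symmetry():
    a = FrequencyProfile(per_gene={f"A{i}": float(i) for i in range(6)}, set_mean=2.5)
    b = FrequencyProfile(per_gene={f"B{i}": float(2 * i) for i in range(5)}, set_mean=4.0)
    ab = compare_frequency_sets({"a": a, "b": b}).iloc[0]
    ba = compare_frequency_sets({"b": b, "a": a}).iloc[0]
    assert ab["ks_p"] == ba["ks_p"]
    assert (ab["mean_a"], ab["mean_b"]) == (ba["mean_b"], ba["mean_a"])


def test_compare_frequency_sets_empty_profile_raises():
    good = FrequencyProfile(per_gene={"A": 1.0}, set_mean=1.0)
    with pytest.raises(ValueError):
        compare_frequency_sets({"x": good, "y": FrequencyProfile(per_gene={}, set_mean=0.0)})


def test_threshold_zero_gives_all_ones():
    prof = {
        "a": FrequencyProfile(per_gene={"A": 0.0, "B": 5.0}, set_mean=2.5),
        "b": FrequencyProfile(per_gene={"C": 1.0}, set_mean=1.0),
    }
    fractions, _ = threshold_fraction(prof, 0.0)
    assert fractions == {"a": 1.0, "b": 1.0}


def _chi2_2x2_oracle(a, b, c, d):
    n = a + b + c + d
    expected = [
        [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
        [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
    ]
    observed = [[a, b], [c, d]]
    return sum(
        (observed[i][j] - expected[i][j]) ** 2 / expected[i][j]
        for i in range(2)
        for j in range(2)
    )


def test_threshold_chi2_matches_closed_form():
    # set "a": 18 of 32 genes above threshold; set "b": 27 of 70
    prof = {
        "a": FrequencyProfile(
            per_gene={f"A{i}": (5.0 if i < 18 else 0.5) for i in range(32)}, set_mean=0.0
        ),
        "b": FrequencyProfile(
            per_gene={f"B{i}": (5.0 if i < 27 else 0.5) for i in range(70)}, set_mean=0.0
        ),
    }
    fractions, frame = threshold_fraction(prof, 2.0)
    assert fractions["a"] == pytest.approx(18 / 32)
    row = frame.iloc[0]
    assert row["chi2"] == pytest.approx(_chi2_2x2_oracle(18, 14, 27, 43), rel=1e-12)
    assert row["chi2_p"] == pytest.approx(sps.chi2.sf(_chi2_2x2_oracle(18, 14, 27, 43), 1), rel=1e-12)


def test_drug_count_correlation_proportional_is_one():
    genes = {"A", "B", "C", "D"}
    freq = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
    counts = {"A": 2, "B": 4, "C": 6, "D": 8}
    r, p = drug_count_correlation(genes, freq, counts)
    assert r == pytest.approx(1.0)


def test_drug_count_correlation_toy_oracle():
    genes = ["G1", "G2", "G3", "G4", "G5"]
    freq = {"G1": 0.5, "G2": 2.0, "G3": 1.0, "G4": 6.0, "G5": 3.5}
    counts = {"G1": 1, "G2": 1, "G3": 2, "G4": 7, "G5": 2}
    r, p = drug_count_correlation(genes, freq, counts)
    x = np.array([freq[g] for g in sorted(genes)])
    y = np.array([counts[g] for g in sorted(genes)], dtype=float)
    rx = ((x - x.mean()) * (y - y.mean())).sum() / (
        math.sqrt(((x - x.mean()) ** 2).sum()) * math.sqrt(((y - y.mean()) ** 2).sum())
    )
    assert r == pytest.approx(rx, rel=1e-12)


def test_drug_count_correlation_constant_raises():
    with pytest.raises(ValueError):
        drug_count_correlation({"A", "B", "C"}, {"A": 1, "B": 1, "C": 1}, {"A": 1, "B": 2, "C": 3})


@settings(max_examples=40, deadline=None)
@given(genes=st.frozensets(GENE, max_size=20), ref=st.frozensets(GENE, max_size=20))
def test_list_overlap_matches_brute_force(genes, ref):
    overlap, n = list_overlap(genes, ref)
    assert overlap == {g for g in genes if g in ref}
    assert n == len(overlap)


def test_load_mutations_round_trip(tmp_path):
    spec = MutationSpec(
        n_samples=50,
        set_rates={"a": 0.2, "b": 0.05},
        genes_per_set={"a": 3, "b": 4},
        seed=5,
    )
    table, _ = generate_mutation_table(spec)
    path = write_mutation_tsv(table, tmp_path / "muts.tsv")
    loaded = load_mutations(path)
    assert loaded.n_samples == 50  # from the #n_samples= directive
    assert set(loaded.records) == set(table.records)
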