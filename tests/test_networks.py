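"""Network construction, degree statistics, K-S comparison, and export."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncodrug import (
    BipartiteNetwork,
    CatalogSpec,
    NetworkError,
    brute_force_ks_statistic,
    build_cancer_drug_target_network,
    build_drug_cancer_network,
    compare_degree_distributions,
    degree_breakdown,
    degree_summary,
    export_network,
    gene_targets,
    generate_catalog,
    import_edge_tsv,
)
from oncodrug.networks import EDGE_DRUG_CANCER, EDGE_DRUG_TARGET

from conftest import make_catalog, make_drug


def test_drug_cancer_network_headline_counts(catalog):
    net = build_drug_cancer_network(catalog)
    assert len(net.drug_nodes) == 150
    assert len(net.cancer_nodes) == 33
    assert net.n_nodes == 183
    assert len(net.edges) == 248


def test_single_drug_two_indications():
    cat = make_catalog([make_drug("A", indications=("CANCER01", "CANCER02"))])
    net = build_drug_cancer_network(cat)
    assert net.n_nodes == 3
    assert len(net.edges) == 2


@pytest.mark.parametrize("seed", [0, 1, 7])
def test_bipartite_edges_equal_indication_recount(seed):
    cat = generate_catalog(CatalogSpec(n_drugs=40, n_cancers=8, seed=seed))
    net = build_drug_cancer_network(cat)
    # brute-force recount of distinct (drug, indication) pairs
    expected = len({(d.name, ind) for d in cat.drugs for ind in d.indications})
    assert len(net.edges) == expected


def test_tripartite_network_headline_counts(catalog):
    net = build_cancer_drug_target_network(catalog)
    assert len(net.drug_nodes) == 89
    assert len(net.target_nodes) == 102
    assert len(net.cancer_nodes) == 23
    assert net.n_nodes == 214
    assert len(net.drug_cancer_edges) == 118
    assert len(net.drug_target_edges) == 195
    assert net.n_edges == 313


def test_tripartite_drug_target_edges_equal_gene_recount(catalog):
    net = build_cancer_drug_target_network(catalog)
    assert len(net.drug_target_edges) == sum(
        len(gene_targets(d)) for d in catalog.targeted_drugs
    )


def test_tripartite_empty_without_targeted_drugs():
    cat = generate_catalog(CatalogSpec(n_drugs=20, n_cancers=5, p_targeted=0.0, seed=3))
    net = build_cancer_drug_target_network(cat)
    assert not net.drug_nodes and not net.target_nodes and net.n_edges == 0


def test_drug_degrees(catalog):
    net = build_drug_cancer_network(catalog)
    summary = degree_summary(net, "drug")
    assert summary.mean == pytest.approx(1.65, abs=0.005)
    assert summary.min == 1
    assert summary.max == 11
    assert summary.skewness > 0  # strongly right-skewed


def test_cancer_degrees(catalog):
    net = build_drug_cancer_network(catalog)
    summary = degree_summary(net, "cancer")
    assert summary.mean == pytest.approx(7.52, abs=0.005)
    assert summary.max == 40


def test_star_graph_degrees():
    k = 6
    net = BipartiteNetwork(
        drug_nodes=frozenset({"hub"}),
        cancer_nodes=frozenset(f"c{i}" for i in range(k)),
        edges=frozenset(("hub", f"c{i}") for i in range(k)),
    )
    assert degree_summary(net, "drug").degrees["hub"] == k
    assert set(degree_summary(net, "cancer").degrees.values()) == {1}


def test_degree_summary_order_invariance(catalog):
    net = build_drug_cancer_network(catalog)
    subset = sorted(net.drug_nodes)[:10]
    a = degree_summary(net, "drug", node_subset=subset)
    b = degree_summary(net, "drug", node_subset=reversed(subset))
    assert a == b


def test_degree_summary_empty_class_raises():
    net = BipartiteNetwork(frozenset(), frozenset(), frozenset())
    with pytest.raises(NetworkError):
        degree_summary(net, "drug")


def test_tripartite_degree_means(catalog):
    net = build_cancer_drug_target_network(catalog)
    assert degree_summary(net, "drug", edge_type=EDGE_DRUG_TARGET).mean == pytest.approx(2.19, abs=0.005)
    assert degree_summary(net, "drug", edge_type=EDGE_DRUG_TARGET).max == 18
    assert degree_summary(net, "drug", edge_type=EDGE_DRUG_CANCER).mean == pytest.approx(1.33, abs=0.005)
    assert degree_summary(net, "target").mean == pytest.approx(1.91, abs=0.005)
    assert degree_summary(net, "target").max == 7
    assert degree_summary(net, "cancer").mean == pytest.approx(5.13, abs=0.005)


def test_drug_degree_breakdown(catalog):
    net = build_drug_cancer_network(catalog)
    counts = degree_breakdown(net, "drug", ["=1", "=2", ">=3"])
    assert counts == {"=1": 105, "=2": 24, ">=3": 21}


def test_cancer_degree_breakdown(catalog):
    net = build_drug_cancer_network(catalog)
    counts = degree_breakdown(net, "cancer", ["=1", "2-9", ">=10"])
    assert counts == {"=1": 11, "2-9": 12, ">=10": 10}


def test_breakdown_by_category(catalog):
    net = build_drug_cancer_network(catalog)
    cyt = {d.name for d in catalog.cytotoxic_drugs}
    counts = degree_breakdown(net, "drug", ["=1", "=2", ">=3"], node_subset=cyt)
    assert counts["=1"] == 35
    assert counts[">=3"] == 15


def test_breakdown_empty_network_is_zero():
    net = BipartiteNetwork(frozenset(), frozenset(), frozenset())
    assert degree_breakdown(net, "drug", ["=1", ">=2"]) == {"=1": 0, ">=2": 0}


def test_breakdown_overlapping_bins_raise(catalog):
    net = build_drug_cancer_network(catalog)
    with pytest.raises(NetworkError, match="overlap"):
        degree_breakdown(net, "drug", ["=1", "<=2", ">=3"])


def test_breakdown_uncovered_degree_raises(catalog):
    net = build_drug_cancer_network(catalog)
    with pytest.raises(NetworkError, match="no bin"):
        degree_breakdown(net, "drug", ["=1", "=2"])


def test_cytotoxic_degrees_exceed_targeted(catalog):
    net = build_drug_cancer_network(catalog)
    cyt = degree_summary(net, "drug", node_subset={d.name for d in catalog.cytotoxic_drugs})
    tar = degree_summary(net, "drug", node_subset={d.name for d in catalog.targeted_drugs})
    assert cyt.mean == pytest.approx(2.13, abs=0.005)
    assert tar.mean == pytest.approx(1.33, abs=0.005)
    res = compare_degree_distributions(
        list(cyt.degrees.values()), list(tar.degrees.values()), alternative="greater"
    )
    # one-sided asymptotic p-value of the degree dominance
    assert res.p_value == pytest.approx(0.0378, abs=5e-4)


def test_ks_identical_samples():
    res = compare_degree_distributions([1, 2, 2, 3], [1, 2, 2, 3])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_ks_hand_made_sample():
    # F_a jumps to 1 at 1; F_b stays 0 until 2: gap = 1 at x=1
    res = compare_degree_distributions([1, 1], [2, 2])
    assert res.statistic == pytest.approx(1.0)


@settings(max_examples=60, deadline=None)
@given(
    a=st.lists(st.integers(0, 12), min_size=1, max_size=50),
    b=st.lists(st.integers(0, 12), min_size=1, max_size=50),
)
def test_ks_statistic_matches_brute_force(a, b):
    res = compare_degree_distributions(a, b)
    assert res.statistic == pytest.approx(brute_force_ks_statistic(a, b), abs=1e-12)


def test_ks_empty_raises():
    with pytest.raises(ValueError):
        compare_degree_distributions([], [1])


def test_export_edge_tsv_round_trip(tmp_path, catalog):
    for net in (
        build_drug_cancer_network(catalog),
        build_cancer_drug_target_network(catalog),
    ):
        path = export_network(net, "edge-tsv", tmp_path / "net.tsv")
        assert import_edge_tsv(path) == net


def test_export_edge_tsv_row_count(tmp_path, catalog):
    path = export_network(build_drug_cancer_network(catalog), "edge-tsv", tmp_path / "n.tsv")
    lines = path.read_text().splitlines()
    assert len(lines) == 1 + 248  # header + one row per association


def test_export_empty_network_header_only(tmp_path):
    net = BipartiteNetwork(frozenset(), frozenset(), frozenset())
    path = export_network(net, "edge-tsv", tmp_path / "empty.tsv")
    assert path.read_text().splitlines() == ["source\tsource_class\ttarget\ttarget_class\tedge_type"]


def test_export_sif_and_graphml(tmp_path, catalog):
    net = build_cancer_drug_target_network(catalog)
    sif = export_network(net, "sif", tmp_path / "net.sif")
    assert len(sif.read_text().splitlines()) == 313
    gml = export_network(net, "graphml", tmp_path / "net.graphml")
    graph = nx.read_graphml(gml)
    assert graph.number_of_nodes() == 214
    assert graph.number_of_edges() == 313
    classes = nx.get_node_attributes(graph, "class")
    assert sorted(set(classes.values())) == ["cancer", "drug", "target"]


def test_export_unknown_format(tmp_path, catalog):
    net = build_drug_cancer_network(catalog)
    with pytest.raises(NetworkError, match="format"):
        export_network(net, "gexf", tmp_path / "x")
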