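"""Drug–cancer and cancer–drug–target networks with degree analytics.

Two undirected networks are built from a validated catalog:

* a bipartite network whose nodes are drugs and cancer classes, with one
  edge per approved (drug, indication) pair;
* a tripartite network restricted to targeted drugs, adding target nodes and
  drug–target edges (gene-level targets only; mechanism phrases excluded).

The degree of a node is its incident edge count; for drugs in the tripartite
network the target degree and the cancer degree are reported separately via
an edge-type filter.  Degree distributions are compared with a two-sample
Kolmogorov–Smirnov test (see :mod:`oncodrug.stats_util`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .catalog import Catalog, Category, gene_targets
from .stats_util import KSResult, ks_test

__all__ = [
    "BipartiteNetwork",
    "TripartiteNetwork",
    "DegreeSummary",
    "NetworkError",
    "build_drug_cancer_network",
    "build_cancer_drug_target_network",
    "degree_summary",
    "degree_breakdown",
    "parse_degree_bins",
    "compare_degree_distributions",
    "export_network",
    "import_edge_tsv",
    "to_networkx",
]

EDGE_DRUG_CANCER = "drug-cancer"
EDGE_DRUG_TARGET = "drug-target"


class NetworkError(ValueError):
    """Raised on malformed networks, bins, or export formats."""


@dataclass(frozen=True)
class BipartiteNetwork:
    drug_nodes: frozenset[str]
    cancer_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (drug, cancer)

    def __post_init__(self) -> None:
        for drug, cancer in self.edges:
            if drug not in self.drug_nodes or cancer not in self.cancer_nodes:
                raise NetworkError(f"edge ({drug!r}, {cancer!r}) has unknown endpoint")

    @property
    def n_nodes(self) -> int:
        return len(self.drug_nodes) + len(self.cancer_nodes)

    def node_class(self, name: str) -> str:
        if name in self.drug_nodes:
            return "drug"
        if name in self.cancer_nodes:
            return "cancer"
        raise KeyError(name)

    def typed_edges(self) -> list[tuple[str, str, str]]:
        return [(d, c, EDGE_DRUG_CANCER) for d, c in sorted(self.edges)]

    def nodes_of(self, node_class: str) -> frozenset[str]:
        try:
            return {"drug": self.drug_nodes, "cancer": self.cancer_nodes}[node_class]
        except KeyError:
            raise NetworkError(f"no node class {node_class!r}") from None


@dataclass(frozen=True)
class TripartiteNetwork:
    cancer_nodes: frozenset[str]
    drug_nodes: frozenset[str]
    target_nodes: frozenset[str]
    drug_cancer_edges: frozenset[tuple[str, str]]
    drug_target_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for drug, cancer in self.drug_cancer_edges:
            if drug not in self.drug_nodes or cancer not in self.cancer_nodes:
                raise NetworkError(f"edge ({drug!r}, {cancer!r}) has unknown endpoint")
        for drug, target in self.drug_target_edges:
            if drug not in self.drug_nodes or target not in self.target_nodes:
                raise NetworkError(f"edge ({drug!r}, {target!r}) has unknown endpoint")
        dangling = self.target_nodes - {t for _, t in self.drug_target_edges}
        if dangling:
            raise NetworkError(f"target nodes without incident edges: {sorted(dangling)}")

    @property
    def n_nodes(self) -> int:
        return len(self.cancer_nodes) + len(self.drug_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.drug_cancer_edges) + len(self.drug_target_edges)

    def node_class(self, name: str) -> str:
        if name in self.drug_nodes:
            return "drug"
        if name in self.cancer_nodes:
            return "cancer"
        if name in self.target_nodes:
            return "target"
        raise KeyError(name)

    def typed_edges(self) -> list[tuple[str, str, str]]:
        out = [(d, c, EDGE_DRUG_CANCER) for d, c in sorted(self.drug_cancer_edges)]
        out += [(d, t, EDGE_DRUG_TARGET) for d, t in sorted(self.drug_target_edges)]
        return out

    def nodes_of(self, node_class: str) -> frozenset[str]:
        table = {
            "drug": self.drug_nodes,
            "cancer": self.cancer_nodes,
            "target": self.target_nodes,
        }
        try:
            return table[node_class]
        except KeyError:
            raise NetworkError(f"no node class {node_class!r}") from None


@dataclass(frozen=True)
class DegreeSummary:
    degrees: Mapping[str, int]
    mean: float
    min: int
    max: int
    skewness: float

    def __post_init__(self) -> None:
        assert self.min <= self.mean <= self.max


def build_drug_cancer_network(catalog: Catalog) -> BipartiteNetwork:
    """One node per drug, one per cancer class with >=1 approval, one edge
    per distinct (drug, indication) pair."""
    edges = {(d.name, ind) for d in catalog.drugs for ind in d.indications}
    return BipartiteNetwork(
        drug_nodes=frozenset(d.name for d in catalog.drugs),
        cancer_nodes=frozenset(c for _, c in edges),
        edges=frozenset(edges),
    )


def build_cancer_drug_target_network(catalog: Catalog) -> TripartiteNetwork:
    """Tripartite network over targeted drugs, their indications, and their
    gene-level targets (mechanism tokens are not target nodes)."""
    targeted = catalog.targeted_drugs
    dc = {(d.name, ind) for d in targeted for ind in d.indications}
    dt = {(d.name, g) for d in targeted for g in gene_targets(d)}
    return TripartiteNetwork(
        cancer_nodes=frozenset(c for _, c in dc),
        drug_nodes=frozenset(d.name for d in targeted),
        target_nodes=frozenset(t for _, t in dt),
        drug_cancer_edges=frozenset(dc),
        drug_target_edges=frozenset(dt),
    )


def _incident_edges(
    network: BipartiteNetwork | TripartiteNetwork, edge_type: str | None
) -> list[tuple[str, str, str]]:
    edges = network.typed_edges()
    if edge_type is not None:
        known = {t for _, _, t in edges} | {EDGE_DRUG_CANCER, EDGE_DRUG_TARGET}
        if edge_type not in known:
            raise NetworkError(f"unknown edge type {edge_type!r}")
        edges = [e for e in edges if e[2] == edge_type]
    return edges


def degree_summary(
    network: BipartiteNetwork | TripartiteNetwork,
    node_class: str,
    node_subset: Iterable[str] | None = None,
    edge_type: str | None = None,
) -> DegreeSummary:
    """Degree statistics over one node class.

    ``node_subset`` restricts to a subset of that class (e.g. cytotoxic
    drugs); ``edge_type`` restricts the counted edges (e.g. ``"drug-target"``
    for the target degree of drugs in the tripartite network).  Skewness is
    the sample skewness g1.
    """
    nodes = network.nodes_of(node_class)
    if node_subset is not None:
        subset = frozenset(node_subset)
        unknown = subset - nodes
        if unknown:
            raise NetworkError(
                f"subset members not in class {node_class!r}: {sorted(unknown)}"
            )
        nodes = subset
    if not nodes:
        raise NetworkError(f"no nodes in class {node_class!r}")
    degrees = dict.fromkeys(sorted(nodes), 0)
    for a, b, _ in _incident_edges(network, edge_type):
        if a in degrees:
            degrees[a] += 1
        if b in degrees:
            degrees[b] += 1
    values = np.array(list(degrees.values()), dtype=float)
    if values.size > 1 and np.ptp(values) > 0:
        skewness = float(sps.skew(values, bias=True))
    else:
        skewness = 0.0  # constant or singleton: g1 undefined, report 0
    return DegreeSummary(
        degrees=degrees,
        mean=float(values.mean()),
        min=int(values.min()),
        max=int(values.max()),
        skewness=skewness,
    )


def parse_degree_bins(specs: Sequence[str]):
    """Turn bin strings like ``"=1"``, ``"2-9"``, ``">=10"``, ``"<=3"`` into
    (label, predicate) pairs."""
    bins = []
    for spec in specs:
        s = spec.strip()
        if s.startswith(">="):
            lo = int(s[2:])
            bins.append((s, lambda d, lo=lo: d >= lo))
        elif s.startswith("<="):
            hi = int(s[2:])
            bins.append((s, lambda d, hi=hi: d <= hi))
        elif s.startswith("="):
            k = int(s[1:])
            bins.append((s, lambda d, k=k: d == k))
        elif "-" in s:
            lo, hi = (int(x) for x in s.split("-", 1))
            bins.append((s, lambda d, lo=lo, hi=hi: lo <= d <= hi))
        else:
            k = int(s)
            bins.append((s, lambda d, k=k: d == k))
    return bins


def degree_breakdown(
    network: BipartiteNetwork | TripartiteNetwork,
    node_class: str,
    bins: Sequence[str] | Sequence[tuple[str, object]],
    node_subset: Iterable[str] | None = None,
    edge_type: str | None = None,
) -> dict[str, int]:
    """Node counts per degree bin.

    ``bins`` is either a list of strings understood by
    :func:`parse_degree_bins` or pre-built (label, predicate) pairs.  The
    bins must partition the observed degrees: a degree matching two bins
    raises, a degree matching none raises.
    """
    if all(isinstance(b, str) for b in bins):
        bins = parse_degree_bins(bins)  # type: ignore[arg-type]
    try:
        nodes = network.nodes_of(node_class)
    except NetworkError:
        raise
    if not nodes:
        return {label: 0 for label, _ in bins}
    summary = degree_summary(network, node_class, node_subset, edge_type)
    counts = {label: 0 for label, _ in bins}
    for node, deg in summary.degrees.items():
        hits = [label for label, pred in bins if pred(deg)]
        if len(hits) > 1:
            raise NetworkError(f"degree {deg} matches overlapping bins {hits}")
        if not hits:
            raise NetworkError(f"degree {deg} (node {node!r}) matches no bin")
        counts[hits[0]] += 1
    return counts


def compare_degree_distributions(
    degrees_a: Sequence[float],
    degrees_b: Sequence[float],
    alternative: str = "two-sided",
) -> KSResult:
    """Two-sample K-S comparison of two degree lists (asymptotic p)."""
    return ks_test(degrees_a, degrees_b, alternative=alternative)


def to_networkx(network: BipartiteNetwork | TripartiteNetwork) -> nx.Graph:
    graph = nx.Graph()
    for node_class in ("drug", "cancer", "target"):
        try:
            nodes = network.nodes_of(node_class)
        except NetworkError:
            continue
        for n in sorted(nodes):
            graph.add_node(n, **{"class": node_class})
    for a, b, etype in network.typed_edges():
        graph.add_edge(a, b, edge_type=etype)
    return graph


_EDGE_TSV_HEADER = "source\tsource_class\ttarget\ttarget_class\tedge_type"


def export_network(
    network: BipartiteNetwork | TripartiteNetwork,
    format: str,
    path: str | Path,
) -> Path:
    """Write the network as ``edge-tsv``, ``sif``, or ``graphml``.

    The edge-TSV round-trips losslessly through :func:`import_edge_tsv` for
    networks without isolated nodes.
    """
    path = Path(path)
    if format == "edge-tsv":
        lines = [_EDGE_TSV_HEADER]
        for a, b, etype in network.typed_edges():
            lines.append(
                f"{a}\t{network.node_class(a)}\t{b}\t{network.node_class(b)}\t{etype}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "sif":
        lines = [f"{a}\t{etype}\t{b}" for a, b, etype in network.typed_edges()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        nx.write_graphml(to_networkx(network), path)
    else:
        raise NetworkError(f"unknown export format {format!r}")
    return path


def import_edge_tsv(path: str | Path) -> BipartiteNetwork | TripartiteNetwork:
    """Re-read an edge-TSV export; returns a tripartite network when target
    nodes are present, otherwise a bipartite one."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _EDGE_TSV_HEADER:
        raise NetworkError(f"{path}: not an oncodrug edge TSV")
    nodes: dict[str, set[str]] = {"drug": set(), "cancer": set(), "target": set()}
    dc, dt = set(), set()
    for line in lines[1:]:
        src, src_class, dst, dst_class, etype = line.split("\t")
        nodes[src_class].add(src)
        nodes[dst_class].add(dst)
        if etype == EDGE_DRUG_CANCER:
            dc.add((src, dst))
        elif etype == EDGE_DRUG_TARGET:
            dt.add((src, dst))
        else:
            raise NetworkError(f"{path}: unknown edge type {etype!r}")
    if nodes["target"] or dt:
        return TripartiteNetwork(
            cancer_nodes=frozenset(nodes["cancer"]),
            drug_nodes=frozenset(nodes["drug"]),
            target_nodes=frozenset(nodes["target"]),
            drug_cancer_edges=frozenset(dc),
            drug_target_edges=frozenset(dt),
        )
    return BipartiteNetwork(
        drug_nodes=frozenset(nodes["drug"]),
        cancer_nodes=frozenset(nodes["cancer"]),
        edges=frozenset(dc),
    )
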