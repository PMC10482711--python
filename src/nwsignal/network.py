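"""Co-occurrence network of withdrawal symptoms.

Nodes are clinical symptom categories weighted by the number of patients
presenting them; edges connect categories co-occurring in the same patient,
weighted by the co-occurrence count.  The analyzed subset is the
confounder-free core of the cohort: monotherapy cases with at least two
distinct symptom categories, counted at patient level (duplicate PTs within
a category count once per patient).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import networkx as nx

from .casedef import AnalysisSet, SymptomCategoryMap

__all__ = [
    "SymptomNetwork",
    "select_network_subset",
    "build_network",
    "export_graph",
    "FORMATS",
]

FORMATS = ("graphml", "gexf", "edgelist-csv")


@dataclass
class SymptomNetwork:
    """Weighted co-occurrence graph over symptom categories.

    ``graph`` is an undirected :class:`networkx.Graph`; every node carries a
    ``frequency`` attribute (patients with the category) and every edge a
    ``weight`` (patients with both endpoint categories).  ``subset_size`` is
    the number of contributing patients.
    """

    graph: nx.Graph
    subset_size: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_weight(self, category: str) -> int:
        return self.graph.nodes[category]["frequency"]

    def edge_weight(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["weight"]

    def validate(self) -> None:
        """Structural invariants: positive integer weights, no self-loops,
        edge weight bounded by both endpoint frequencies."""
        for node, data in self.graph.nodes(data=True):
            if data["frequency"] <= 0:
                raise ValueError(f"node {node!r} has non-positive frequency")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-loop in symptom network")
            if data["weight"] <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive weight")
            if data["weight"] > min(
                self.graph.nodes[u]["frequency"], self.graph.nodes[v]["frequency"]
            ):
                raise ValueError(f"edge ({u}, {v}) heavier than an endpoint")


def select_network_subset(aset: AnalysisSet, min_categories: int = 2) -> list:
    """Patient-level category sets for the network: monotherapy cases with at
    least ``min_categories`` distinct symptom categories.

    Multiple reports of one patient are merged (union of categories) before
    the category-count filter.
    """
    t = aset.table
    sub = t[t["is_case"] & t["monotherapy"]]
    by_patient: dict = {}
    for pid, cats in zip(sub["patient_id"], sub["symptom_categories"]):
        by_patient[pid] = by_patient.get(pid, frozenset()) | cats
    return [cats for _, cats in sorted(by_patient.items()) if len(cats) >= min_categories]


def build_network(
    subset: Iterable,
    mapping: Optional[SymptomCategoryMap] = None,
) -> SymptomNetwork:
    """Build the co-occurrence network from per-patient symptom sets.

    ``subset`` is an iterable of per-patient collections of symptom
    categories (as produced by :func:`select_network_subset`) or of raw PT
    strings, in which case ``mapping`` translates them to categories
    (unmapped PTs are ignored).  An empty subset yields an empty graph.
    """
    graph = nx.Graph()
    n_patients = 0
    for item in subset:
        if mapping is not None:
            cats = {c for c in (mapping.category_of(pt) for pt in item) if c is not None}
        else:
            cats = set(item)
        n_patients += 1
        for cat in cats:
            if graph.has_node(cat):
                graph.nodes[cat]["frequency"] += 1
            else:
                graph.add_node(cat, frequency=1, label=cat)
        for u, v in combinations(sorted(cats), 2):
            if graph.has_edge(u, v):
                graph.edges[u, v]["weight"] += 1
            else:
                graph.add_edge(u, v, weight=1)
    net = SymptomNetwork(graph=graph, subset_size=n_patients)
    net.validate()
    return net


def export_graph(net: SymptomNetwork, path: str, format: str = "graphml") -> None:
    """Write the network for external rendering (node attribute
    ``frequency``, edge attribute ``weight``)."""
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "gexf":
        nx.write_gexf(net.graph, path)
    elif format == "edgelist-csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for u, v, data in sorted(net.graph.edges(data=True)):
                writer.writerow([u, v, data["weight"]])
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
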