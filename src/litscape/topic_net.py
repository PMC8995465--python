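"""Top-2 topic assignment and the topic co-occurrence network.

Every document is labelled with its two highest-probability topics; the
network has one node per topic (size = number of documents whose *primary*
topic it is, so sizes partition the corpus) and one edge per unordered topic
pair, weighted by how many documents carry exactly that pair as their top-2.
Hence both the node sizes and the edge weights sum to the document count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TopicAssignment",
    "assign_topics",
    "build_network",
    "export_graph",
    "import_graph",
    "write_edge_list",
]


@dataclass(frozen=True)
class TopicAssignment:
    doc_id: str
    primary_topic: int
    secondary_topic: int
    primary_prob: float
    secondary_prob: float


def assign_topics(
    theta: np.ndarray, doc_ids: Optional[Sequence[str]] = None
) -> list[TopicAssignment]:
    """Primary/secondary topic per document from the document-topic matrix.

    Primary is the argmax of the theta row, secondary the runner-up; ties are
    broken toward the lowest topic index so the result is deterministic.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[1] < 2:
        raise ValueError("theta must be 2-D with K >= 2 topics")
    if doc_ids is None:
        doc_ids = [str(i) for i in range(theta.shape[0])]
    if len(doc_ids) != theta.shape[0]:
        raise ValueError("doc_ids must align with theta rows")
    out = []
    for doc_id, row in zip(doc_ids, theta):
        # stable argsort on -row keeps the lowest index first among ties
        order = np.argsort(-row, kind="stable")
        p, s = int(order[0]), int(order[1])
        out.append(
            TopicAssignment(
                doc_id=doc_id,
                primary_topic=p,
                secondary_topic=s,
                primary_prob=float(row[p]),
                secondary_prob=float(row[s]),
            )
        )
    return out


def build_network(
    assignments: Sequence[TopicAssignment],
    n_topics: Optional[int] = None,
    labels: Optional[dict[int, str]] = None,
) -> nx.Graph:
    """Weighted undirected topic co-occurrence graph.

    Node attribute ``size`` counts primary-topic documents, ``label`` is the
    (optionally configured) topic name; edge attribute ``weight`` counts
    documents whose unordered top-2 pair is that edge.  Topics that attract
    no documents are kept as size-0 nodes so the node set always covers
    [0, n_topics).
    """
    if n_topics is None:
        n_topics = (
            1
            + max(
                max((a.primary_topic for a in assignments), default=0),
                max((a.secondary_topic for a in assignments), default=0),
            )
            if assignments
            else 0
        )
    labels = labels or {}
    g = nx.Graph()
    for k in range(n_topics):
        g.add_node(k, label=labels.get(k, f"topic_{k}"), size=0)
    for a in assignments:
        if a.primary_topic == a.secondary_topic:
            raise ValueError("degenerate assignment: primary == secondary")
        g.nodes[a.primary_topic]["size"] += 1
        u, v = sorted((a.primary_topic, a.secondary_topic))
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return g


def export_graph(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML or GEXF (both re-importable losslessly)."""
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "gexf":
        nx.write_gexf(network, path)
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def import_graph(path, format: str = "graphml") -> nx.Graph:
    """Read back a network written by :func:`export_graph`.

    Node ids are restored as integers and edge weights as integer counts.
    """
    fmt = format.lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "gexf":
        g = nx.read_gexf(path)
    else:
        raise ValueError(f"unknown graph format: {format!r}")
    g = nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
    for _, _, data in g.edges(data=True):
        data["weight"] = int(data["weight"])
    for _, data in g.nodes(data=True):
        if "size" in data:
            data["size"] = int(data["size"])
    return g


def write_edge_list(network: nx.Graph, path) -> None:
    """Edge list CSV (topic_a, topic_b, weight) sorted by topic pair."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic_a", "topic_b", "weight"])
        for u, v, w in sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in network.edges(data=True)
        ):
            writer.writerow([u, v, w])
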