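"""Assemble per-bait HCIP lists into one undirected interaction network.

Baits are nodes alongside their preys; a bait-prey hit observed in both
directions (A pulls down B and B pulls down A) collapses to a single edge
flagged *reciprocal*, and hits for the same pair from different cell lines
merge into one edge carrying multiple evidence records.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx

from .compass import ScoredInteraction

__all__ = [
    "BaitHcips",
    "InteractionNetwork",
    "build_network",
    "network_stats",
    "export_network",
    "read_network",
]


@dataclass
class BaitHcips:
    """The filtered HCIP list of one bait run in one cell line."""

    bait: str
    cell_line: str
    hcips: Sequence[ScoredInteraction]


@dataclass
class InteractionNetwork:
    """Undirected HCIP graph with per-edge evidence.

    Node attribute ``role`` is one of bait/prey/both; edge attributes are
    ``evidence`` (list of dicts with bait, prey, cell_line, nwd),
    ``reciprocal``, ``n_evidence`` and ``max_nwd``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    @property
    def reciprocal_edge_count(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d.get("reciprocal"))


def build_network(
    entries: Iterable[BaitHcips], include_isolated_baits: bool = True
) -> InteractionNetwork:
    """Merge per-bait HCIP lists into one network.

    Self-hits (bait recovering itself) are ignored; duplicate
    (bait, prey, cell line) records are de-duplicated with a warning.
    The result is independent of the order of ``entries``.
    """
    entries = list(entries)
    g = nx.Graph()
    baits = {e.bait for e in entries}
    directed: set[tuple[str, str]] = set()
    seen: set[tuple[str, str, str]] = set()
    evidence: dict[frozenset[str], list[dict]] = {}

    for entry in sorted(entries, key=lambda e: (e.bait, e.cell_line)):
        for s in entry.hcips:
            if s.prey == entry.bait:
                continue  # no self-loops
            key = (entry.bait, s.prey, entry.cell_line)
            if key in seen:
                warnings.warn(
                    f"duplicate HCIP record {key}; keeping first occurrence"
                )
                continue
            seen.add(key)
            directed.add((entry.bait, s.prey))
            pair = frozenset((entry.bait, s.prey))
            evidence.setdefault(pair, []).append(
                {
                    "bait": entry.bait,
                    "prey": s.prey,
                    "cell_line": entry.cell_line,
                    "nwd": s.NWD,
                }
            )

    nodes = set()
    if include_isolated_baits:
        nodes |= baits
    for pair in evidence:
        nodes |= set(pair)
    for node in sorted(nodes):
        role = "bait" if node in baits else "prey"
        g.add_node(node, role=role)
    # a bait that also appears as a prey gets role "both"
    prey_nodes = {ev["prey"] for evs in evidence.values() for ev in evs}
    for node in prey_nodes & baits:
        g.nodes[node]["role"] = "both"

    for pair, evs in evidence.items():
        a, b = sorted(pair)
        reciprocal = (a, b) in directed and (b, a) in directed
        g.add_edge(
            a,
            b,
            evidence=evs,
            reciprocal=reciprocal,
            n_evidence=len(evs),
            max_nwd=max(ev["nwd"] for ev in evs),
        )
    return InteractionNetwork(graph=g)


def network_stats(net: InteractionNetwork) -> dict:
    """Node/edge/reciprocal counts and per-node degree."""
    g = net.graph
    return {
        "node_count": g.number_of_nodes(),
        "edge_count": g.number_of_edges(),
        "reciprocal_edge_count": net.reciprocal_edge_count,
        "degree": {n: int(d) for n, d in g.degree()},
    }


def export_network(net: InteractionNetwork, path, fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV or GraphML file.

    The TSV carries node roles in comment lines (so isolated nodes
    round-trip) and one row per edge: source, target, reciprocal,
    n_evidence, max_NWD, evidence (JSON).  GraphML stores the same
    attributes, with evidence JSON-encoded.
    """
    g = net.graph
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for n in sorted(g.nodes):
                fh.write(f"# node: {n}\t{g.nodes[n].get('role', 'prey')}\n")
            fh.write("source\ttarget\treciprocal\tn_evidence\tmax_NWD\tevidence\n")
            for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
                d = g.edges[a, b]
                fh.write(
                    f"{a}\t{b}\t{int(d['reciprocal'])}\t{d['n_evidence']}\t"
                    f"{d['max_nwd']:.10g}\t{json.dumps(d['evidence'])}\n"
                )
    elif fmt == "graphml":
        h = nx.Graph()
        for n, d in g.nodes(data=True):
            h.add_node(n, role=d.get("role", "prey"))
        for a, b, d in g.edges(data=True):
            h.add_edge(
                a,
                b,
                reciprocal=bool(d["reciprocal"]),
                n_evidence=int(d["n_evidence"]),
                max_NWD=float(d["max_nwd"]),
                evidence=json.dumps(d["evidence"]),
            )
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected 'tsv' or 'graphml'")


def read_network(path, fmt: str = "tsv") -> InteractionNetwork:
    """Re-import a network written by :func:`export_network`."""
    g = nx.Graph()
    if fmt == "tsv":
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
        data = []
        for line in lines:
            if line.startswith("# node:"):
                name, role = line[len("# node:"):].strip().split("\t")
                g.add_node(name, role=role)
            elif line.startswith("#") or not line.strip():
                continue
            else:
                data.append(line.rstrip("\n"))
        header = data[0].split("\t")
        for line in data[1:]:
            row = dict(zip(header, line.split("\t")))
            g.add_edge(
                row["source"],
                row["target"],
                reciprocal=bool(int(row["reciprocal"])),
                n_evidence=int(row["n_evidence"]),
                max_nwd=float(row["max_NWD"]),
                evidence=json.loads(row["evidence"]),
            )
    elif fmt == "graphml":
        h = nx.read_graphml(path)
        for n, d in h.nodes(data=True):
            g.add_node(n, role=d.get("role", "prey"))
        for a, b, d in h.edges(data=True):
            g.add_edge(
                a,
                b,
                reciprocal=bool(d["reciprocal"]),
                n_evidence=int(d["n_evidence"]),
                max_nwd=float(d["max_NWD"]),
                evidence=json.loads(d["evidence"]),
            )
    else:
        raise ValueError(f"unknown import format {fmt!r}; expected 'tsv' or 'graphml'")
    return InteractionNetwork(graph=g)
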