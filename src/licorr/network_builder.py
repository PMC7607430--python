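"""Breadth-first expansion of biosynthesis networks from seed glycans.

Rules are applied generation by generation: one iteration applies every
eligible rule to every frontier glycan, and newly produced canonical
structures form the next frontier. Expansion is a set closure, so the
result is independent of seed and rule iteration order. Hard limits
(iterations, nodes, residues per glycan) guarantee termination against
processive elongation rules such as the poly-LacNAc iGnT/b4GalT cycle;
hitting a limit flags the network as truncated rather than erroring.

When a compartment order is given (e.g. cis, medial, trans Golgi), the
rules of each compartment are only applied after the previous compartment's
closure has stabilized; rules with no compartment are active in every
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .core_model import Glycan, count_residues, parse_glycan, serialize_glycan
from .errors import LicorrError
from .registry import Registry, default_registry
from .rule_engine import RuleTable, apply_rule


@dataclass
class ExpansionLimits:
    max_iterations: int = 20
    max_su_per_glycan: int = 30
    max_nodes: int = 10000
    compartment_order: tuple | None = None

    def __post_init__(self):
        for name in ("max_iterations", "max_su_per_glycan", "max_nodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True, order=True)
class Edge:
    substrate: str
    product: str
    enzyme: str
    rule_id: int
    site_index: int


@dataclass
class ReactionNetwork:
    nodes: set = field(default_factory=set)
    edges: list = field(default_factory=list)
    truncated: bool = False

    def sorted_nodes(self) -> list:
        return sorted(self.nodes)

    def sorted_edges(self) -> list:
        return sorted(self.edges)


def expand(
    seeds: list,
    t: RuleTable,
    limits: ExpansionLimits | None = None,
    registry: Registry | None = None,
) -> ReactionNetwork:
    """Breadth-first closure of ``t`` over ``seeds``.

    Node identity is the canonical string including any conjugate suffix.
    Glycans larger than ``max_su_per_glycan`` become nodes but are not
    expanded further.
    """
    limits = limits or ExpansionLimits()
    registry = registry or default_registry()
    seed_glycans = [
        parse_glycan(s, registry=registry) if isinstance(s, str) else s for s in seeds
    ]
    net = ReactionNetwork()
    edge_set = set()
    glycan_cache = {}
    for g in seed_glycans:
        text = serialize_glycan(g)
        net.nodes.add(text)
        glycan_cache[text] = g

    if limits.compartment_order:
        stages = [
            [
                (i, r)
                for i, r in enumerate(t.rules)
                if r.compartment in (None, comp)
            ]
            for comp in limits.compartment_order
        ]
    else:
        stages = [list(enumerate(t.rules))]

    for stage_rules in stages:
        frontier = set(net.nodes)
        for _ in range(limits.max_iterations):
            if not frontier:
                break
            new_frontier = set()
            for text in sorted(frontier):
                g = glycan_cache[text]
                if count_residues(g, registry=registry) > limits.max_su_per_glycan:
                    net.truncated = True
                    continue
                for rule_id, rule in stage_rules:
                    for product, site in apply_rule(rule, g, registry):
                        ptext = serialize_glycan(product)
                        if ptext == text:
                            continue
                        edge = Edge(text, ptext, rule.enzyme, rule_id, site)
                        if edge not in edge_set:
                            edge_set.add(edge)
                        if ptext not in net.nodes:
                            if len(net.nodes) >= limits.max_nodes:
                                net.truncated = True
                                continue
                            net.nodes.add(ptext)
                            glycan_cache[ptext] = product
                            new_frontier.add(ptext)
            frontier = new_frontier
        else:
            if frontier:
                net.truncated = True

    net.edges = sorted(edge_set)
    return net


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["substrate", "product", "enzyme", "rule_id", "site_index"]


def export_network(n: ReactionNetwork, format: str = "tsv_edges") -> str:
    """Render a network as text: 'tsv_edges', 'graphml', or 'json'.

    All three formats round-trip losslessly through
    :func:`import_network` (in the edge list, isolated nodes appear as rows
    with only the substrate column filled).
    """
    if format == "tsv_edges":
        lines = ["\t".join(_EDGE_HEADER)]
        for e in n.sorted_edges():
            lines.append(
                f"{e.substrate}\t{e.product}\t{e.enzyme}\t{e.rule_id}\t{e.site_index}"
            )
        connected = {e.substrate for e in n.edges} | {e.product for e in n.edges}
        for node in sorted(n.nodes - connected):
            lines.append(f"{node}\t\t\t\t")
        return "\n".join(lines) + "\n"
    if format == "json":
        return json.dumps(
            {
                "nodes": n.sorted_nodes(),
                "edges": [
                    {
                        "substrate": e.substrate,
                        "product": e.product,
                        "enzyme": e.enzyme,
                        "rule_id": e.rule_id,
                        "site_index": e.site_index,
                    }
                    for e in n.sorted_edges()
                ],
                "truncated": n.truncated,
            },
            indent=1,
            sort_keys=True,
        )
    if format == "graphml":
        graph = nx.MultiDiGraph()
        for node in n.sorted_nodes():
            graph.add_node(node)
        for e in n.sorted_edges():
            graph.add_edge(
                e.substrate,
                e.product,
                enzyme=e.enzyme,
                rule_id=e.rule_id,
                site_index=e.site_index,
            )
        return "\n".join(nx.generate_graphml(graph)) + "\n"
    raise LicorrError(f"unknown export format {format!r}")


def import_network(text: str, format: str = "tsv_edges") -> ReactionNetwork:
    net = ReactionNetwork()
    if format == "tsv_edges":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].split("\t") != _EDGE_HEADER:
            raise LicorrError("bad edge-list header")
        for ln in lines[1:]:
            sub, prod, enzyme, rule_id, site = (ln.split("\t") + [""] * 5)[:5]
            net.nodes.add(sub)
            if prod:
                net.nodes.add(prod)
                net.edges.append(Edge(sub, prod, enzyme, int(rule_id), int(site)))
    elif format == "json":
        data = json.loads(text)
        net.nodes = set(data["nodes"])
        net.edges = [
            Edge(e["substrate"], e["product"], e["enzyme"], e["rule_id"],
                 e["site_index"])
            for e in data["edges"]
        ]
        net.truncated = data.get("truncated", False)
    elif format == "graphml":
        graph = nx.parse_graphml(text)
        net.nodes = set(graph.nodes)
        for u, v, data in graph.edges(data=True):
            net.edges.append(
                Edge(u, v, data["enzyme"], int(data["rule_id"]),
                     int(data["site_index"]))
            )
    else:
        raise LicorrError(f"unknown import format {format!r}")
    net.edges = sorted(net.edges)
    return net


__all__ = [
    "ExpansionLimits",
    "Edge",
    "ReactionNetwork",
    "expand",
    "export_network",
    "import_network",
]
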