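"""Causal DAGs, d-separation and minimal sufficient adjustment sets.

The estimation pipeline decides which covariates enter the mediator and
outcome regressions from a user-supplied causal diagram rather than from a
stepwise procedure: a set Z is a sufficient adjustment set for the effect of
``source`` on ``target`` when it blocks every non-causal path between them,
which (with descendants of the exposure excluded from Z) reduces to the
backdoor criterion — Z d-separates ``source`` from ``target`` in the graph
with the source's outgoing edges removed.

d-separation is decided by the moralized-ancestral-graph construction:
restrict to ancestors of the query nodes, marry co-parents, drop the
conditioning set, and test plain undirected connectivity.  Graphs here are
small (a dozen-odd variables), so minimal adjustment sets are found by
exhaustive subset search in order of increasing size with superset pruning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "DagError",
    "CausalDAG",
    "AdjustmentSets",
    "read_dag",
    "d_separated",
    "minimal_adjustment_sets",
    "adjustment_sets",
    "select_adjustment_set",
]


class DagError(ValueError):
    """Raised for malformed DAG files or invalid graph queries."""


@dataclass
class CausalDAG:
    """A directed acyclic graph with designated exposure, mediator and
    outcome nodes, plus optional latent (unmeasured) node flags."""

    graph: nx.DiGraph
    exposure: str
    mediator: str
    outcome: str
    latent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DagError(f"graph contains a cycle: {cycle}")
        roles = {"exposure": self.exposure, "mediator": self.mediator,
                 "outcome": self.outcome}
        for role, node in roles.items():
            if node is None:
                raise DagError(f"missing role annotation: {role}")
            if node not in g:
                raise DagError(f"{role} node {node!r} not in graph")
        if len({self.exposure, self.mediator, self.outcome}) != 3:
            raise DagError("exposure, mediator and outcome must be distinct")
        for bad in (self.mediator, self.outcome):
            if g.has_edge(bad, self.exposure):
                raise DagError(f"edge {bad!r} -> exposure violates temporality")
        self.latent = frozenset(self.latent)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def observed_nodes(self) -> set[str]:
        return self.nodes - self.latent

    def descendants(self, node: str) -> set[str]:
        return nx.descendants(self.graph, node)


@dataclass
class AdjustmentSets:
    """Minimal sufficient adjustment sets for the two regression equations."""

    for_outcome_equation: list[frozenset[str]]
    for_mediator_equation: list[frozenset[str]]


def read_dag(text: str) -> CausalDAG:
    """Parse a plain-text DAG description.

    Syntax: one ``Parent -> Child`` edge per line (``;`` also separates
    statements), ``#`` comments, and role lines ``exposure: X``,
    ``mediator: M``, ``outcome: Y``, plus optional ``latent: U`` lines.
    Bare node names declare isolated nodes.
    """
    g = nx.DiGraph()
    roles: dict[str, str | None] = {"exposure": None, "mediator": None,
                                    "outcome": None}
    latent: set[str] = set()
    for raw_line in text.splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        for stmt in filter(None, (s.strip() for s in line.split(";"))):
            lowered = stmt.lower()
            matched_role = False
            for role in roles:
                if lowered.startswith(role + ":"):
                    roles[role] = stmt.split(":", 1)[1].strip()
                    matched_role = True
                    break
            if matched_role:
                continue
            if lowered.startswith("latent:"):
                latent.add(stmt.split(":", 1)[1].strip())
                continue
            if "->" in stmt:
                parts = [p.strip() for p in stmt.split("->")]
                if len(parts) < 2 or not all(parts):
                    raise DagError(f"cannot parse edge statement {stmt!r}")
                for parent, child in zip(parts, parts[1:]):
                    g.add_edge(parent, child)
            else:
                g.add_node(stmt)
    for node in latent:
        g.add_node(node)
    return CausalDAG(graph=g, exposure=roles["exposure"],
                     mediator=roles["mediator"], outcome=roles["outcome"],
                     latent=frozenset(latent))


def _check_nodes(g: nx.DiGraph, nodes) -> None:
    unknown = [n for n in nodes if n not in g]
    if unknown:
        raise DagError(f"unknown node(s): {unknown}")


def d_separated(dag: CausalDAG | nx.DiGraph, a: str, b: str,
                given=()) -> bool:
    """True iff ``given`` d-separates ``a`` from ``b``.

    Uses the moralized ancestral graph: keep only ancestors of
    ``{a, b} | given``, add an undirected edge between every pair of
    co-parents, drop directions and the conditioning nodes, and test whether
    ``a`` and ``b`` are disconnected.
    """
    g = dag.graph if isinstance(dag, CausalDAG) else dag
    given = set(given)
    _check_nodes(g, {a, b} | given)
    if a == b:
        raise DagError("d-separation query requires distinct endpoints")
    if a in given or b in given:
        raise DagError("conditioning set must exclude the query endpoints")

    relevant = {a, b} | given
    ancestral = set(relevant)
    for node in relevant:
        ancestral |= nx.ancestors(g, node)
    sub = g.subgraph(ancestral)

    moral = nx.Graph()
    moral.add_nodes_from(sub.nodes)
    moral.add_edges_from(sub.edges)
    for child in sub.nodes:
        for u, v in itertools.combinations(sorted(sub.predecessors(child)), 2):
            moral.add_edge(u, v)
    moral.remove_nodes_from(given)
    if a not in moral or b not in moral:
        return True
    return not nx.has_path(moral, a, b)


def _backdoor_graph(g: nx.DiGraph, source: str) -> nx.DiGraph:
    out = g.copy()
    out.remove_edges_from(list(g.out_edges(source)))
    return out


def is_sufficient(dag: CausalDAG, source: str, target: str, z) -> bool:
    """Backdoor check: does Z block all non-causal paths from source to
    target (d-separation in the graph with source's outgoing edges cut)?"""
    g = dag.graph if isinstance(dag, CausalDAG) else dag
    bd = _backdoor_graph(g, source)
    return d_separated(bd, source, target, z)


def minimal_adjustment_sets(
    dag: CausalDAG,
    source: str | None = None,
    target: str | None = None,
    forbidden=None,
) -> list[frozenset[str]]:
    """All minimal sufficient adjustment sets for ``source`` → ``target``.

    Candidate nodes are observed, are not the source/target, and are not in
    ``forbidden`` (which always includes every descendant of ``source``, so
    no set can open a path through a collider caused by the exposure or
    adjust away part of the effect).  Returns ``[frozenset()]`` when no
    adjustment is needed and ``[]`` when no sufficient set exists.  Sets are
    ordered by size, then lexicographically by sorted node names.
    """
    if isinstance(dag, nx.DiGraph):
        g, observed = dag, set(dag.nodes)
        if source is None or target is None:
            raise DagError("source and target are required for a bare graph")
    else:
        g, observed = dag.graph, dag.observed_nodes()
        source = dag.exposure if source is None else source
        target = dag.outcome if target is None else target
    _check_nodes(g, {source, target})
    forbidden = set(forbidden or ())
    forbidden |= nx.descendants(g, source) | {source, target}
    candidates = sorted(observed - forbidden)

    found: list[frozenset[str]] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            z = frozenset(combo)
            if any(prev <= z for prev in found):
                continue  # superset of a known minimal set
            if is_sufficient(dag, source, target, z):
                found.append(z)
        # keep scanning larger sizes: a larger set is only reported if no
        # subset of it was sufficient, so everything reported is minimal
    found.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return found


def adjustment_sets(dag: CausalDAG) -> AdjustmentSets:
    """Minimal sufficient sets for the outcome (X→Y) and mediator (X→M)
    equations; the mediator equation treats the mediator as the temporary
    outcome node under the same forbidden-descendant rule."""
    return AdjustmentSets(
        for_outcome_equation=minimal_adjustment_sets(
            dag, dag.exposure, dag.outcome
        ),
        for_mediator_equation=minimal_adjustment_sets(
            dag, dag.exposure, dag.mediator
        ),
    )


def select_adjustment_set(sets: list[frozenset[str]]) -> list[str]:
    """Deterministic choice among minimal sets: smallest, ties broken
    lexicographically by sorted node names."""
    if not sets:
        raise DagError("no sufficient adjustment set exists for this graph")
    best = min(sets, key=lambda s: (len(s), tuple(sorted(s))))
    return sorted(best)
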