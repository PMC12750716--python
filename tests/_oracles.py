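"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take the slow, literal route: d-separation by enumerating
every undirected simple path and applying the blocking rules path by path,
and minimal adjustment sets by testing every subset of eligible nodes.
They share no code with the implementation they check.
"""

from __future__ import annotations

import itertools

import networkx as nx


def all_undirected_paths(g: nx.DiGraph, a: str, b: str) -> list[list[str]]:
    """All simple paths between a and b ignoring edge direction."""
    ug = g.to_undirected(as_view=False)
    return [list(p) for p in nx.all_simple_paths(ug, a, b)]


def path_blocked(g: nx.DiGraph, path: list[str], given: set[str]) -> bool:
    """Blocking rule applied along one path: a non-collider node blocks when
    conditioned on; a collider blocks unless it or one of its descendants is
    conditioned on."""
    for i in range(1, len(path) - 1):
        u, v, w = path[i - 1], path[i], path[i + 1]
        is_collider = g.has_edge(u, v) and g.has_edge(w, v)
        if is_collider:
            opened = v in given or bool(nx.descendants(g, v) & given)
            if not opened:
                return True
        else:
            if v in given:
                return True
    return False


def d_separated_by_paths(g: nx.DiGraph, a: str, b: str, given) -> bool:
    given = set(given)
    return all(path_blocked(g, p, given)
               for p in all_undirected_paths(g, a, b))


def _is_causal_path(g: nx.DiGraph, path: list[str]) -> bool:
    return all(g.has_edge(u, v) for u, v in zip(path, path[1:]))


def sufficient_by_paths(g: nx.DiGraph, x: str, y: str, z) -> bool:
    """Z blocks every non-causal path from x to y."""
    z = set(z)
    for path in all_undirected_paths(g, x, y):
        if _is_causal_path(g, path):
            continue
        if not path_blocked(g, path, z):
            return False
    return True


def minimal_sets_brute_force(g: nx.DiGraph, x: str, y: str,
                             observed: set[str]) -> list[frozenset[str]]:
    """Every minimal sufficient adjustment set, by exhaustive subset search."""
    candidates = sorted(observed - nx.descendants(g, x) - {x, y})
    sufficient = [frozenset(c)
                  for size in range(len(candidates) + 1)
                  for c in itertools.combinations(candidates, size)
                  if sufficient_by_paths(g, x, y, c)]
    minimal = [s for s in sufficient
               if not any(t < s for t in sufficient)]
    minimal.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return minimal


def random_dag(rng, n_nodes: int, p_edge: float = 0.3) -> nx.DiGraph:
    """Random DAG over a random topological order of ``n_nodes`` nodes."""
    names = [f"v{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            g.add_edge(names[order[i]], names[order[j]])
    return g
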