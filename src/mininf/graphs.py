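"""Causal DAGs with hidden nodes, d-separation, and instrumental-set search.

A :class:`CausalDAG` is a plain directed acyclic graph plus a designated set
of hidden nodes. Bidirected arcs ``a <-> b`` (a dependence mediated by an
unobserved common cause) are expanded into an explicit fresh hidden parent
before any query, so every separation question reduces to ordinary
d-separation on a DAG, which is delegated to networkx.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .distributions import _as_names

__all__ = ["CausalDAG", "InstrumentalPair", "read_dag_json", "write_dag_json"]


@dataclass
class CausalDAG:
    """Directed acyclic graph over named nodes, some of them hidden."""

    nodes: tuple[str, ...]
    hidden: frozenset[str]
    edges: tuple[tuple[str, str], ...]
    arcs: tuple[tuple[str, str], ...] = ()
    _nx: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]],
                 hidden: Iterable[str] = (), arcs: Iterable[tuple[str, str]] = ()):
        nodes = tuple(nodes)
        hidden = frozenset(hidden)
        edges = tuple((str(a), str(b)) for a, b in edges)
        arcs = tuple((str(a), str(b)) for a, b in arcs)
        if not hidden <= set(nodes):
            raise ValueError("hidden nodes must be a subset of nodes")
        for a, b in edges + arcs:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a},{b}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        # each bidirected arc becomes a fresh hidden common parent
        expanded_hidden = set(hidden)
        all_nodes = list(nodes)
        for i, (a, b) in enumerate(arcs):
            latent = f"_arc{i}_{a}_{b}"
            g.add_node(latent)
            g.add_edge(latent, a)
            g.add_edge(latent, b)
            expanded_hidden.add(latent)
            all_nodes.append(latent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph has a directed cycle after arc expansion")
        self.nodes = tuple(all_nodes)
        self.hidden = frozenset(expanded_hidden)
        self.edges = edges
        self.arcs = arcs
        self._nx = g

    @property
    def observable(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.hidden)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._nx.predecessors(node)))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._nx))

    def _node_set(self, spec) -> set[str]:
        names = set(_as_names(spec))
        unknown = names - set(self.nodes)
        if unknown:
            raise KeyError(f"unknown node(s): {sorted(unknown)}")
        return names

    # -- d-separation --------------------------------------------------------
    def d_separated(self, a, b, s=()) -> bool:
        """True iff every path between A and B is blocked given S.

        A collider on a path is active iff it or one of its descendants is in
        S; a non-collider is active iff it is not in S.
        """
        a_s, b_s, s_s = self._node_set(a), self._node_set(b), self._node_set(s)
        if (a_s & b_s) or (a_s & s_s) or (b_s & s_s):
            raise ValueError("A, B, S must be pairwise disjoint")
        if not a_s or not b_s:
            return True
        return nx.is_d_separator(self._nx, a_s, b_s, s_s)

    def implied_independencies(self, max_condition_size: int | None = None
                               ) -> list[tuple[str, str, frozenset[str]]]:
        """All d-separations (a, b, S) with singleton a, b and |S| bounded.

        Enumeration covers every node pair (hidden included) and every
        conditioning set of admissible size, in deterministic sorted order.
        """
        nodes = sorted(self.nodes)
        if max_condition_size is None:
            max_condition_size = len(nodes) - 2
        out = []
        for a, b in itertools.combinations(nodes, 2):
            rest = [n for n in nodes if n not in (a, b)]
            for k in range(min(max_condition_size, len(rest)) + 1):
                for cond in itertools.combinations(rest, k):
                    if self.d_separated([a], [b], cond):
                        out.append((a, b, frozenset(cond)))
        return out

    # -- instrumental-set discovery ------------------------------------------
    def find_instrumental_sets(self, x, u, candidates) -> list["InstrumentalPair"]:
        """All (Z, B0) splits of ``candidates`` with Z nonempty and Z ⊥ U | B0.

        Pairs are returned in deterministic order. A pair is flagged
        *dominated* when another valid pair over the same union of candidate
        variables uses a strictly larger instrumental set Z (transferring
        variables from B0 into Z never loses testing power, since the upper
        bound H(X|Z,B0) is invariant under the exchange).
        """
        u_s = self._node_set(u)
        cand = sorted(self._node_set(candidates))
        if set(cand) & set(_as_names(x)):
            raise ValueError("candidates must exclude X")
        valid: list[tuple[frozenset, frozenset]] = []
        for r in range(1, len(cand) + 1):
            for z in itertools.combinations(cand, r):
                rest = [n for n in cand if n not in z]
                for k in range(len(rest) + 1):
                    for b0 in itertools.combinations(rest, k):
                        if self.d_separated(z, u_s, b0):
                            valid.append((frozenset(z), frozenset(b0)))
        pairs = []
        for z, b0 in valid:
            dominated = any(z < z2 and (z | b0) == (z2 | b02)
                            for z2, b02 in valid)
            pairs.append(InstrumentalPair(z, b0, dominated))
        pairs.sort(key=lambda p: (len(p.z), sorted(p.z), sorted(p.b0)))
        return pairs


@dataclass(frozen=True)
class InstrumentalPair:
    z: frozenset[str]
    b0: frozenset[str]
    dominated: bool


# -- brute-force oracle (used by the test suite as an independent check) -----

def d_separated_bruteforce(g: CausalDAG, a, b, s=()) -> bool:
    """Path-enumeration d-separation, independent of networkx internals."""
    a_s, b_s, s_s = g._node_set(a), g._node_set(b), g._node_set(s)
    skel = g._nx.to_undirected(as_view=True)
    desc = {n: nx.descendants(g._nx, n) | {n} for n in g.nodes}
    for src in a_s:
        for dst in b_s:
            for path in nx.all_simple_paths(skel, src, dst):
                if _path_active(g._nx, path, s_s, desc):
                    return False
    return True


def _path_active(dg: nx.DiGraph, path: Sequence[str], s: set[str], desc) -> bool:
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        collider = dg.has_edge(prev, node) and dg.has_edge(nxt, node)
        if collider:
            if not (desc[node] & s):
                return False
        elif node in s:
            return False
    return True


# -- JSON interchange --------------------------------------------------------

def read_dag_json(path) -> CausalDAG:
    with open(path) as fh:
        spec = json.load(fh)
    return CausalDAG(spec["nodes"], spec.get("edges", []),
                     hidden=spec.get("hidden", []), arcs=spec.get("arcs", []))


def write_dag_json(g: CausalDAG, path) -> None:
    base = [n for n in g.nodes if not n.startswith("_arc")]
    spec = {"nodes": base,
            "hidden": sorted(h for h in g.hidden if not h.startswith("_arc")),
            "edges": [list(e) for e in g.edges],
            "arcs": [list(a) for a in g.arcs]}
    with open(path, "w") as fh:
        json.dump(spec, fh, indent=1)
        fh.write("\n")
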