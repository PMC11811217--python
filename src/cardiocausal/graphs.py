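"""Partially directed acyclic graphs (PDAGs/CPDAGs) and orientation machinery.

A CPDAG (completed partially directed acyclic graph) represents a Markov
equivalence class of DAGs: edges whose direction is shared by every member
are directed, the rest are undirected.  Greedy Equivalence Search moves
between equivalence classes, so it needs three primitives implemented here:

* ``meek_orient`` — closure under Meek's orientation rules,
* ``pdag_to_dag`` — a consistent DAG extension (Dor–Tarsi),
* ``dag_to_cpdag`` — the equivalence class of a DAG (v-structures + Meek).
"""

from __future__ import annotations

import itertools
from typing import Hashable, Iterable, Iterator

Node = Hashable

__all__ = [
    "PDag",
    "Cpdag",
    "meek_orient",
    "pdag_to_dag",
    "dag_to_cpdag",
    "NoConsistentExtensionError",
]


class NoConsistentExtensionError(ValueError):
    """The PDAG admits no DAG with the same skeleton and v-structures."""


class PDag:
    """Mixed graph with directed (x -> y) and undirected (x -- y) edges.

    At most one edge may join a pair of nodes.  Node identity is by name;
    all edge queries are O(1) set lookups.
    """

    def __init__(self, nodes: Iterable[Node] = ()):
        self._pa: dict[Node, set[Node]] = {}
        self._ch: dict[Node, set[Node]] = {}
        self._un: dict[Node, set[Node]] = {}
        for v in nodes:
            self.add_node(v)

    # -- construction -------------------------------------------------
    def add_node(self, v: Node) -> None:
        if v not in self._pa:
            self._pa[v] = set()
            self._ch[v] = set()
            self._un[v] = set()

    def add_directed(self, x: Node, y: Node) -> None:
        if x == y:
            raise ValueError("self-loops are not allowed")
        if self.adjacent(x, y):
            raise ValueError(f"{x!r} and {y!r} are already adjacent")
        self.add_node(x)
        self.add_node(y)
        self._ch[x].add(y)
        self._pa[y].add(x)

    def add_undirected(self, x: Node, y: Node) -> None:
        if x == y:
            raise ValueError("self-loops are not allowed")
        if self.adjacent(x, y):
            raise ValueError(f"{x!r} and {y!r} are already adjacent")
        self.add_node(x)
        self.add_node(y)
        self._un[x].add(y)
        self._un[y].add(x)

    def remove_edge(self, x: Node, y: Node) -> None:
        self._ch[x].discard(y)
        self._pa[y].discard(x)
        self._ch[y].discard(x)
        self._pa[x].discard(y)
        self._un[x].discard(y)
        self._un[y].discard(x)

    def orient(self, x: Node, y: Node) -> None:
        """Turn the undirected edge x -- y into x -> y."""
        if y not in self._un[x]:
            raise ValueError(f"no undirected edge between {x!r} and {y!r}")
        self._un[x].discard(y)
        self._un[y].discard(x)
        self._ch[x].add(y)
        self._pa[y].add(x)

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> list[Node]:
        return list(self._pa)

    def parents(self, y: Node) -> set[Node]:
        return set(self._pa[y])

    def children(self, x: Node) -> set[Node]:
        return set(self._ch[x])

    def undirected_neighbors(self, y: Node) -> set[Node]:
        return set(self._un[y])

    def adjacent_set(self, v: Node) -> set[Node]:
        return self._pa[v] | self._ch[v] | self._un[v]

    def adjacent(self, x: Node, y: Node) -> bool:
        return y in self._pa[x] or y in self._ch[x] or y in self._un[x]

    def has_directed(self, x: Node, y: Node) -> bool:
        return y in self._ch[x]

    def has_undirected(self, x: Node, y: Node) -> bool:
        return y in self._un[x]

    @property
    def directed_edges(self) -> list[tuple[Node, Node]]:
        return sorted((x, y) for x in self._ch for y in self._ch[x])

    @property
    def undirected_edges(self) -> list[tuple[Node, Node]]:
        out = set()
        for x in self._un:
            for y in self._un[x]:
                out.add((x, y) if str(x) <= str(y) else (y, x))
        return sorted(out)

    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def copy(self) -> "PDag":
        g = type(self)(self.nodes)
        for v in self._pa:
            g._pa[v] = set(self._pa[v])
            g._ch[v] = set(self._ch[v])
            g._un[v] = set(self._un[v])
        return g

    def same_structure(self, other: "PDag") -> bool:
        """Identical node, directed-edge and undirected-edge sets."""
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed_edges == other.directed_edges
            and self.undirected_edges == other.undirected_edges
        )

    def is_clique(self, nodes: Iterable[Node]) -> bool:
        ns = list(nodes)
        return all(self.adjacent(a, b) for a, b in itertools.combinations(ns, 2))

    # -- path queries --------------------------------------------------
    def has_directed_path(self, x: Node, y: Node) -> bool:
        """True if a path of directed edges leads from x to y."""
        seen, stack = {x}, [x]
        while stack:
            v = stack.pop()
            if v == y:
                return True
            for w in self._ch[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def has_semidirected_path(self, x: Node, y: Node, avoiding: set[Node] = frozenset()) -> bool:
        """True if y is reachable from x along edges that are undirected or
        point away from x, without visiting any node in ``avoiding``."""
        if x in avoiding:
            return False
        seen, stack = {x}, [x]
        while stack:
            v = stack.pop()
            if v == y:
                return True
            for w in self._ch[v] | self._un[v]:
                if w not in seen and w not in avoiding:
                    seen.add(w)
                    stack.append(w)
        return False

    def directed_part_acyclic(self) -> bool:
        return not any(
            self.has_directed_path(y, x) for x, y in self.directed_edges
        )

    def topological_order(self) -> list[Node]:
        """Topological order of the directed part (ignores undirected edges)."""
        indeg = {v: len(self._pa[v]) for v in self._pa}
        queue = sorted(v for v in indeg if indeg[v] == 0)
        order: list[Node] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in sorted(self._ch[v], key=str):
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if len(order) != len(self._pa):
            cycle = sorted((v for v in indeg if indeg[v] > 0), key=str)
            raise ValueError(f"directed part contains a cycle among {cycle}")
        return order

    # -- v-structures --------------------------------------------------
    def v_structures(self) -> set[tuple[Node, Node, Node]]:
        """All (x, z, y) with x -> z <- y and x, y nonadjacent, x < y by name."""
        out = set()
        for z in self._pa:
            for x, y in itertools.combinations(sorted(self._pa[z], key=str), 2):
                if not self.adjacent(x, y):
                    out.add((x, z, y))
        return out

    # -- export ---------------------------------------------------------
    def edge_records(self) -> Iterator[dict]:
        for x, y in self.directed_edges:
            yield {"source": x, "target": y, "kind": "directed"}
        for x, y in self.undirected_edges:
            yield {"source": x, "target": y, "kind": "undirected"}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for rec in self.edge_records():
            g.add_edge(rec["source"], rec["target"], kind=rec["kind"])
            if rec["kind"] == "undirected":
                g.add_edge(rec["target"], rec["source"], kind="undirected")
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"{type(self).__name__}(|V|={len(self._pa)}, "
            f"directed={self.directed_edges}, undirected={self.undirected_edges})"
        )


class Cpdag(PDag):
    """A PDag that records the provenance of the search that produced it."""

    def __init__(self, nodes: Iterable[Node] = (), provenance: dict | None = None):
        super().__init__(nodes)
        self.provenance: dict = dict(provenance or {})

    def copy(self) -> "Cpdag":
        g = super().copy()
        g.provenance = dict(self.provenance)
        return g


def _would_cycle(g: PDag, x: Node, y: Node) -> bool:
    """Orienting x -> y would close a directed cycle."""
    return g.has_directed_path(y, x)


def meek_orient(pdag: PDag, diagnostics: list[str] | None = None) -> PDag:
    """Apply Meek's four orientation rules to fixpoint.

    Returns a new graph; the input is not modified.  An orientation that
    would close a directed cycle is skipped and noted in ``diagnostics``.
    The operation is idempotent: re-applying it to its own output is a
    no-op.
    """
    if not pdag.directed_part_acyclic():
        raise ValueError("directed part of the input contains a cycle")
    g = pdag.copy()
    changed = True
    while changed:
        changed = False
        for a, b in list(g.undirected_edges):
            for x, y in ((a, b), (b, a)):
                if not g.has_undirected(x, y):
                    continue
                if _rule_fires(g, x, y):
                    if _would_cycle(g, x, y):
                        if diagnostics is not None:
                            diagnostics.append(
                                f"skipped orientation {x!r}->{y!r}: would create a cycle"
                            )
                        continue
                    g.orient(x, y)
                    changed = True
                    break
    return g


def _rule_fires(g: PDag, a: Node, b: Node) -> bool:
    """Does any Meek rule orient the undirected edge a -- b as a -> b?"""
    # R1: c -> a, c and b nonadjacent.
    for c in g.parents(a):
        if not g.adjacent(c, b):
            return True
    # R2: directed chain a -> c -> b.
    for c in g.children(a):
        if g.has_directed(c, b):
            return True
    # R3: a -- c -> b and a -- d -> b with c, d nonadjacent.
    cands = [c for c in g.undirected_neighbors(a) if g.has_directed(c, b)]
    for c, d in itertools.combinations(cands, 2):
        if not g.adjacent(c, d):
            return True
    # R4: d -- a, d -> c -> b with d and b nonadjacent (either orientation of
    # b -- a then forces a cycle or a fresh v-structure, so a -> b).
    for d in g.undirected_neighbors(a):
        if g.adjacent(d, b):
            continue
        for c in g.children(d):
            if g.has_directed(c, b):
                return True
    return False


def pdag_to_dag(pdag: PDag) -> PDag:
    """A consistent extension: orient all undirected edges without creating a
    cycle or a new v-structure (Dor–Tarsi algorithm).

    Raises :class:`NoConsistentExtensionError` when none exists.
    """
    work = pdag.copy()
    dag = PDag(pdag.nodes)
    for x, y in pdag.directed_edges:
        dag.add_directed(x, y)
    remaining = set(work.nodes)
    while remaining:
        chosen = None
        for x in sorted(remaining, key=str):
            if work.children(x):
                continue  # x must be a sink of the directed part
            un = work.undirected_neighbors(x)
            adj = work.adjacent_set(x)
            # every undirected neighbour of x must see all of x's other
            # neighbours, else orienting into x creates a v-structure
            if all(adj - {w} <= work.adjacent_set(w) for w in un):
                chosen = x
                break
        if chosen is None:
            raise NoConsistentExtensionError(
                "PDAG admits no consistent DAG extension"
            )
        for w in work.undirected_neighbors(chosen):
            dag.add_directed(w, chosen)
        for w in list(work.adjacent_set(chosen)):
            work.remove_edge(chosen, w)
        remaining.discard(chosen)
    if not dag.directed_part_acyclic():  # pragma: no cover - defensive
        raise NoConsistentExtensionError("extension produced a cycle")
    return dag


def dag_to_cpdag(dag: PDag) -> Cpdag:
    """The CPDAG of a DAG: keep the skeleton, direct exactly the edges taking
    part in a v-structure, then close under Meek's rules."""
    if dag.undirected_edges:
        raise ValueError("input must be fully directed")
    dag.topological_order()  # raises on cycles
    compelled: set[tuple[Node, Node]] = set()
    for x, z, y in dag.v_structures():
        compelled.add((x, z))
        compelled.add((y, z))
    g = Cpdag(dag.nodes)
    for x, y in dag.directed_edges:
        if (x, y) in compelled:
            g.add_directed(x, y)
        else:
            g.add_undirected(x, y)
    closed = meek_orient(g)
    out = Cpdag(closed.nodes)
    for x, y in closed.directed_edges:
        out.add_directed(x, y)
    for x, y in closed.undirected_edges:
        out.add_undirected(x, y)
    return out
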