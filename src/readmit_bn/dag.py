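"""DAG algebra: constraint sets, Markov blankets, d-separation, structural indicators.

The directed acyclic graph is the structural half of a discrete Bayesian
network: each arc points from a cause to an effect and the joint
distribution factorizes into one conditional per node given its parents.
Clinical prior knowledge enters as a whitelist (arcs that must be present)
and a blacklist (arcs that must be absent). networkx supplies the graph
primitives (cycle detection, topological order, d-separation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import networkx as nx

Arc = tuple[str, str]

__all__ = [
    "DAG",
    "ConstraintSet",
    "ConstraintReport",
    "GraphIndicators",
    "GraphError",
    "dag_from_factorization",
    "validate_constraints",
    "markov_blanket",
    "graph_indicators",
    "d_separated",
    "to_dot",
    "from_dot",
]


class GraphError(ValueError):
    """Structural violation: cycle, self-arc, duplicate arc, or unknown node."""


class DAG:
    """Immutable directed acyclic graph over named variables."""

    def __init__(self, nodes: Sequence[str], arcs: Iterable[Arc] = ()) -> None:
        self.nodes = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphError("duplicate node names")
        arcs = [tuple(a) for a in arcs]
        if len(set(arcs)) != len(arcs):
            raise GraphError("duplicate arcs")
        node_set = set(self.nodes)
        for u, v in arcs:
            if u == v:
                raise GraphError(f"self-arc {u}->{v}")
            if u not in node_set or v not in node_set:
                raise GraphError(f"arc {u}->{v} references an unknown node")
        self.arcs = frozenset(arcs)
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise GraphError(f"graph contains a directed cycle: {cycle}")
        self._g = g

    # -- structure queries --------------------------------------------------

    def parents(self, v: str) -> tuple[str, ...]:
        self._check(v)
        return tuple(sorted(self._g.predecessors(v)))

    def children(self, v: str) -> tuple[str, ...]:
        self._check(v)
        return tuple(sorted(self._g.successors(v)))

    def parent_map(self) -> dict[str, tuple[str, ...]]:
        return {v: self.parents(v) for v in self.nodes}

    def topological_order(self) -> tuple[str, ...]:
        return tuple(nx.lexicographical_topological_sort(self._g))

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def _check(self, v: str) -> None:
        if v not in self._g:
            raise GraphError(f"unknown node {v!r}")

    # -- value semantics ----------------------------------------------------

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAG)
            and set(self.nodes) == set(other.nodes)
            and self.arcs == other.arcs
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.arcs))

    def __repr__(self) -> str:
        arcs = ", ".join(f"{u}->{v}" for u, v in sorted(self.arcs))
        return f"DAG({len(self.nodes)} nodes, {len(self.arcs)} arcs: {arcs})"


def dag_from_factorization(spec: Sequence[tuple[str, Sequence[str]]]) -> DAG:
    """Build the DAG whose arcs are read off a product-of-conditionals formula.

    ``spec`` lists ``(variable, parents)`` pairs, one per factor; every parent
    must itself appear as a variable, and the implied graph must be acyclic.
    """
    names = [v for v, _ in spec]
    if len(set(names)) != len(names):
        raise GraphError("a variable appears in more than one factor")
    known = set(names)
    arcs: list[Arc] = []
    for child, parents in spec:
        for p in parents:
            if p not in known:
                raise GraphError(f"parent {p!r} of {child!r} is not a declared variable")
            arcs.append((p, child))
    return DAG(names, arcs)


@dataclass(frozen=True)
class ConstraintSet:
    """Whitelist (forced) and blacklist (forbidden) arcs for structure search."""

    whitelist: frozenset[Arc] = frozenset()
    blacklist: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        wl = frozenset(tuple(a) for a in self.whitelist)
        bl = frozenset(tuple(a) for a in self.blacklist)
        object.__setattr__(self, "whitelist", wl)
        object.__setattr__(self, "blacklist", bl)
        overlap = wl & bl
        if overlap:
            raise GraphError(f"arcs both white- and blacklisted: {sorted(overlap)}")
        # the forced arcs must be jointly realizable
        nodes = sorted({n for a in wl for n in a})
        DAG(nodes, wl)

    @classmethod
    def from_csv(cls, path) -> "ConstraintSet":
        """Read a ``from,to,list`` CSV with list values ``whitelist``/``blacklist``."""
        import pandas as pd

        table = pd.read_csv(path, dtype=str)
        for col in ("from", "to", "list"):
            if col not in table.columns:
                raise GraphError(f"constraint file {path!r} lacks column {col!r}")
        wl, bl = [], []
        for _, row in table.iterrows():
            arc = (row["from"], row["to"])
            kind = row["list"].strip().lower()
            if kind == "whitelist":
                wl.append(arc)
            elif kind == "blacklist":
                bl.append(arc)
            else:
                raise GraphError(f"unknown constraint list {row['list']!r}")
        return cls(frozenset(wl), frozenset(bl))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"from": u, "to": v, "list": kind}
            for kind, arcs in (("whitelist", self.whitelist), ("blacklist", self.blacklist))
            for u, v in sorted(arcs)
        ]
        pd.DataFrame(rows, columns=["from", "to", "list"]).to_csv(path, index=False)


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of checking a DAG against a constraint set."""

    missing_whitelist: tuple[Arc, ...]
    present_blacklist: tuple[Arc, ...]

    @property
    def ok(self) -> bool:
        return not self.missing_whitelist and not self.present_blacklist

    @property
    def violations(self) -> tuple[str, ...]:
        out = [f"whitelist arc {u}->{v} missing" for u, v in self.missing_whitelist]
        out += [f"blacklist arc {u}->{v} present" for u, v in self.present_blacklist]
        return tuple(out)


def validate_constraints(g: DAG, constraints: ConstraintSet) -> ConstraintReport:
    """List every forced arc the graph lacks and every forbidden arc it carries."""
    missing = tuple(sorted(a for a in constraints.whitelist if a not in g.arcs))
    present = tuple(sorted(a for a in constraints.blacklist if a in g.arcs))
    return ConstraintReport(missing, present)


def markov_blanket(g: DAG, v: str) -> frozenset[str]:
    """Parents, children, and the children's other parents of *v*.

    Conditioning on this set renders *v* independent of every other node.
    """
    g._check(v)
    blanket = set(g.parents(v)) | set(g.children(v))
    for child in g.children(v):
        blanket |= set(g.parents(child))
    blanket.discard(v)
    return frozenset(blanket)


def _round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal("1." + "0" * decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GraphIndicators:
    """Structural summary of a DAG: arc count and per-node averages.

    ``avg_neighborhood`` is the mean undirected degree (= 2·arcs/nodes),
    ``avg_branching`` the mean out-degree (= arcs/nodes), and
    ``avg_markov_blanket`` the mean Markov-blanket size, never smaller than
    the mean neighborhood.
    """

    n_arcs: int
    avg_markov_blanket: float
    avg_neighborhood: float
    avg_branching: float

    def display(self, decimals: int = 2) -> dict[str, float]:
        """Half-up rounded values for tabular reporting (0.875 -> 0.88)."""
        return {
            "directed_arcs": self.n_arcs,
            "avg_markov_blanket": _round_half_up(self.avg_markov_blanket, decimals),
            "avg_neighborhood": _round_half_up(self.avg_neighborhood, decimals),
            "avg_branching": _round_half_up(self.avg_branching, decimals),
        }


def graph_indicators(g: DAG) -> GraphIndicators:
    """Compute the arc count and average blanket/neighborhood/branching sizes."""
    if not g.nodes:
        raise GraphError("indicators are undefined for an empty node set")
    n = len(g.nodes)
    mb = sum(len(markov_blanket(g, v)) for v in g.nodes) / n
    neigh = sum(len(set(g.parents(v)) | set(g.children(v))) for v in g.nodes) / n
    branch = len(g.arcs) / n
    return GraphIndicators(len(g.arcs), mb, neigh, branch)


def d_separated(g: DAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between *x* and *y* is blocked given the set *z*.

    Standard d-separation: chains and forks are blocked by conditioning,
    colliders are opened by conditioning on the collider or a descendant.
    """
    z = set(z)
    for node in {x, y} | z:
        g._check(node)
    if x == y or x in z or y in z:
        raise GraphError("x and y must be distinct and disjoint from z")
    return nx.is_d_separator(g.to_networkx(), {x}, {y}, z)


# -- DOT serialization ------------------------------------------------------
# Minimal writer/reader pair: round-trips its own output (quoted node names,
# one statement per line); not a general DOT parser.

def to_dot(g: DAG, annotations: Mapping[Arc, str] | None = None, name: str = "G") -> str:
    """Render the DAG as DOT text, optionally labeling arcs (e.g. significance tiers)."""
    annotations = dict(annotations or {})
    unknown = [a for a in annotations if tuple(a) not in g.arcs]
    if unknown:
        raise GraphError(f"annotations refer to absent arcs: {sorted(unknown)}")
    lines = [f"digraph {name} {{"]
    for v in g.nodes:
        lines.append(f'  "{v}";')
    for u, v in sorted(g.arcs):
        label = annotations.get((u, v))
        suffix = f' [label="{label}"]' if label is not None else ""
        lines.append(f'  "{u}" -> "{v}"{suffix};')
    lines.append("}")
    return "\n".join(lines) + "\n"


_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*;')


def from_dot(text: str) -> DAG:
    """Parse DOT text produced by :func:`to_dot` back into a DAG."""
    nodes: list[str] = []
    arcs: list[Arc] = []
    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            arcs.append((m.group(1), m.group(2)))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.append(m.group(1))
    for u, v in arcs:
        for n in (u, v):
            if n not in nodes:
                nodes.append(n)
    return DAG(nodes, arcs)
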