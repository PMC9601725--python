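"""Score-based structure search under whitelist/blacklist constraints.

The searcher is greedy hill climbing over single-arc moves (add, delete,
reverse) on the decomposable BIC/AIC score: the search starts from the
whitelist-only graph, takes the best strictly improving admissible move each
step, and stops at a local optimum. Whitelist arcs can never be deleted or
reversed, blacklist arcs never added, and cycles are rejected. Ties are
broken lexicographically by (move type, parent, child) so a run with zero
restarts is fully deterministic; optional seeded random restarts perturb the
start graph to escape local optima. An exhaustive enumeration oracle covers
instances of up to five variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .dag import DAG, Arc, ConstraintSet, validate_constraints
from .model import family_log_likelihood, parameter_count

__all__ = ["SearchStep", "SearchTrace", "hill_climb", "exhaustive_search"]

_IMPROVEMENT_EPS = 1e-9  # strict-improvement threshold guarding float noise


@dataclass(frozen=True)
class SearchStep:
    move: str  # "add" | "delete" | "reverse"
    arc: Arc
    delta: float
    score: float  # cumulative maximization-form score after the move


@dataclass
class SearchTrace:
    """Record of the accepted moves of the best climbing run."""

    steps: list[SearchStep] = field(default_factory=list)
    start_score: float = float("nan")
    final_score: float = float("nan")
    restarts: int = 0
    seed: object = None

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i + 1,
                    "move": s.move,
                    "from": s.arc[0],
                    "to": s.arc[1],
                    "delta": s.delta,
                    "score": s.score,
                }
                for i, s in enumerate(self.steps)
            ],
            columns=["step", "move", "from", "to", "delta", "score"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Scorer:
    """Cached decomposable family scores for one cohort and criterion."""

    def __init__(self, cohort: Cohort, criterion: str) -> None:
        criterion = criterion.lower()
        if criterion not in ("bic", "aic"):
            raise ValueError(f"unknown criterion {criterion!r}")
        self.names = list(cohort.names)
        self.pos = {v: i for i, v in enumerate(self.names)}
        self.codes = cohort.codes(self.names)
        self.cards = [cohort.variable(v).n_levels for v in self.names]
        n = cohort.n
        self.pen = math.log(n) / 2.0 if criterion == "bic" else 1.0
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def family(self, child: str, parents: Iterable[str]) -> float:
        c = self.pos[child]
        ps = frozenset(self.pos[p] for p in parents)
        key = (c, ps)
        if key not in self._cache:
            ll = family_log_likelihood(self.codes, self.cards, c, sorted(ps))
            k = (self.cards[c] - 1) * int(
                np.prod([self.cards[p] for p in ps], dtype=np.int64)
            )
            self._cache[key] = ll - self.pen * k
        return self._cache[key]

    def total(self, parent_map: dict[str, set[str]]) -> float:
        return sum(self.family(v, ps) for v, ps in parent_map.items())


def _creates_cycle(parent_map: dict[str, set[str]], u: str, v: str) -> bool:
    """Would adding u -> v close a directed cycle (i.e. is u reachable from v)?"""
    # children adjacency from parent map, DFS from v looking for u
    stack, seen = [v], set()
    children: dict[str, list[str]] = {w: [] for w in parent_map}
    for child, ps in parent_map.items():
        for p in ps:
            children[p].append(child)
    while stack:
        node = stack.pop()
        if node == u:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(children[node])
    return False


def _check_constraints(nodes: Iterable[str], constraints: ConstraintSet) -> None:
    node_set = set(nodes)
    for u, v in constraints.whitelist | constraints.blacklist:
        if u not in node_set or v not in node_set:
            raise ValueError(f"constraint arc {u}->{v} references an unknown variable")


def _climb(
    scorer: _Scorer,
    start: dict[str, set[str]],
    constraints: ConstraintSet,
) -> tuple[dict[str, set[str]], list[SearchStep], float]:
    parent_map = {v: set(ps) for v, ps in start.items()}
    nodes = sorted(parent_map)
    wl, bl = constraints.whitelist, constraints.blacklist
    score = scorer.total(parent_map)
    steps: list[SearchStep] = []
    while True:
        best = None  # (delta, move, (u, v), apply)
        # moves examined in deterministic lexicographic (move, parent, child) order
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                arc_present = u in parent_map[v]
                if not arc_present:
                    if (u, v) in bl or _creates_cycle(parent_map, u, v):
                        continue
                    delta = scorer.family(v, parent_map[v] | {u}) - scorer.family(
                        v, parent_map[v]
                    )
                    cand = (delta, "add", (u, v))
                else:
                    continue
                # strict ">" keeps the earliest candidate among ties, which is
                # the lexicographically least (move, parent, child)
                if best is None or cand[0] > best[0] + _IMPROVEMENT_EPS:
                    best = cand
        for u in nodes:
            for v in nodes:
                if u == v or u not in parent_map[v] or (u, v) in wl:
                    continue
                delta = scorer.family(v, parent_map[v] - {u}) - scorer.family(
                    v, parent_map[v]
                )
                cand = (delta, "delete", (u, v))
                if best is None or cand[0] > best[0] + _IMPROVEMENT_EPS:
                    best = cand
        for u in nodes:
            for v in nodes:
                if u == v or u not in parent_map[v] or (u, v) in wl or (v, u) in bl:
                    continue
                # reversing u->v: remove it, then v->u must not close a cycle
                parent_map[v].discard(u)
                cycle = _creates_cycle(parent_map, v, u)
                parent_map[v].add(u)
                if cycle:
                    continue
                delta = (
                    scorer.family(v, parent_map[v] - {u})
                    + scorer.family(u, parent_map[u] | {v})
                    - scorer.family(v, parent_map[v])
                    - scorer.family(u, parent_map[u])
                )
                cand = (delta, "reverse", (u, v))
                if best is None or cand[0] > best[0] + _IMPROVEMENT_EPS:
                    best = cand
        if best is None or best[0] <= _IMPROVEMENT_EPS:
            break
        delta, move, (u, v) = best
        if move == "add":
            parent_map[v].add(u)
        elif move == "delete":
            parent_map[v].discard(u)
        else:
            parent_map[v].discard(u)
            parent_map[u].add(v)
        score += delta
        steps.append(SearchStep(move, (u, v), delta, score))
    return parent_map, steps, score


def _to_dag(nodes: Iterable[str], parent_map: dict[str, set[str]]) -> DAG:
    arcs = [(p, v) for v, ps in parent_map.items() for p in ps]
    return DAG(tuple(nodes), arcs)


def hill_climb(
    cohort: Cohort,
    constraints: ConstraintSet | None = None,
    criterion: str = "bic",
    restarts: int = 0,
    seed=None,
    perturb: int = 4,
) -> tuple[DAG, SearchTrace]:
    """Greedy constrained search for the score-optimal DAG.

    Returns the best DAG found plus the trace of the winning run. With
    ``restarts`` > 0, each restart perturbs the whitelist start graph with
    up to ``perturb`` random admissible arc additions drawn from the seeded
    generator, and the best-scoring end point (ties broken by lexicographic
    arc set) is returned.
    """
    constraints = constraints or ConstraintSet()
    _check_constraints(cohort.names, constraints)
    scorer = _Scorer(cohort, criterion)
    nodes = list(cohort.names)
    start = {v: set() for v in nodes}
    for u, v in constraints.whitelist:
        start[v].add(u)
    start_score = scorer.total(start)

    runs: list[tuple[float, tuple[Arc, ...], dict[str, set[str]], list[SearchStep]]] = []
    parent_map, steps, score = _climb(scorer, start, constraints)
    runs.append((score, tuple(sorted((p, v) for v, ps in parent_map.items() for p in ps)),
                 parent_map, steps))

    rng = np.random.default_rng(seed)
    for _ in range(max(0, restarts)):
        perturbed = {v: set(ps) for v, ps in start.items()}
        n_moves = int(rng.integers(0, perturb + 1))
        for _ in range(n_moves):
            candidates = [
                (u, v)
                for u in nodes
                for v in nodes
                if u != v
                and u not in perturbed[v]
                and (u, v) not in constraints.blacklist
                and not _creates_cycle(perturbed, u, v)
            ]
            if not candidates:
                break
            u, v = candidates[int(rng.integers(len(candidates)))]
            perturbed[v].add(u)
        pm, st, sc = _climb(scorer, perturbed, constraints)
        runs.append((sc, tuple(sorted((p, v) for v, ps in pm.items() for p in ps)), pm, st))

    # deterministic tie-break: highest score, then lexicographically least arc set
    best_score = max(r[0] for r in runs)
    tied = [r for r in runs if abs(r[0] - best_score) <= _IMPROVEMENT_EPS]
    best = min(tied, key=lambda r: r[1])
    dag = _to_dag(nodes, best[2])
    report = validate_constraints(dag, constraints)
    assert report.ok, f"search produced a constraint-violating graph: {report.violations}"
    trace = SearchTrace(
        steps=best[3],
        start_score=start_score,
        final_score=best[0],
        restarts=max(0, restarts),
        seed=seed,
    )
    return dag, trace


def exhaustive_search(
    cohort: Cohort,
    constraints: ConstraintSet | None = None,
    criterion: str = "bic",
    max_variables: int = 5,
) -> DAG:
    """Enumerate every constraint-compliant DAG and return the score optimum.

    Intended as a test oracle: refuses instances above ``max_variables``
    (there are already 29,281 DAGs on five nodes). Among score ties the
    lexicographically least arc set wins.
    """
    constraints = constraints or ConstraintSet()
    _check_constraints(cohort.names, constraints)
    nodes = list(cohort.names)
    if len(nodes) > max_variables:
        raise ValueError(
            f"exhaustive search is limited to {max_variables} variables, got {len(nodes)}"
        )
    scorer = _Scorer(cohort, criterion)
    wl = constraints.whitelist
    optional = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and (u, v) not in wl and (u, v) not in constraints.blacklist
    ]
    optional.sort()
    best_score, best_arcs, best_map = -math.inf, None, None
    base = {v: set() for v in nodes}
    for u, v in wl:
        base[v].add(u)
    for mask in range(1 << len(optional)):
        parent_map = {v: set(ps) for v, ps in base.items()}
        ok = True
        m = mask
        i = 0
        while m:
            if m & 1:
                u, v = optional[i]
                parent_map[v].add(u)
            m >>= 1
            i += 1
        # acyclicity via Kahn's algorithm
        indeg = {v: len(ps) for v, ps in parent_map.items()}
        children: dict[str, list[str]] = {v: [] for v in nodes}
        for v, ps in parent_map.items():
            for p in ps:
                children[p].append(v)
        queue = [v for v in nodes if indeg[v] == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for c in children[node]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(nodes):
            continue
        score = scorer.total(parent_map)
        arcs = tuple(sorted((p, v) for v, ps in parent_map.items() for p in ps))
        if (
            score > best_score + _IMPROVEMENT_EPS
            or (abs(score - best_score) <= _IMPROVEMENT_EPS and (best_arcs is None or arcs < best_arcs))
        ):
            best_score, best_arcs, best_map = score, arcs, parent_map
    assert best_map is not None
    return _to_dag(nodes, best_map)
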