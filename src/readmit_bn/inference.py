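"""Exact posterior queries on a fitted discrete network.

Conditional-probability queries are answered by variable elimination with a
min-degree elimination order: CPT factors are reduced on the evidence,
then non-query variables are summed out one at a time, keeping intermediate
factors as small as the graph allows. At the scale of this analysis
(hundreds of joint states) a full-joint enumeration oracle is also provided
and is used to verify the elimination path. Queries are observational
conditioning, not interventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import BayesianNetwork

Evidence = Mapping[str, str]

__all__ = [
    "Evidence",
    "QueryResult",
    "InconsistentEvidenceError",
    "StateSpaceError",
    "eliminate_query",
    "enumerate_joint",
    "posterior_shift",
]


class InconsistentEvidenceError(ValueError):
    """The evidence assignment has probability zero under the network."""


class StateSpaceError(ValueError):
    """The full joint table would exceed the enumeration bound."""


@dataclass(frozen=True)
class _Factor:
    """A nonnegative table over a tuple of named discrete variables."""

    variables: tuple[str, ...]
    values: np.ndarray

    def marginalize(self, var: str) -> "_Factor":
        axis = self.variables.index(var)
        return _Factor(
            self.variables[:axis] + self.variables[axis + 1:],
            self.values.sum(axis=axis),
        )

    def reduce(self, var: str, level_index: int) -> "_Factor":
        axis = self.variables.index(var)
        return _Factor(
            self.variables[:axis] + self.variables[axis + 1:],
            np.take(self.values, level_index, axis=axis),
        )


def _product(factors: list[_Factor]) -> _Factor:
    out_vars: list[str] = []
    for f in factors:
        for v in f.variables:
            if v not in out_vars:
                out_vars.append(v)
    out = np.ones([1] * len(out_vars))
    for f in factors:
        # transpose the factor's axes into out_vars order, then broadcast
        order = sorted(range(len(f.variables)), key=lambda i: out_vars.index(f.variables[i]))
        arr = np.transpose(f.values, order) if f.variables else f.values
        view_shape = [1] * len(out_vars)
        it = iter(arr.shape)
        for i, v in enumerate(out_vars):
            if v in f.variables:
                view_shape[i] = next(it)
        out = out * arr.reshape(view_shape)
    return _Factor(tuple(out_vars), out)


def _validate_evidence(bn: BayesianNetwork, evidence: Evidence) -> dict[str, int]:
    reduced: dict[str, int] = {}
    for var, level in evidence.items():
        if var not in bn.cpts:
            raise KeyError(f"evidence names unknown variable {var!r}")
        reduced[var] = bn.variable(var).index(level)
    return reduced


def _min_degree_order(factors: list[_Factor], eliminate: set[str]) -> list[str]:
    """Greedy min-degree elimination order on the factor interaction graph."""
    neighbors: dict[str, set[str]] = {v: set() for v in eliminate}
    scopes = [set(f.variables) for f in factors]
    order: list[str] = []
    remaining = set(eliminate)
    while remaining:
        for v in remaining:
            neigh = set()
            for scope in scopes:
                if v in scope:
                    neigh |= scope
            neigh.discard(v)
            neighbors[v] = neigh
        # fewest neighbors, ties by name for determinism
        v = min(remaining, key=lambda u: (len(neighbors[u]), u))
        merged = neighbors[v] | {v}
        scopes = [s for s in scopes if v not in s] + [neighbors[v]]
        order.append(v)
        remaining.discard(v)
    return order


def _posterior(bn: BayesianNetwork, target: str, evidence: Evidence) -> np.ndarray:
    reduced = _validate_evidence(bn, evidence)
    factors = []
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        f = _Factor(tuple(p.name for p in cpt.parents) + (node,), cpt.table)
        for var, idx in reduced.items():
            if var in f.variables:
                f = f.reduce(var, idx)
        factors.append(f)
    to_eliminate = {v for v in bn.dag.nodes if v != target and v not in reduced}
    for var in _min_degree_order(factors, to_eliminate):
        related = [f for f in factors if var in f.variables]
        factors = [f for f in factors if var not in f.variables]
        factors.append(_product(related).marginalize(var))
    result = _product(factors)
    if result.variables != (target,):
        result_axis = result.variables.index(target)
        values = np.moveaxis(result.values, result_axis, 0).reshape(
            bn.variable(target).n_levels, -1
        ).sum(axis=1)
    else:
        values = result.values
    total = values.sum()
    if total <= 0.0:
        detail = ", ".join(f"{k}={v}" for k, v in evidence.items())
        raise InconsistentEvidenceError(
            f"evidence ({detail}) has probability zero under the network"
        )
    return values / total


@dataclass(frozen=True)
class QueryResult:
    """Posterior of one variable under evidence, with its no-evidence marginal."""

    target: str
    levels: tuple[str, ...]
    posterior: pd.Series
    marginal: pd.Series
    evidence: dict[str, str]
    smoothing: float | None = None

    @property
    def shift_pp(self) -> pd.Series:
        """Per-level (posterior − marginal) in percentage points."""
        return (self.posterior - self.marginal) * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "marginal": self.marginal.to_numpy(),
                "posterior": self.posterior.to_numpy(),
                "shift_pp": self.shift_pp.to_numpy(),
            }
        )


def eliminate_query(
    bn: BayesianNetwork, target: str, evidence: Evidence | None = None
) -> QueryResult:
    """Exact P(target | evidence) by variable elimination.

    The result also carries the no-evidence marginal and the per-level
    percentage-point shifts against it. Evidence with probability zero is an
    error naming the impossible assignment.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError(f"target {target!r} cannot also be evidence")
    levels = bn.variable(target).levels
    posterior = _posterior(bn, target, evidence)
    marginal = posterior if not evidence else _posterior(bn, target, {})
    return QueryResult(
        target=target,
        levels=levels,
        posterior=pd.Series(posterior, index=list(levels)),
        marginal=pd.Series(marginal, index=list(levels)),
        evidence=evidence,
        smoothing=bn.smoothing,
    )


def enumerate_joint(bn: BayesianNetwork, max_states: int = 10**6) -> pd.Series:
    """Full joint table as an explicit product of CPTs (test oracle).

    Returns a Series indexed by a MultiIndex of level labels in DAG node
    order; refuses state spaces beyond ``max_states`` configurations.
    """
    cards = [bn.variable(v).n_levels for v in bn.dag.nodes]
    n_states = int(np.prod(cards, dtype=np.int64))
    if n_states > max_states:
        raise StateSpaceError(
            f"joint has {n_states} configurations, above the {max_states} bound"
        )
    factors = [
        _Factor(tuple(p.name for p in bn.cpts[v].parents) + (v,), bn.cpts[v].table)
        for v in bn.dag.nodes
    ]
    joint = _product(factors)
    order = [joint.variables.index(v) for v in bn.dag.nodes]
    values = np.transpose(joint.values, order)
    index = pd.MultiIndex.from_product(
        [list(bn.variable(v).levels) for v in bn.dag.nodes], names=list(bn.dag.nodes)
    )
    return pd.Series(values.reshape(-1), index=index)


def posterior_shift(
    bn: BayesianNetwork, target: str, e1: Evidence, e2: Evidence
) -> pd.Series:
    """Per-level posterior difference P(target|e1) − P(target|e2), in pp."""
    q1 = eliminate_query(bn, target, e1)
    q2 = eliminate_query(bn, target, e2)
    return (q1.posterior - q2.posterior) * 100.0
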