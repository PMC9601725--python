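"""Multinomial Bayesian-network parameterization and information-criterion scoring.

A network is a DAG plus one conditional probability table (CPT) per node.
Fitting is closed-form: each CPT row is the (optionally Dirichlet-smoothed)
multinomial frequency of the child's levels within one parent configuration.
Scoring uses the Bayesian Information Criterion in both printed conventions:

    bic   = k·ln n − 2·ln L(θ)        (minimized)
    score = ln L(θ) − (ln n / 2)·k    (maximized; bic = −2·score)

where k counts free parameters, Σ_nodes (levels−1)·Π(parent levels), and the
per-parameter penalization coefficient is ln n / 2. AIC is the analogous
score with penalization coefficient 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, VariableSpec
from .dag import DAG

logger = logging.getLogger(__name__)

__all__ = [
    "CPT",
    "BayesianNetwork",
    "ScoreReport",
    "fit_cpts",
    "parameter_count",
    "log_likelihood",
    "network_score",
    "family_log_likelihood",
]


@dataclass(frozen=True)
class CPT:
    """Conditional distribution of one variable per parent configuration.

    ``table`` has shape ``(*parent_cardinalities, n_levels)``; each slice
    along the last axis is a probability vector.
    """

    variable: VariableSpec
    parents: tuple[VariableSpec, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        expected = tuple(p.n_levels for p in self.parents) + (self.variable.n_levels,)
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if table.shape != expected:
            raise ValueError(
                f"CPT for {self.variable.name!r}: shape {table.shape} != {expected}"
            )
        if np.any(table < -1e-12) or np.any(table > 1 + 1e-12):
            raise ValueError(f"CPT for {self.variable.name!r} has entries outside [0,1]")
        sums = table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(
                f"CPT rows for {self.variable.name!r} do not sum to 1 "
                f"(max deviation {np.abs(sums - 1).max():.3g})"
            )

    @property
    def n_free_parameters(self) -> int:
        n_rows = int(np.prod([p.n_levels for p in self.parents], dtype=int))
        return (self.variable.n_levels - 1) * n_rows

    def with_parent_order(self, order: Sequence[str]) -> "CPT":
        """The same conditional distribution with parent axes permuted to *order*."""
        names = [p.name for p in self.parents]
        if sorted(names) != sorted(order):
            raise ValueError(f"parent order {order} does not match {names}")
        perm = [names.index(o) for o in order]
        table = np.transpose(self.table, perm + [len(names)])
        return CPT(self.variable, tuple(self.parents[i] for i in perm), table)


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG plus one CPT per node, parent sets matching exactly."""

    dag: DAG
    cpts: Mapping[str, CPT]
    smoothing: float | None = None  # pseudo-count used at fit time, if fitted

    def __post_init__(self) -> None:
        if set(self.cpts) != set(self.dag.nodes):
            raise ValueError("CPTs must cover exactly the DAG's nodes")
        for v in self.dag.nodes:
            cpt_parents = tuple(p.name for p in self.cpts[v].parents)
            if tuple(sorted(cpt_parents)) != tuple(sorted(self.dag.parents(v))):
                raise ValueError(
                    f"CPT parents {cpt_parents} for {v!r} differ from "
                    f"DAG parents {self.dag.parents(v)}"
                )

    @property
    def variables(self) -> tuple[VariableSpec, ...]:
        return tuple(self.cpts[v].variable for v in self.dag.nodes)

    def variable(self, name: str) -> VariableSpec:
        return self.cpts[name].variable

    def n_free_parameters(self) -> int:
        return sum(cpt.n_free_parameters for cpt in self.cpts.values())


def fit_cpts(cohort: Cohort, dag: DAG, alpha: float = 0.0) -> BayesianNetwork:
    """Estimate all CPTs from the cohort by (smoothed) relative frequencies.

    Each entry is ``(count + α) / (config_total + α·levels)``; with α = 0 a
    parent configuration never observed falls back to the uniform row.
    """
    if alpha < 0:
        raise ValueError("smoothing pseudo-count must be nonnegative")
    missing = [v for v in dag.nodes if v not in cohort.names]
    if missing:
        raise ValueError(f"cohort lacks network variable(s) {missing}")
    cpts: dict[str, CPT] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        spec = cohort.variable(node)
        parent_specs = tuple(cohort.variable(p) for p in parents)
        shape = tuple(p.n_levels for p in parent_specs) + (spec.n_levels,)
        counts = np.zeros(shape, dtype=float)
        codes = cohort.codes(list(parents) + [node])
        np.add.at(counts, tuple(codes[:, j] for j in range(codes.shape[1])), 1.0)
        counts += alpha
        totals = counts.sum(axis=-1, keepdims=True)
        table = np.empty_like(counts)
        seen = totals[..., 0] > 0
        np.divide(counts, totals, out=table, where=totals > 0)
        table[~seen] = 1.0 / spec.n_levels  # unseen configuration: uniform fallback
        cpts[node] = CPT(spec, parent_specs, table)
    return BayesianNetwork(dag, cpts, smoothing=alpha)


def parameter_count(dag: DAG, cardinalities: Mapping[str, int]) -> int:
    """k = Σ over nodes of (levels − 1) · Π(parent levels)."""
    k = 0
    for node in dag.nodes:
        rows = 1
        for p in dag.parents(node):
            rows *= cardinalities[p]
        k += (cardinalities[node] - 1) * rows
    return k


def log_likelihood(bn: BayesianNetwork, cohort: Cohort) -> float:
    """ln L(θ): Σ over records and nodes of ln P(level | parent levels).

    −inf (with a warning naming the first offending record) when the data
    contain an observation the network gives probability zero.
    """
    if cohort.n == 0:
        return 0.0
    total = 0.0
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        parents = tuple(p.name for p in cpt.parents)
        codes = cohort.codes(list(parents) + [node])
        probs = cpt.table[tuple(codes[:, j] for j in range(codes.shape[1]))]
        zero = probs <= 0.0
        if zero.any():
            record = int(np.flatnonzero(zero)[0])
            logger.warning(
                "record %d has zero probability under node %r; log-likelihood is -inf",
                record, node,
            )
            return -math.inf
        total += float(np.log(probs).sum())
    return total


def family_log_likelihood(
    codes: np.ndarray, cards: Sequence[int], child: int, parents: Sequence[int]
) -> float:
    """Maximized multinomial log-likelihood of one (child | parents) family.

    ``codes`` is the (n, p) integer-coded data matrix; the result is
    Σ_configs Σ_levels N·ln(N/N_config) with 0·ln 0 = 0. Decomposable
    scores sum this over families.
    """
    idx = np.zeros(len(codes), dtype=np.int64)
    size = 1
    for p in parents:
        idx = idx * cards[p] + codes[:, p]
        size *= cards[p]
    idx = idx * cards[child] + codes[:, child]
    size *= cards[child]
    counts = np.bincount(idx, minlength=size).reshape(-1, cards[child]).astype(float)
    row_tot = np.broadcast_to(counts.sum(axis=1, keepdims=True), counts.shape)
    mask = counts > 0  # 0·ln 0 = 0 convention
    return float((counts[mask] * (np.log(counts[mask]) - np.log(row_tot[mask]))).sum())


@dataclass(frozen=True)
class ScoreReport:
    """BIC/AIC scoring of one (DAG, data) pair under maximum likelihood."""

    log_likelihood: float
    k: int
    n: int
    criterion: str
    penalization: float  #: per-parameter penalty: ln(n)/2 for BIC, 1 for AIC
    score: float  #: maximization form, ln L − penalization·k
    bic: float  #: minimization form, k·ln n − 2·ln L (= −2·score for BIC)
    aic: float  #: ln L − k
    family_scores: Mapping[str, float] = field(default_factory=dict)


def network_score(cohort: Cohort, dag: DAG, criterion: str = "bic") -> ScoreReport:
    """Fit MLE CPTs implicitly and score the structure on the cohort.

    The score decomposes additively over (node, parent-set) families; the
    per-family maximized log-likelihoods are included in the report.
    """
    criterion = criterion.lower()
    if criterion not in ("bic", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if cohort.n == 0:
        raise ValueError("cannot score a network on an empty cohort")
    names = list(cohort.names)
    pos = {v: i for i, v in enumerate(names)}
    codes = cohort.codes(names)
    cards = [cohort.variable(v).n_levels for v in names]
    fam_ll = {
        node: family_log_likelihood(
            codes, cards, pos[node], [pos[p] for p in dag.parents(node)]
        )
        for node in dag.nodes
    }
    loglik = sum(fam_ll.values())
    k = parameter_count(dag, {v: cohort.variable(v).n_levels for v in dag.nodes})
    n = cohort.n
    pen = math.log(n) / 2.0 if criterion == "bic" else 1.0
    bic = k * math.log(n) - 2.0 * loglik
    aic = loglik - k
    score = loglik - pen * k
    return ScoreReport(
        log_likelihood=loglik,
        k=k,
        n=n,
        criterion=criterion,
        penalization=pen,
        score=score,
        bic=bic,
        aic=aic,
        family_scores=fam_ll,
    )
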