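"""Synthetic ground-truth network and cohort sampler.

The study cohort sits behind a data deposit, so every pipeline stage is
exercised against a synthetic stand-in: a fixed, documented network on the
eight analysis variables whose DAG is the score-selected 7-arc structure and
whose root CPTs reproduce the published cohort marginals. Child CPTs are
synthetic: calibrated so the *exact* implied marginals match the published
one-way table within ±0.01, with conditional effects chosen qualitatively
(e.g. high BMI favors non-predictable breakthrough pain; nutritional support
without radiotherapy lowers the readmission count class) and deliberately
strong enough for structure recovery at simulation scale. They are not
estimates of the real cohort's conditionals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import study
from .cohort import Cohort
from .dag import DAG
from .inference import eliminate_query
from .model import CPT, BayesianNetwork

__all__ = ["default_ground_truth_network", "sample_cohort", "exact_marginal"]


def default_ground_truth_network() -> BayesianNetwork:
    """The fixed 8-variable network used as simulation ground truth.

    Root marginals: P(BMI ≥25) = 0.458, P(ALB ≤3.5) = 0.51,
    P(cancer group) = (0.18, 0.53, 0.29). Conditionals (probability of the
    second level, or the full row for the 3-level readmission class):

    - metastasis | cancer group: 0.12 / 0.16 / 0.19
    - nutrition | albumin: 0.30 if ≤3.5 g/dL else 0.075
    - predictable BTcP | metastasis, BMI: 0.55 with metastasis, else
      0.25 (<25 kg/m2) / 0.15 (≥25 kg/m2)
    - radiotherapy | metastasis: 0.40 / 0.06
    - readmission class (≤10, 11–22, >22) | nutrition, radiotherapy:
      no/no (0.20, 0.40, 0.40); yes/no (0.45, 0.38, 0.17);
      no/yes (0.30, 0.45, 0.25); yes/yes (0.33, 0.34, 0.33)
    """
    dag = study.bic_dag()
    s = {v.name: v for v in study.VARIABLES}

    def row2(p_second: float) -> list[float]:
        return [1.0 - p_second, p_second]

    cpts = {
        "BMI": CPT(s["BMI"], (), np.array(row2(0.458))),
        "ALB": CPT(s["ALB"], (), np.array([0.51, 0.49])),
        "CANCER": CPT(s["CANCER"], (), np.array([0.18, 0.53, 0.29])),
        "MTX": CPT(
            s["MTX"], (s["CANCER"],),
            np.array([row2(0.12), row2(0.16), row2(0.19)]),
        ),
        "NUTR": CPT(
            s["NUTR"], (s["ALB"],),
            np.array([row2(0.30), row2(0.075)]),
        ),
        # parents ordered (MTX, BMI); second level of BTcP is "Predictable"
        "BTcP": CPT(
            s["BTcP"], (s["MTX"], s["BMI"]),
            np.array([[row2(0.25), row2(0.15)], [row2(0.55), row2(0.55)]]),
        ),
        "RADIO": CPT(
            s["RADIO"], (s["MTX"],),
            np.array([row2(0.06), row2(0.40)]),
        ),
        # parents ordered (NUTR, RADIO); rows over (≤10, 11–22, >22)
        "HRA": CPT(
            s["HRA"], (s["NUTR"], s["RADIO"]),
            np.array(
                [
                    [[0.20, 0.40, 0.40], [0.30, 0.45, 0.25]],
                    [[0.45, 0.38, 0.17], [0.33, 0.34, 0.33]],
                ]
            ),
        ),
    }
    return BayesianNetwork(dag, cpts)


def exact_marginal(bn: BayesianNetwork, variable: str) -> pd.Series:
    """Exact (not sampled) marginal distribution of one variable."""
    return eliminate_query(bn, variable).marginal


def sample_cohort(bn: BayesianNetwork, n: int, seed) -> Cohort:
    """Draw *n* patients by ancestral sampling in topological order.

    ``seed`` feeds ``numpy.random.default_rng``; identical seeds yield
    byte-identical cohorts.
    """
    if n < 0:
        raise ValueError("sample size must be nonnegative")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        parent_names = [p.name for p in cpt.parents]
        if parent_names:
            rows = cpt.table[tuple(codes[p] for p in parent_names)]
        else:
            rows = np.broadcast_to(cpt.table, (n, cpt.variable.n_levels))
        cdf = np.cumsum(rows, axis=1)
        u = rng.random(n)
        codes[node] = np.minimum(
            (u[:, None] > cdf).sum(axis=1), cpt.variable.n_levels - 1
        )
    data = {}
    for spec in bn.variables:
        levels = np.asarray(spec.levels, dtype=object)
        data[spec.name] = levels[codes[spec.name]] if n else np.array([], dtype=object)
    frame = pd.DataFrame(data, columns=[v.name for v in bn.variables])
    return Cohort(bn.variables, frame, validate=False)
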