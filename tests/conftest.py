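import numpy as np
import pandas as pd
import pytest

from readmit_bn import synthetic
from readmit_bn.cohort import Cohort, VariableSpec
from readmit_bn.dag import DAG
from readmit_bn.model import CPT, BayesianNetwork


def make_cohort(columns: dict[str, list[str]], specs: dict[str, VariableSpec] | None = None) -> Cohort:
    """Build a validated cohort from literal columns; level sets inferred unless given."""
    specs = specs or {}
    spec_list = []
    for name, values in columns.items():
        spec = specs.get(name) or VariableSpec(name, tuple(sorted(set(map(str, values)))))
        spec_list.append(spec)
    return Cohort(spec_list, pd.DataFrame({k: list(map(str, v)) for k, v in columns.items()}))


def random_binary_network(rng: np.random.Generator, n_vars: int = 4, arc_prob: float = 0.4) -> BayesianNetwork:
    """A random DAG over binary variables with Dirichlet(2,2) CPT rows."""
    names = [f"V{i}" for i in range(n_vars)]
    specs = {nm: VariableSpec(nm, ("a", "b")) for nm in names}
    order = [names[i] for i in rng.permutation(n_vars)]
    arcs = [
        (order[i], order[j])
        for i in range(n_vars)
        for j in range(i + 1, n_vars)
        if rng.random() < arc_prob
    ]
    dag = DAG(names, arcs)
    cpts = {}
    for nm in names:
        parents = tuple(specs[p] for p in dag.parents(nm))
        rows = int(np.prod([p.n_levels for p in parents], dtype=int))
        table = rng.dirichlet((2.0, 2.0), size=rows).reshape(
            tuple(p.n_levels for p in parents) + (2,)
        )
        cpts[nm] = CPT(specs[nm], parents, table)
    return BayesianNetwork(dag, cpts)


@pytest.fixture(scope="session")
def ground_truth() -> BayesianNetwork:
    return synthetic.default_ground_truth_network()


@pytest.fixture(scope="session")
def cohort_10k(ground_truth) -> Cohort:
    return synthetic.sample_cohort(ground_truth, 10_000, 0)
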