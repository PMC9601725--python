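"""CPT estimation, parameter counting, likelihood, and BIC/AIC scoring."""

import math

import numpy as np
import pytest

from readmit_bn import study, synthetic
from readmit_bn.cohort import VariableSpec
from readmit_bn.dag import DAG
from readmit_bn.model import (
    CPT,
    BayesianNetwork,
    fit_cpts,
    log_likelihood,
    network_score,
    parameter_count,
)

from conftest import make_cohort


def binary_cohort(n_yes: int, n_no: int):
    return make_cohort(
        {"X": ["yes"] * n_yes + ["no"] * n_no},
        specs={"X": VariableSpec("X", ("yes", "no"))},
    )


class TestFit:
    def test_maximum_likelihood_frequencies(self):
        bn = fit_cpts(binary_cohort(7, 3), DAG(["X"]), alpha=0.0)
        assert bn.cpts["X"].table[0] == pytest.approx(0.7)

    def test_laplace_smoothing(self):
        bn = fit_cpts(binary_cohort(7, 3), DAG(["X"]), alpha=1.0)
        assert bn.cpts["X"].table[0] == pytest.approx(8 / 12)

    def test_unseen_parent_configuration_gets_uniform_row(self):
        cohort = make_cohort(
            {"P": ["a"] * 10, "C": ["u"] * 5 + ["v"] * 5},
            specs={
                "P": VariableSpec("P", ("a", "b")),
                "C": VariableSpec("C", ("u", "v")),
            },
        )
        bn = fit_cpts(cohort, DAG(["P", "C"], [("P", "C")]), alpha=0.0)
        assert bn.cpts["C"].table[1] == pytest.approx([0.5, 0.5])

    def test_rows_normalize_tightly(self, ground_truth, cohort_10k):
        bn = fit_cpts(cohort_10k, ground_truth.dag, alpha=0.0)
        for cpt in bn.cpts.values():
            assert np.allclose(cpt.table.sum(axis=-1), 1.0, atol=1e-12)

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            fit_cpts(binary_cohort(1, 1), DAG(["Y"]))


class TestParameterCount:
    def test_three_level_child_with_two_binary_parents(self):
        dag = DAG(["N", "R", "H"], [("N", "H"), ("R", "H")])
        cards = {"N": 2, "R": 2, "H": 3}
        assert parameter_count(dag, cards) == 1 + 1 + (3 - 1) * 4

    def test_full_study_model_has_23_parameters(self):
        cards = {v.name: v.n_levels for v in study.VARIABLES}
        assert parameter_count(study.bic_dag(), cards) == 23

    def test_single_binary_root(self):
        assert parameter_count(DAG(["X"]), {"X": 2}) == 1


class TestLogLikelihood:
    def test_fair_coin(self):
        spec = VariableSpec("X", ("yes", "no"))
        bn = BayesianNetwork(DAG(["X"]), {"X": CPT(spec, (), np.array([0.5, 0.5]))})
        cohort = binary_cohort(6, 4)
        assert log_likelihood(bn, cohort) == pytest.approx(10 * math.log(0.5))

    def test_empty_cohort_scores_zero(self):
        spec = VariableSpec("X", ("yes", "no"))
        bn = BayesianNetwork(DAG(["X"]), {"X": CPT(spec, (), np.array([0.5, 0.5]))})
        cohort = binary_cohort(1, 1)
        empty = cohort.select(["X"])
        empty.data = empty.data.iloc[:0]
        assert log_likelihood(bn, empty) == 0.0

    def test_zero_probability_record_gives_minus_inf(self):
        spec = VariableSpec("X", ("yes", "no"))
        bn = BayesianNetwork(DAG(["X"]), {"X": CPT(spec, (), np.array([1.0, 0.0]))})
        assert log_likelihood(bn, binary_cohort(3, 1)) == -math.inf

    def test_mle_beats_perturbed_parameterizations(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 400, 21)
        dag = ground_truth.dag
        fitted = fit_cpts(cohort, dag, alpha=0.0)
        best = log_likelihood(fitted, cohort)
        rng = np.random.default_rng(21)
        for _ in range(10):
            cpts = {}
            for name, cpt in fitted.cpts.items():
                noisy = cpt.table + rng.uniform(0.01, 0.2, size=cpt.table.shape)
                noisy /= noisy.sum(axis=-1, keepdims=True)
                cpts[name] = CPT(cpt.variable, cpt.parents, noisy)
            other = BayesianNetwork(dag, cpts)
            assert log_likelihood(other, cohort) <= best + 1e-9


class TestScoring:
    def test_penalization_coefficient_at_study_size(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 96, 5)
        report = network_score(cohort, study.bic_dag(), "bic")
        assert report.penalization == pytest.approx(math.log(96) / 2)
        assert round(report.penalization, 2) == 2.28
        assert report.k == 23
        assert report.n == 96

    def test_bic_is_minus_two_score(self, ground_truth):
        for seed, n in [(1, 50), (2, 96), (3, 400)]:
            cohort = synthetic.sample_cohort(ground_truth, n, seed)
            r = network_score(cohort, study.bic_dag(), "bic")
            assert r.bic == pytest.approx(-2.0 * r.score, abs=1e-9)
            assert r.bic == pytest.approx(r.k * math.log(n) - 2 * r.log_likelihood)

    def test_aic_penalizes_one_per_parameter(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 96, 5)
        r = network_score(cohort, study.bic_dag(), "aic")
        assert r.penalization == 1.0
        assert r.score == pytest.approx(r.log_likelihood - r.k)

    def test_score_decomposes_over_families(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 300, 6)
        r = network_score(cohort, study.bic_dag(), "bic")
        assert sum(r.family_scores.values()) == pytest.approx(r.log_likelihood, abs=1e-9)

    def test_adding_an_arc_never_hurts_likelihood_or_k(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 200, 8)
        rng = np.random.default_rng(8)
        base = study.bic_dag()
        for _ in range(10):
            candidates = [
                (u, v)
                for u in base.nodes
                for v in base.nodes
                if u != v and (u, v) not in base.arcs
            ]
            u, v = candidates[int(rng.integers(len(candidates)))]
            try:
                bigger = DAG(base.nodes, list(base.arcs) + [(u, v)])
            except Exception:
                continue
            r0 = network_score(cohort, base, "bic")
            r1 = network_score(cohort, bigger, "bic")
            assert r1.log_likelihood >= r0.log_likelihood - 1e-9
            assert r1.k >= r0.k

    def test_parameter_recovery_from_large_sample(self, ground_truth, cohort_10k):
        # rows with decent support recover their generating probabilities
        fitted = fit_cpts(cohort_10k, ground_truth.dag, alpha=0.0)
        for node in ("BMI", "ALB", "CANCER", "NUTR"):
            assert np.allclose(
                fitted.cpts[node].table, ground_truth.cpts[node].table, atol=0.02
            ), node
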