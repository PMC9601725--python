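"""DAG construction, constraints, Markov blankets, d-separation, indicators."""

import numpy as np
import pytest

from readmit_bn import study
from readmit_bn.dag import (
    DAG,
    ConstraintSet,
    GraphError,
    d_separated,
    dag_from_factorization,
    from_dot,
    graph_indicators,
    markov_blanket,
    to_dot,
    validate_constraints,
)


def random_dag(rng: np.random.Generator, n_nodes: int, arc_prob: float = 0.35) -> DAG:
    names = [f"N{i}" for i in range(n_nodes)]
    order = [names[i] for i in rng.permutation(n_nodes)]
    arcs = [
        (order[i], order[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < arc_prob
    ]
    return DAG(names, arcs)


class TestConstruction:
    def test_factorization_yields_seven_arcs(self):
        dag = dag_from_factorization(study.BIC_FACTORIZATION)
        assert dag.arcs == frozenset(
            {
                ("CANCER", "MTX"),
                ("ALB", "NUTR"),
                ("MTX", "BTcP"),
                ("BMI", "BTcP"),
                ("MTX", "RADIO"),
                ("NUTR", "HRA"),
                ("RADIO", "HRA"),
            }
        )

    def test_empty_parent_sets_give_empty_graph(self):
        dag = dag_from_factorization([("A", ()), ("B", ())])
        assert dag.arcs == frozenset()

    def test_cyclic_factorization_rejected(self):
        with pytest.raises(GraphError):
            dag_from_factorization([("A", ("B",)), ("B", ("A",))])

    def test_unknown_parent_rejected(self):
        with pytest.raises(GraphError, match="parent"):
            dag_from_factorization([("A", ("Z",))])

    @pytest.mark.parametrize(
        "arcs", [[("A", "A")], [("A", "B"), ("B", "C"), ("C", "A")]]
    )
    def test_self_arcs_and_cycles_rejected(self, arcs):
        with pytest.raises(GraphError):
            DAG(["A", "B", "C"], arcs)


class TestMarkovBlanket:
    def test_metastasis_blanket_includes_spouse(self):
        dag = study.bic_dag()
        assert markov_blanket(dag, "MTX") == {"CANCER", "BTcP", "RADIO", "BMI"}

    def test_albumin_blanket_is_its_only_child(self):
        assert markov_blanket(study.bic_dag(), "ALB") == {"NUTR"}

    def test_isolated_node_has_empty_blanket(self):
        dag = DAG(["A", "B", "C"], [("A", "B")])
        assert markov_blanket(dag, "C") == frozenset()

    def test_unknown_node_is_an_error(self):
        with pytest.raises(GraphError):
            markov_blanket(study.bic_dag(), "XYZ")

    def test_blanket_symmetric_in_moral_graph(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            dag = random_dag(rng, int(rng.integers(3, 8)))
            for x in dag.nodes:
                for y in markov_blanket(dag, x):
                    assert x in markov_blanket(dag, y)


class TestIndicators:
    def test_learned_structure_indicators(self):
        gi = graph_indicators(study.bic_dag()).display()
        assert gi == {
            "directed_arcs": 7,
            "avg_markov_blanket": 2.25,
            "avg_neighborhood": 1.75,
            "avg_branching": 0.88,  # 7/8 = 0.875 rounded half-up
        }

    def test_knowledge_structure_indicators(self):
        gi = graph_indicators(study.knowledge_dag()).display()
        assert gi["directed_arcs"] == 11
        assert gi["avg_neighborhood"] == 2.75
        assert gi["avg_branching"] == 1.38

    def test_empty_graph_indicators_are_zero(self):
        gi = graph_indicators(DAG(study.VARIABLE_NAMES, []))
        assert (gi.n_arcs, gi.avg_markov_blanket, gi.avg_neighborhood, gi.avg_branching) == (0, 0, 0, 0)

    def test_identities_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(2, 9)))
            gi = graph_indicators(dag)
            n, a = len(dag.nodes), len(dag.arcs)
            assert gi.avg_neighborhood == pytest.approx(2 * a / n)
            assert gi.avg_branching == pytest.approx(a / n)
            assert gi.avg_markov_blanket >= gi.avg_neighborhood - 1e-12


class TestDSeparation:
    def test_parents_block_paths_to_readmission(self):
        assert d_separated(study.bic_dag(), "HRA", "MTX", {"RADIO", "NUTR"})

    def test_collider_opens_on_conditioning(self):
        dag = study.bic_dag()
        assert d_separated(dag, "MTX", "BMI", set())
        assert not d_separated(dag, "MTX", "BMI", {"BTcP"})

    def test_chain_blocked_by_middle_node(self):
        chain = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert d_separated(chain, "A", "C", {"B"})
        assert not d_separated(chain, "A", "C", set())

    def test_degenerate_arguments_rejected(self):
        with pytest.raises(GraphError):
            d_separated(study.bic_dag(), "BMI", "BMI", set())
        with pytest.raises(GraphError):
            d_separated(study.bic_dag(), "BMI", "MTX", {"BMI"})


class TestConstraints:
    def test_study_constraints_hold_on_learned_structure(self):
        report = validate_constraints(study.bic_dag(), study.study_constraints())
        assert report.ok

    def test_missing_whitelist_arc_is_listed(self):
        empty = DAG(study.VARIABLE_NAMES, [])
        report = validate_constraints(
            empty, ConstraintSet(whitelist=frozenset({("ALB", "NUTR")}))
        )
        assert not report.ok
        assert report.missing_whitelist == (("ALB", "NUTR"),)

    def test_present_blacklist_arc_is_listed(self):
        dag = DAG(["A", "B"], [("A", "B")])
        report = validate_constraints(dag, ConstraintSet(blacklist=frozenset({("A", "B")})))
        assert report.present_blacklist == (("A", "B"),)

    def test_overlapping_lists_rejected(self):
        with pytest.raises(GraphError):
            ConstraintSet(frozenset({("A", "B")}), frozenset({("A", "B")}))

    def test_cyclic_whitelist_rejected(self):
        with pytest.raises(GraphError):
            ConstraintSet(whitelist=frozenset({("A", "B"), ("B", "A")}))

    def test_csv_round_trip(self, tmp_path):
        cs = study.study_constraints()
        path = tmp_path / "constraints.csv"
        cs.to_csv(path)
        back = ConstraintSet.from_csv(path)
        assert back == cs


class TestDotSerialization:
    def test_round_trip_preserves_structure(self):
        dag = study.knowledge_dag()
        back = from_dot(to_dot(dag))
        assert back == dag

    def test_empty_graph_keeps_isolated_nodes(self):
        dag = DAG(study.VARIABLE_NAMES, [])
        back = from_dot(to_dot(dag))
        assert set(back.nodes) == set(study.VARIABLE_NAMES)
        assert back.arcs == frozenset()

    def test_annotations_appear_as_labels(self):
        dag = study.bic_dag()
        text = to_dot(dag, {("NUTR", "HRA"): "**"})
        assert '"NUTR" -> "HRA" [label="**"];' in text

    def test_annotation_on_absent_arc_rejected(self):
        with pytest.raises(GraphError):
            to_dot(study.bic_dag(), {("HRA", "NUTR"): "**"})
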