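"""CPT fitting, exact evidence queries, conditional MI, pruning, exogeneity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from causalattrib import (
    BinaryPanel,
    ConfigError,
    DiscreteBayesNetwork,
    UndefinedProbabilityError,
    check_exogeneity,
    conditional_mutual_information,
    conditional_outcome_prob,
    fit_cpts,
    make_dag,
    prune_parents,
    query_marginal,
)
from causalattrib.network import cpts_to_frame, read_edgelist, write_edgelist
from conftest import brute_force_cmi, random_panel


class TestDag:
    def test_cycle_rejected(self):
        with pytest.raises(ConfigError):
            make_dag(["A", "B"], [("A", "B"), ("B", "A")])

    def test_arc_to_unknown_node_rejected(self):
        with pytest.raises(ConfigError):
            make_dag(["A"], [("A", "B")])

    def test_edgelist_round_trip(self, tmp_path):
        dag = make_dag(["X", "Z", "Y", "lonely"], [("X", "Y"), ("Z", "Y")])
        path = tmp_path / "dag.tsv"
        write_edgelist(dag, path)
        back = read_edgelist(path)
        assert set(back.nodes) == set(dag.nodes)
        assert set(back.edges) == set(dag.edges)


class TestFitCpts:
    def test_single_arc_hand_enumeration(self, four_unit_panel):
        cpts = fit_cpts(make_dag(["X", "Y"], [("X", "Y")]), four_unit_panel)
        assert cpts["Y"].table == {(1,): 0.75, (0,): 0.5}
        assert cpts["X"].table[()] == 0.5  # marginal of the root

    def test_support_sums_to_total_weight(self):
        rng = np.random.default_rng(0)
        panel = random_panel(rng, 10, ["A", "B"])
        cpts = fit_cpts(make_dag(["A", "B", "Y"], [("A", "Y"), ("B", "Y")]), panel)
        assert sum(cpts["Y"].support.values()) == panel.total_weight

    def test_unobserved_configuration_flagged_empty(self):
        frame = pd.DataFrame({
            "unit_id": list("abc"),
            "A": [0, 0, 1], "B": [0, 1, 0], "C": [0, 0, 0],
            "Y": [0, 1, 1], "weight": [1, 1, 1],
        })
        panel = BinaryPanel(frame, ["A", "B", "C"], "Y")
        cpts = fit_cpts(make_dag(["A", "B", "C", "Y"],
                                 [("A", "Y"), ("B", "Y"), ("C", "Y")]), panel)
        assert cpts["Y"].table[(1, 1, 1)] is None
        assert cpts["Y"].support[(1, 1, 1)] == 0.0

    def test_node_absent_from_panel_rejected(self, four_unit_panel):
        with pytest.raises(ConfigError):
            fit_cpts(make_dag(["X", "Q", "Y"], [("X", "Y"), ("Q", "Y")]), four_unit_panel)


class TestQueryMarginal:
    def test_equals_conditional_outcome_prob(self, four_unit_panel):
        dag = make_dag(["X", "Y"], [("X", "Y")])
        cpts = fit_cpts(dag, four_unit_panel)
        for x in (0, 1):
            direct, _ = conditional_outcome_prob(four_unit_panel, ["X"], x)
            assert query_marginal(dag, cpts, {"X": x}, "Y") == direct

    def test_equivalence_on_random_panels(self):
        """Evidence on the outcome's parents reproduces raw weighted proportions."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            cols = ["A", "B"]
            panel = random_panel(rng, int(rng.integers(4, 16)), cols)
            dag = make_dag([*cols, "Y"], [(c, "Y") for c in cols])
            cpts = fit_cpts(dag, panel)
            for a, b in itertools.product((0, 1), repeat=2):
                try:
                    direct, _ = conditional_outcome_prob(panel, ["A"], a, {"B": b})
                except UndefinedProbabilityError:
                    continue
                got = query_marginal(dag, cpts, {"A": a, "B": b}, "Y")
                assert got == pytest.approx(direct, abs=1e-12)

    def test_marginalizes_unassigned_parent(self):
        """Evidence on one of two parents sums the other out by its marginal."""
        rng = np.random.default_rng(5)
        panel = random_panel(rng, 12, ["A", "B"])
        dag = make_dag(["A", "B", "Y"], [("A", "Y"), ("B", "Y")])
        cpts = fit_cpts(dag, panel)
        try:
            got = query_marginal(dag, cpts, {"A": 1}, "Y")
        except UndefinedProbabilityError:
            pytest.skip("draw produced an unsupported configuration")
        # independent-parents factorization oracle
        pb = cpts["B"].table[()]
        expected = (cpts["Y"].table[(1, 0)] * (1 - pb) + cpts["Y"].table[(1, 1)] * pb)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_evidence_on_target_rejected(self, four_unit_panel):
        dag = make_dag(["X", "Y"], [("X", "Y")])
        cpts = fit_cpts(dag, four_unit_panel)
        with pytest.raises(ConfigError):
            query_marginal(dag, cpts, {"Y": 1}, "Y")

    def test_reachable_empty_cell_is_undefined(self):
        frame = pd.DataFrame({"unit_id": ["a", "b"], "X": [0, 0],
                              "Y": [0, 1], "weight": [1, 1]})
        panel = BinaryPanel(frame, ["X"], "Y")
        dag = make_dag(["X", "Y"], [("X", "Y")])
        cpts = fit_cpts(dag, panel)
        with pytest.raises(UndefinedProbabilityError):
            query_marginal(dag, cpts, {"X": 1}, "Y")


class TestConditionalMutualInformation:
    def test_independent_product_panel_gives_zero(self):
        rows = []
        for a, y in itertools.product((0, 1), repeat=2):
            rows.append({"unit_id": f"u{a}{y}", "A": a, "Y": y, "weight": 3})
        panel = BinaryPanel(pd.DataFrame(rows), ["A"], "Y")
        assert conditional_mutual_information(panel, "A", "Y") == 0.0

    def test_identical_column_gives_entropy_of_target(self):
        frame = pd.DataFrame({"unit_id": ["a", "b"], "A": [1, 0],
                              "Y": [1, 0], "weight": [3, 1]})
        panel = BinaryPanel(frame, ["A"], "Y")
        p = 0.75
        entropy = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        got = conditional_mutual_information(panel, "A", "Y")
        assert got == pytest.approx(entropy, abs=1e-12)

    def test_factor_equal_target_rejected(self, four_unit_panel):
        with pytest.raises(ConfigError):
            conditional_mutual_information(four_unit_panel, "Y", "Y")

    def test_matches_brute_force_triple_sum(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            panel = random_panel(rng, int(rng.integers(4, 17)), ["A", "B", "C"])
            got = conditional_mutual_information(panel, "A", "Y", ["B"])
            oracle = brute_force_cmi(panel, "A", "Y", ["B"])
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_symmetric_in_factor_and_target(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            panel = random_panel(rng, 10, ["A", "B"])
            ab = conditional_mutual_information(panel, "A", "B", ["Y"])
            ba = conditional_mutual_information(panel, "B", "A", ["Y"])
            assert ab == pytest.approx(ba, abs=1e-12)

    def test_non_negative(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            panel = random_panel(rng, 8, ["A", "B"])
            assert conditional_mutual_information(panel, "A", "Y", ["B"]) >= 0.0


def _fire_analog_panel() -> BinaryPanel:
    """Panel where the fire factor is uninformative noise with unobserved
    joint configurations.

    The outcome is a deterministic OR of linear, cutblock, and evi, so
    given those three the fire column carries zero conditional mutual
    information, while each of the other parents is strictly informative.
    Several (parents, fire) configurations are never observed, leaving
    empty CPT cells that trigger pruning.
    """
    rows = []
    # single-exposure and null configs observed under both fire states
    doubled = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    single = [(1, 1, 0), (1, 0, 1), (0, 1, 1)]  # (1,1,1) never observed
    i = 0
    for linear, cutblock, evi in doubled:
        for fire in (0, 1):
            rows.append({"unit_id": f"u{i}", "linear": linear, "cutblock": cutblock,
                         "evi": evi, "fire": fire,
                         "Y": int(linear or cutblock or evi), "weight": 1})
            i += 1
    for linear, cutblock, evi in single:
        rows.append({"unit_id": f"u{i}", "linear": linear, "cutblock": cutblock,
                     "evi": evi, "fire": 0,
                     "Y": int(linear or cutblock or evi), "weight": 1})
        i += 1
    return BinaryPanel(pd.DataFrame(rows), ["linear", "cutblock", "evi", "fire"], "Y")


class TestPruneParents:
    def test_fire_analog_removed_first(self):
        panel = _fire_analog_panel()
        dag = make_dag(["linear", "cutblock", "evi", "fire", "Y"],
                       [(p, "Y") for p in ("linear", "cutblock", "evi", "fire")])
        pruned, removals = prune_parents(dag, panel, "Y")
        assert removals, "pruning should remove at least one parent"
        assert removals[0][0] == "fire"
        assert ("fire", "Y") not in pruned.edges

    def test_fully_supported_cpt_unchanged(self, four_unit_panel):
        dag = make_dag(["X", "Y"], [("X", "Y")])
        pruned, removals = prune_parents(dag, four_unit_panel, "Y")
        assert removals == []
        assert set(pruned.edges) == {("X", "Y")}

    def test_tie_break_is_lexicographic(self):
        # two parents symmetric by construction: identical columns, CMI tie
        frame = pd.DataFrame({
            "unit_id": ["a", "b"],
            "A": [0, 1], "B": [0, 1],
            "Y": [0, 1], "weight": [1, 1],
        })
        panel = BinaryPanel(frame, ["A", "B"], "Y")
        dag = make_dag(["A", "B", "Y"], [("A", "Y"), ("B", "Y")])
        pruned, removals = prune_parents(dag, panel, "Y")
        # (0,1) and (1,0) configs unobserved; both parents carry equal information
        assert removals[0][0] == "A"

    def test_never_removes_last_parent(self):
        frame = pd.DataFrame({"unit_id": ["a"], "A": [1], "Y": [1], "weight": [1]})
        panel = BinaryPanel(frame, ["A"], "Y")
        dag = make_dag(["A", "Y"], [("A", "Y")])
        pruned, removals = prune_parents(dag, panel, "A" if False else "Y")
        assert ("A", "Y") in pruned.edges and removals == []

    def test_terminates_within_parent_count(self):
        panel = _fire_analog_panel()
        dag = make_dag(["linear", "cutblock", "evi", "fire", "Y"],
                       [(p, "Y") for p in ("linear", "cutblock", "evi", "fire")])
        _, removals = prune_parents(dag, panel, "Y")
        assert len(removals) <= 3


class TestExogeneity:
    def test_aggregate_model_exposure_is_exogenous(self):
        dag = make_dag(["disturbance", "Y"], [("disturbance", "Y")])
        assert check_exogeneity(dag, ["disturbance"])

    def test_incoming_arc_breaks_exogeneity(self):
        dag = make_dag(["evi", "linear", "Y"], [("evi", "linear"), ("linear", "Y")])
        assert not check_exogeneity(dag, ["linear"])

    def test_empty_exposure_set_vacuously_true(self):
        dag = make_dag(["X", "Y"], [("X", "Y")])
        assert check_exogeneity(dag, [])


class TestDiscreteBayesNetworkEstimator:
    def test_fit_query_prune_workflow(self):
        panel = _fire_analog_panel()
        net = DiscreteBayesNetwork(
            arcs=[(p, "Y") for p in ("linear", "cutblock", "evi", "fire")]).fit(panel)
        net.prune("Y")
        assert net.pruning_log_ and net.pruning_log_[0][0] == "fire"
        assert net.exogenous(["linear", "cutblock"])
        # any unit with high linear density is declining in this construction
        assert net.query({"linear": 1}, "Y") == 1.0

    def test_cpt_export_shape(self, four_unit_panel):
        net = DiscreteBayesNetwork(arcs=[("X", "Y")]).fit(four_unit_panel)
        frame = cpts_to_frame(net.cpts_)
        assert list(frame.columns) == ["child", "parents", "configuration",
                                       "probability", "support"]
        assert len(frame) == 3  # X root (1 row) + Y with 2 configs
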