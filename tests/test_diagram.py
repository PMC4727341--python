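"""Core influence-diagram representation: validation, information
partition, reachability, super-value folding, serialization."""

import numpy as np
import pytest

import mediastage as ms
from mediastage.diagram import (
    ProbabilityTable, SuperValueSpec, UtilityTable, Variable,
    folded_utility_tables, supervalue_utility,
)
from mediastage.errors import CapacityError
from mediastage.synthetic import RandomIdConfig, random_influence_diagram, toy_two_decision_id


def _index_all(diag, rng):
    """A random full configuration of chance and decision variables."""
    return {v: diag.states(v)[rng.integers(diag.card(v))]
            for v in diag.global_order()}


class TestValidate:
    def test_well_formed_models_have_no_diagnostics(self, eff_diagram):
        assert ms.validate(eff_diagram) == []
        assert ms.validate(toy_two_decision_id()) == []

    def test_unnormalized_cpt_is_reported(self):
        diag = toy_two_decision_id()
        diag.cpts["X"] = ProbabilityTable("X", (), np.array([0.1, 0.8]))
        msgs = ms.validate(diag)
        assert len(msgs) == 1 and "sum to 1" in msgs[0]

    def test_disconnected_decisions_are_reported(self):
        # two decisions with no arc chain between them
        diag = ms.InfluenceDiagram(
            variables=[Variable("A", "decision", ("a0", "a1")),
                       Variable("B", "decision", ("b0", "b1")),
                       Variable("X", "chance", ("x0", "x1")),
                       Variable("U", "utility")],
            decision_order=["A", "B"],
            observations={"A": (), "B": ()},
            cpts=[ProbabilityTable("X", (), np.array([0.5, 0.5]))],
            utilities=[UtilityTable("U", ("B",), np.array([1.0, 2.0]))],
            root_value="U",
        )
        msgs = ms.validate(diag)
        assert len(msgs) == 1 and "path" in msgs[0]

    def test_seeded_cpt_corruption_is_caught(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            diag = random_influence_diagram(RandomIdConfig(seed=seed))
            assert ms.validate(diag) == []
            victim = rng.choice(list(diag.cpts))
            t = diag.cpts[victim].table.copy()
            flat_idx = rng.integers(t.size)
            t.ravel()[flat_idx] += 0.37
            diag.cpts[victim] = ProbabilityTable(victim, diag.cpts[victim].parents, t)
            assert any("sum to 1" in m or "[0, 1]" in m for m in ms.validate(diag))


class TestInformationPartition:
    def test_toy_partition(self):
        diag = toy_two_decision_id()
        assert ms.information_partition(diag) == [(), ("Y",), ("X",)]

    def test_staging_partition(self, eff_diagram):
        part = [set(b) for b in ms.information_partition(eff_diagram)]
        assert part == [{"CT_scan"}, {"TBNA"}, {"PET"}, {"EBUS", "EUS"},
                        {"MED"}, {"MED_Sv", "N2_N3"}]

    def test_single_decision_no_observations(self):
        diag = ms.InfluenceDiagram(
            variables=[Variable("D", "decision", ("d0", "d1")),
                       Variable("X", "chance", ("x0", "x1")),
                       Variable("U", "utility")],
            decision_order=["D"],
            observations={"D": ()},
            cpts=[ProbabilityTable("X", (), np.array([0.2, 0.8]))],
            utilities=[UtilityTable("U", ("D", "X"), np.ones((2, 2)))],
            root_value="U",
        )
        assert ms.information_partition(diag) == [(), ("X",)]

    def test_partition_ignores_declaration_order(self):
        base = toy_two_decision_id()
        shuffled = ms.InfluenceDiagram(
            variables=list(reversed(list(base.variables.values()))),
            decision_order=base.decision_order,
            observations=base.observations,
            cpts=list(base.cpts.values()),
            utilities=list(base.utilities.values()),
            supervalues=list(base.supervalues.values()),
            root_value=base.root_value,
        )
        a = [set(b) for b in ms.information_partition(base)]
        b = [set(b) for b in ms.information_partition(shuffled)]
        assert a == b


class TestConsistentConfigurations:
    def test_staging_pet_decision_has_six(self, eff_diagram):
        cfgs = ms.consistent_configurations(eff_diagram, "Dec_PET")
        assert len(cfgs) == 6
        assert ("positive", "no", "positive") not in cfgs
        assert ("positive", "no", "no_result") in cfgs

    def test_toy_treatment_decision(self):
        cfgs = ms.consistent_configurations(toy_two_decision_id(), "D")
        assert cfgs == {("yes", "positive"), ("yes", "negative"), ("no", "no_result")}

    def test_first_decision_single_empty_configuration(self):
        cfgs = ms.consistent_configurations(toy_two_decision_id(), "T")
        assert cfgs == {()}


class TestFoldSupervalue:
    def test_survival_product_entry(self, eff_diagram):
        folded = ms.fold_supervalue(eff_diagram)
        net = folded.utilities["Net_QALE"]
        assert set(net.parents) == {"Treatment", "N2_N3", "MED_Sv"}
        idx = tuple(eff_diagram.state_index(p, dict(
            Treatment="thoracotomy", N2_N3="negative", MED_Sv="yes")[p])
            for p in net.parents)
        assert net.table[idx] == pytest.approx(5.75 * 1.0 * 0.978, abs=1e-12)

    def test_single_term_sum_is_identity(self):
        diag = toy_two_decision_id()
        diag.supervalues["U"] = SuperValueSpec("U", "sum", [("U2", 1)])
        folded = ms.fold_supervalue(diag)
        np.testing.assert_array_equal(folded.utilities["U2"].table,
                                      diag.utilities["U2"].table)

    def test_zero_lambda_inverse_zeroes_cost_terms(self, eff_diagram):
        folded = ms.fold_supervalue(eff_diagram)
        cost_terms = [t for n, t in folded.utilities.items()
                      if n.startswith("Weighted_Econ_Cost")]
        assert len(cost_terms) == 7
        for t in cost_terms:
            assert np.all(t.table == 0.0)

    def test_capacity_bound_is_enforced(self, eff_diagram):
        with pytest.raises(CapacityError):
            ms.fold_supervalue(eff_diagram, max_table_size=2)

    @pytest.mark.parametrize("seed", range(12))
    def test_folded_sum_matches_recursive_supervalue(self, seed):
        diag = random_influence_diagram(RandomIdConfig(seed=seed, n_utilities=3))
        terms = folded_utility_tables(diag)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(20):
            cfg = _index_all(diag, rng)
            total = sum(
                t.table[tuple(diag.state_index(p, cfg[p]) for p in t.parents)]
                for t in terms)
            assert total == pytest.approx(supervalue_utility(diag, cfg), abs=1e-9)

    @pytest.mark.parametrize("lam_inv", [0.0, 1 / 30000])
    def test_folding_preserves_staging_utility(self, params, lam_inv):
        diag = ms.build_influence_diagram(
            params, ms.CostEffectivenessSettings(lam_inv))
        terms = folded_utility_tables(diag)
        rng = np.random.default_rng(3)
        for _ in range(30):
            cfg = _index_all(diag, rng)
            total = sum(
                t.table[tuple(diag.state_index(p, cfg[p]) for p in t.parents)]
                for t in terms)
            assert total == pytest.approx(supervalue_utility(diag, cfg), abs=1e-9)


class TestJsonRoundTrip:
    @pytest.mark.parametrize("make", [
        toy_two_decision_id,
        lambda: random_influence_diagram(RandomIdConfig(seed=11, n_utilities=3)),
    ])
    def test_round_trip_is_bit_exact(self, make):
        diag = make()
        text = ms.to_json(diag)
        back = ms.from_json(text)
        assert ms.to_json(back) == text
        for name, t in diag.cpts.items():
            np.testing.assert_array_equal(back.cpts[name].table, t.table)
        for name, t in diag.utilities.items():
            np.testing.assert_array_equal(back.utilities[name].table, t.table)
        assert back.decision_order == diag.decision_order
        assert back.observations == diag.observations

    def test_staging_model_round_trips(self, nhb_diagram):
        text = ms.to_json(nhb_diagram)
        back = ms.from_json(text)
        assert ms.to_json(back) == text
        r1 = ms.evaluate_variable_elimination(nhb_diagram)
        r2 = ms.evaluate_variable_elimination(back)
        assert r1.meu == r2.meu
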