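"""Evaluation engines: variable elimination against the symmetric-tree
oracle, imposed strategies, posterior inference, and decision-theoretic
properties of the staging model."""

import numpy as np
import pytest

import mediastage as ms
from mediastage.diagram import ProbabilityTable, UtilityTable, Variable
from mediastage.errors import DiagramError, InconsistentEvidenceError
from mediastage.synthetic import RandomIdConfig, random_influence_diagram, toy_two_decision_id


def single_decision_id(values=(3.0, 5.0)):
    return ms.InfluenceDiagram(
        variables=[Variable("D", "decision", ("a", "b")),
                   Variable("U", "utility")],
        decision_order=["D"],
        observations={"D": ()},
        cpts=[],
        utilities=[UtilityTable("U", ("D",), np.array(values))],
        root_value="U",
    )


class TestTrivialDiagrams:
    def test_single_decision_picks_the_better_option(self):
        res = ms.evaluate_variable_elimination(single_decision_id((3.0, 5.0)))
        assert res.meu == 5.0
        assert int(res.policies["D"].table) == 1

    def test_single_chance_node_gives_the_expectation(self):
        diag = ms.InfluenceDiagram(
            variables=[Variable("D", "decision", ("only",)),
                       Variable("X", "chance", ("x0", "x1")),
                       Variable("U", "utility")],
            decision_order=["D"],
            observations={"D": ()},
            cpts=[ProbabilityTable("X", (), np.array([0.25, 0.75]))],
            utilities=[UtilityTable("U", ("X",), np.array([4.0, 8.0]))],
            root_value="U",
        )
        for evaluate in (ms.evaluate_variable_elimination, ms.evaluate_brute_force):
            assert evaluate(diag).meu == pytest.approx(7.0, abs=1e-12)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(40))
    def test_variable_elimination_matches_symmetric_tree(self, seed):
        diag = random_influence_diagram(RandomIdConfig(
            n_chance=4, n_decisions=3, max_states=3, max_parents=2,
            n_utilities=3, seed=seed))
        ve = ms.evaluate_variable_elimination(diag)
        bf = ms.evaluate_brute_force(diag)
        assert ve.meu == pytest.approx(bf.meu, abs=1e-9)
        for d in diag.decision_order:
            np.testing.assert_array_equal(ve.policies[d].table, bf.policies[d].table)

    def test_toy_diagram_agreement(self):
        diag = toy_two_decision_id(p_disease=0.1, sens=0.9, spec=0.9,
                                   u_treat_sick=80, u_treat_healthy=95,
                                   u_no_treat_sick=20, u_no_treat_healthy=100,
                                   test_morbidity=1.0)
        ve = ms.evaluate_variable_elimination(diag)
        bf = ms.evaluate_brute_force(diag)
        assert ve.meu == pytest.approx(bf.meu, abs=1e-12)
        for d in diag.decision_order:
            np.testing.assert_array_equal(ve.policies[d].table, bf.policies[d].table)

    def test_staging_model_agreement(self, nhb_diagram, nhb_result):
        bf = ms.evaluate_brute_force(nhb_diagram)
        assert nhb_result.meu == pytest.approx(bf.meu, abs=1e-9)
        for d in nhb_diagram.decision_order:
            np.testing.assert_array_equal(nhb_result.policies[d].table,
                                          bf.policies[d].table)


class TestToyDecisionTheory:
    def test_useless_test_is_skipped(self):
        diag = toy_two_decision_id(sens=0.5, spec=0.5, test_morbidity=0.5)
        res = ms.evaluate_variable_elimination(diag)
        assert int(res.policies["T"].table) == 0  # "no"

    def test_perfect_free_test_achieves_clairvoyant_value(self):
        p = 0.1
        diag = toy_two_decision_id(p_disease=p, sens=1.0, spec=1.0,
                                   test_morbidity=0.0)
        res = ms.evaluate_variable_elimination(diag)
        clairvoyant = p * max(80, 20) + (1 - p) * max(95, 100)
        assert res.meu == pytest.approx(clairvoyant, abs=1e-12)


class TestImposedStrategies:
    def test_optimal_policies_reproduce_the_meu(self, nhb_diagram, nhb_result):
        eu = ms.expected_utility(nhb_diagram, nhb_result.policies)
        assert eu == pytest.approx(nhb_result.meu, abs=1e-9)

    def test_no_strategy_beats_the_meu(self, nhb_diagram, nhb_result):
        rng = np.random.default_rng(0)
        for _ in range(5):
            policies = {
                d: ms.Policy(d, pol.predecessors,
                             rng.integers(0, nhb_diagram.card(d), size=pol.table.shape))
                for d, pol in nhb_result.policies.items()
            }
            assert ms.expected_utility(nhb_diagram, policies) <= nhb_result.meu + 1e-9

    def test_never_testing_is_feasible_but_not_better(self, nhb_diagram, nhb_result):
        policies = {
            d: ms.Policy(d, pol.predecessors, np.zeros_like(pol.table))
            for d, pol in nhb_result.policies.items()
        }
        # option 0 of every decision is no/no_test/no_treatment
        eu = ms.expected_utility(nhb_diagram, policies)
        assert eu <= nhb_result.meu - 1e-6

    def test_partial_policy_is_rejected(self, nhb_diagram, nhb_result):
        partial = {d: p for d, p in nhb_result.policies.items() if d != "Dec_MED"}
        with pytest.raises(DiagramError):
            ms.expected_utility(nhb_diagram, partial)


class TestPosterior:
    def test_prior_equals_prevalence(self, eff_diagram, eff_result):
        post = ms.posterior_probability(eff_diagram, eff_result.policies, {}, "N2_N3")
        assert post["positive"] == pytest.approx(0.30, abs=1e-12)

    def test_positive_ct_raises_the_probability(self, eff_diagram, eff_result):
        post = ms.posterior_probability(eff_diagram, eff_result.policies,
                                        {"CT_scan": "positive"}, "N2_N3")
        # independent Bayes: p*sens / (p*sens + (1-p)*(1-spec))
        expected = 0.3 * 0.55 / (0.3 * 0.55 + 0.7 * 0.19)
        assert post["positive"] == pytest.approx(expected, abs=1e-12)
        assert post["positive"] > 0.30

    def test_contradictory_findings_lower_the_probability(self, eff_diagram, eff_result):
        """A positive CT scan followed by a negative TBNA ends up *below*
        the prior: the TBNA's negative likelihood ratio dominates."""
        post = ms.posterior_probability(
            eff_diagram, eff_result.policies,
            {"CT_scan": "positive", "Dec_TBNA": "yes", "TBNA": "negative"},
            "N2_N3")
        # two-step Bayes with the reference means
        num = 0.3 * 0.55 * (1 - 0.78)
        den = num + 0.7 * 0.19 * 0.995
        assert post["positive"] == pytest.approx(num / den, abs=1e-12)
        assert post["positive"] == pytest.approx(0.2153, abs=5e-4)
        assert post["positive"] < 0.30

    def test_impossible_evidence_is_an_error(self, eff_diagram, eff_result):
        with pytest.raises(InconsistentEvidenceError):
            ms.posterior_probability(
                eff_diagram, eff_result.policies,
                {"Dec_TBNA": "no", "TBNA": "positive"}, "N2_N3")


class TestCriterionProperties:
    def test_costs_are_irrelevant_under_effectiveness(self, params, eff_result):
        """With λ⁻¹ = 0 the MEU and all policies are invariant to arbitrary
        cost perturbation."""
        inflated = params.with_values({
            pid: params.value(pid) * 7.3 + 11.0
            for pid in params.ids() if pid.startswith("cost_")})
        diag = ms.build_influence_diagram(inflated, ms.CostEffectivenessSettings(0.0))
        res = ms.evaluate_variable_elimination(diag)
        assert res.meu == pytest.approx(eff_result.meu, abs=1e-12)
        for d in diag.decision_order:
            np.testing.assert_array_equal(res.policies[d].table,
                                          eff_result.policies[d].table)

    def test_nhb_decreases_with_lambda_inverse_for_fixed_policies(self, params, nhb_result):
        lam_invs = [0.0, 1 / 60000, 1 / 30000, 1 / 10000]
        values = []
        for li in lam_invs:
            diag = ms.build_influence_diagram(params, ms.CostEffectivenessSettings(li))
            values.append(ms.expected_utility(diag, nhb_result.policies))
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("test", ["TBNA", "EBUS", "MED"])
    def test_better_tests_never_lower_the_meu(self, params, nhb_result, test):
        """Raising both sensitivity and specificity refines the information
        (and changes nothing else), so the MEU cannot drop."""
        key = test.lower()
        better = params.with_values({
            pid: min(params.value(pid) + 0.004, 1.0)
            for pid in (f"sens_{key}_ct_pos", f"spec_{key}_ct_pos",
                        f"sens_{key}_ct_neg", f"spec_{key}_ct_neg")})
        diag = ms.build_influence_diagram(better, ms.settings_for("nhb", better))
        res = ms.evaluate_variable_elimination(diag)
        assert res.meu >= nhb_result.meu - 1e-9
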