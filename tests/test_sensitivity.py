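"""Sensitivity analyses: EVPI, strategy-change thresholds, and per-decision
change probabilities, checked on closed-form synthetic models and on the
staging model."""

import numpy as np
import pytest

import mediastage as ms
from mediastage.diagram import UtilityTable, Variable
from mediastage.elicitation import uniform_from_interval
from mediastage.errors import MediastageError
from mediastage.model import Parameter, ParameterSet
from mediastage.sensitivity import (
    decision_change_probability, evpi_per_parameter, make_model_builder,
    threshold_intervals,
)


def linear_choice_set(mean, lower, upper):
    """One parameter θ with a uniform second-order distribution."""
    return ParameterSet([Parameter(
        id="theta", mean=mean, value=mean,
        second_order=uniform_from_interval(lower, upper),
        interval=(0.0, 1.0))])


def linear_choice_builder(alternative=0.5):
    """A one-decision model: option 'a' pays θ, option 'b' pays a constant.

    The optimal strategy flips exactly at θ = alternative, so thresholds
    and EVPI have closed forms.
    """
    def build(ps):
        return ms.InfluenceDiagram(
            variables=[Variable("D", "decision", ("a", "b")),
                       Variable("U", "utility")],
            decision_order=["D"],
            observations={"D": ()},
            cpts=[],
            utilities=[UtilityTable("U", ("D",),
                                    np.array([ps.value("theta"), alternative]))],
            root_value="U",
        )
    return build


class TestEvpi:
    def test_degenerate_parameter_has_exactly_zero_evpi(self, params):
        est = evpi_per_parameter(make_model_builder("nhb"), params, "cost_pet",
                                 n_samples=10, seed=0)
        assert est.evpi == 0.0 and est.std_error == 0.0

    def test_closed_form_linear_model(self):
        # EVPI = E[(θ - 0.5)+] = w/4 for θ ~ U(0.5 - w, 0.5 + w)
        for w, seed in ((0.08, 1), (0.16, 2), (0.24, 3)):
            ps = linear_choice_set(0.5, 0.5 - w, 0.5 + w)
            est = evpi_per_parameter(linear_choice_builder(), ps, "theta",
                                     n_samples=800, seed=seed)
            assert est.evpi == pytest.approx(w / 4, abs=4 * est.std_error + 1e-12)

    def test_evpi_grows_under_mean_preserving_spread(self):
        """For the linear-choice model, widening the uniform spread around
        the kink strictly increases the value of information."""
        values = []
        for w in (0.05, 0.15, 0.30):
            ps = linear_choice_set(0.5, 0.5 - w, 0.5 + w)
            est = evpi_per_parameter(linear_choice_builder(), ps, "theta",
                                     n_samples=800, seed=9)
            values.append(est.evpi)
        assert values[0] < values[1] < values[2]

    @pytest.mark.parametrize("pid", ["prevalence_n2_n3", "qale_chemoradio_pos"])
    def test_staging_evpi_is_nonnegative(self, params, pid):
        est = evpi_per_parameter(make_model_builder("nhb"), params, pid,
                                 n_samples=150, seed=4)
        assert est.evpi >= -3 * est.std_error - 1e-12
        assert est.n_strategies >= 1

    def test_zero_samples_is_an_error(self, params):
        with pytest.raises(MediastageError):
            evpi_per_parameter(make_model_builder("nhb"), params,
                               "prevalence_n2_n3", n_samples=0, seed=0)


class TestThresholds:
    def test_closed_form_crossing_is_recovered_to_grid_resolution(self):
        ps = linear_choice_set(0.6, 0.0, 1.0)
        scan = threshold_intervals(linear_choice_builder(0.5), ps, "theta",
                                   grid_step=0.01, scan_range=(0.0, 1.0))
        # below 0.5 the constant option wins; the exact tie at 0.5 keeps
        # the reference option by the first-option tie-break
        assert scan.largest_change_value == pytest.approx(0.49)
        assert scan.stable_containing(0.6) is not None
        assert scan.stable_containing(0.3) is None

    def test_parameter_without_influence_keeps_the_full_range(self, params):
        """Under the effectiveness-only criterion a cost cannot move any
        decision: the whole scanned range is one stable interval."""
        scan = threshold_intervals(make_model_builder("effectiveness"), params,
                                   "cost_tbna", grid_step=100.0,
                                   scan_range=(0.0, 1000.0))
        assert scan.largest_change_value is None
        assert scan.stable_intervals == [(0.0, 1000.0)]

    def test_reference_mean_lies_in_a_stable_interval(self, params):
        scan = threshold_intervals(make_model_builder("nhb"), params,
                                   "sens_ct", grid_step=0.05)
        assert scan.stable_containing(params.value("sens_ct")) is not None


class TestChangeProbability:
    def test_degenerate_parameter_never_changes_the_strategy(self, params):
        cp = decision_change_probability(make_model_builder("nhb"), params,
                                         "cost_ebus", n_samples=10, seed=0)
        assert cp.any_change == 0.0
        assert all(v == 0.0 for v in cp.per_decision.values())

    def test_probabilities_are_valid_and_seed_stable(self, params):
        builder = make_model_builder("nhb")
        a = decision_change_probability(builder, params, "qale_chemoradio_pos",
                                        n_samples=150, seed=1, restrict="reachable")
        b = decision_change_probability(builder, params, "qale_chemoradio_pos",
                                        n_samples=150, seed=2, restrict="reachable")
        for cp in (a, b):
            assert 0.0 <= cp.any_change <= 1.0
            assert all(0.0 <= v <= 1.0 for v in cp.per_decision.values())
            assert cp.any_change >= max(cp.per_decision.values()) - 1e-12
        # estimator consistency: two seeds agree within binomial MC error
        se = np.sqrt(0.5 * 0.5 * (1 / 150 + 1 / 150))
        assert abs(a.any_change - b.any_change) < 4 * se

    def test_metastasis_qale_parameters_dominate(self, params):
        """The QALE of treated patients with nodal metastasis drives the
        strategy hardest; degenerate and morbidity parameters do nothing,
        and the most affected decisions are the endoscopy and TBNA choices."""
        builder = make_model_builder("nhb")
        probs = {}
        for pid in ("qale_chemoradio_pos", "qale_thoracotomy_pos",
                    "prevalence_n2_n3", "morb_tbna"):
            probs[pid] = decision_change_probability(
                builder, params, pid, n_samples=120, seed=5, restrict="reachable")
        ranked = sorted(probs, key=lambda p: -probs[p].any_change)
        assert set(ranked[:2]) == {"qale_chemoradio_pos", "qale_thoracotomy_pos"}
        assert probs["morb_tbna"].any_change == 0.0
        top = probs["qale_chemoradio_pos"].per_decision
        assert top["Dec_EBUS_EUS"] == max(top.values())
        assert top["Dec_TBNA"] > 0.0

    def test_unknown_decision_is_rejected(self, params):
        with pytest.raises(MediastageError):
            decision_change_probability(make_model_builder("nhb"), params,
                                        "prevalence_n2_n3", decision="Dec_XYZ",
                                        n_samples=5)

    def test_named_decision_returns_its_probability(self, params):
        p = decision_change_probability(make_model_builder("nhb"), params,
                                        "cost_ebus", decision="Dec_TBNA",
                                        n_samples=5, seed=0)
        assert p == 0.0


class TestPurity:
    def test_analyses_do_not_mutate_the_reference_set(self, params):
        before = {p: params.value(p) for p in params.ids()}
        builder = make_model_builder("nhb")
        evpi_per_parameter(builder, params, "prevalence_n2_n3", n_samples=20, seed=0)
        threshold_intervals(builder, params, "sens_ct", grid_step=0.2)
        decision_change_probability(builder, params, "sens_ct", n_samples=10, seed=0)
        assert {p: params.value(p) for p in params.ids()} == before
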