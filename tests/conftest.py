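import pytest

import mediastage as ms


@pytest.fixture(scope="session")
def params():
    return ms.reference_parameter_set()


@pytest.fixture(scope="session")
def eff_diagram(params):
    """Reference model under the effectiveness-only criterion."""
    return ms.build_influence_diagram(params, ms.CostEffectivenessSettings(0.0))


@pytest.fixture(scope="session")
def nhb_diagram(params):
    """Reference model under net health benefit at 30,000 EUR/QALY."""
    return ms.build_influence_diagram(params, ms.settings_for("nhb", params))


@pytest.fixture(scope="session")
def eff_result(eff_diagram):
    return ms.evaluate_variable_elimination(eff_diagram)


@pytest.fixture(scope="session")
def nhb_result(nhb_diagram):
    return ms.evaluate_variable_elimination(nhb_diagram)


@pytest.fixture(scope="session")
def eff_tree(eff_diagram, eff_result):
    return ms.build_strategy_tree(eff_diagram, eff_result)


@pytest.fixture(scope="session")
def nhb_tree(nhb_diagram, nhb_result):
    return ms.build_strategy_tree(nhb_diagram, nhb_result)
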