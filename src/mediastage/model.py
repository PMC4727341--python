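"""The mediastinal-staging influence diagram.

The model describes a patient with presumably operable NSCLC and no distant
metastases. Whether mediastinal lymph nodes are involved (binary ``N2_N3``,
prevalence 30 %) determines the best treatment, but is not directly
observable: a CT scan is always performed, after which the clinician decides
sequentially whether to perform TBNA, PET, endoscopic ultrasound (EBUS
and/or EUS, possibly combined in one session), and mediastinoscopy, each
with its own sensitivity/specificity (conditional on the CT result), QALY
morbidity and monetary cost, before choosing thoracotomy, chemoradiotherapy
or no treatment.

Utilities form three groups: total quality-adjusted life expectancy (the
survivors' QALE times mediastinoscopy survival times immediate treatment
survival, plus the negative test morbidities), total economic cost, and the
net-health-benefit root NHB = E - λ⁻¹·C. Setting λ⁻¹ = 0 recovers the
effectiveness-only criterion without touching the graph.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from . import elicitation
from .diagram import (
    CHANCE, DECISION, UTILITY,
    CostEffectivenessSettings, InfluenceDiagram, ProbabilityTable,
    SuperValueSpec, UtilityTable, Variable,
)
from .elicitation import SecondOrderSpec
from .errors import MediastageError

POSITIVE, NEGATIVE, NO_RESULT = "positive", "negative", "no_result"
TEST_STATES = (POSITIVE, NEGATIVE, NO_RESULT)

#: Treatment options, least invasive first (tie-break order).
TREATMENTS = ("no_treatment", "chemoradiotherapy", "thoracotomy")
#: Endoscopy options, no-test first.
ENDO_OPTIONS = ("no_test", "ebus", "eus", "ebus_eus")

EXPECTED_PARAMETER_COUNT = 46


@dataclass(frozen=True)
class Parameter:
    """One independent model parameter: reference mean plus second-order
    distribution, and the current value used when building the diagram."""

    id: str
    mean: float
    value: float
    second_order: SecondOrderSpec
    units: str = ""
    description: str = ""
    source_table: str = ""
    interval: tuple[float, float] | None = None

    def scan_range(self) -> tuple[float, float]:
        """Default range for threshold scans: the published interval,
        falling back to a central 95 % band, then to the support."""
        if self.interval is not None:
            return self.interval
        if self.second_order.is_degenerate():
            return (self.value, self.value)
        lo, hi = self.second_order.interval(0.95)
        return (float(lo), float(hi))


class ParameterSet:
    """An ordered, immutable collection of the model parameters."""

    def __init__(self, parameters):
        self.parameters: dict[str, Parameter] = {p.id: p for p in parameters}

    def __len__(self) -> int:
        return len(self.parameters)

    def __contains__(self, pid: str) -> bool:
        return pid in self.parameters

    def ids(self) -> list[str]:
        return list(self.parameters)

    def value(self, pid: str) -> float:
        return self.parameters[pid].value

    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        """A copy with the given parameter values replaced."""
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise KeyError(f"unknown parameter ids: {sorted(unknown)}")
        out = []
        for p in self.parameters.values():
            if p.id in updates:
                out.append(replace(p, value=float(updates[p.id])))
            else:
                out.append(p)
        return ParameterSet(out)

    def at_means(self) -> "ParameterSet":
        return ParameterSet([replace(p, value=p.mean) for p in self.parameters.values()])

    def provenance_hash(self) -> str:
        """SHA-256 over ids and current values, for report provenance."""
        doc = json.dumps({p.id: p.value for p in self.parameters.values()},
                         sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()

    def validate(self) -> list[str]:
        out = []
        if len(self.parameters) != EXPECTED_PARAMETER_COUNT:
            out.append(
                f"expected {EXPECTED_PARAMETER_COUNT} parameters, "
                f"got {len(self.parameters)}"
            )
        for p in self.parameters.values():
            if not math.isfinite(p.value):
                out.append(f"{p.id}: non-finite value")
            elif p.units == "probability" and not 0 <= p.value <= 1:
                out.append(f"{p.id}: probability outside [0, 1]")
            elif p.units in ("EUR", "QALY", "EUR/QALY") and p.value < 0:
                out.append(f"{p.id}: negative value")
        return out


def load_parameters(path=None) -> ParameterSet:
    """Load a parameter configuration file (YAML); defaults to the shipped
    reference file. Second-order fits are recomputed from the raw inputs."""
    if path is None:
        ref = importlib.resources.files("mediastage") / "data" / "reference_parameters.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    records = yaml.safe_load(text)
    params = []
    for rec in records:
        try:
            so = dict(rec["second_order"])
            method = so.pop("method")
            spec = elicitation.build_spec(method, rec["mean"], **so)
            interval = rec.get("interval")
            params.append(Parameter(
                id=rec["id"],
                mean=float(rec["mean"]),
                value=float(rec["mean"]),
                second_order=spec,
                units=rec.get("units", ""),
                description=rec.get("description", ""),
                source_table=rec.get("source_table", ""),
                interval=tuple(interval) if interval is not None else None,
            ))
        except (KeyError, TypeError, ValueError, MediastageError) as exc:
            rid = rec.get("id", "<missing id>") if isinstance(rec, dict) else rec
            raise MediastageError(f"malformed parameter record {rid!r}: {exc}") from exc
    return ParameterSet(params)


def reference_parameter_set() -> ParameterSet:
    """All 46 parameters at their published reference means."""
    return load_parameters()


# -- diagram construction --------------------------------------------------

TESTS = ("TBNA", "PET", "EBUS", "EUS", "MED")


def _test_cpt(ps, test, performed, n_options):
    """CPT over (N2_N3, CT_scan, decision) -> test result.

    ``performed`` maps decision-option index -> bool. When the test is not
    performed its result is `no_result` with probability one.
    """
    t = np.zeros((2, 2, n_options, 3))
    key = test.lower()
    for ct, ct_label in enumerate(("pos", "neg")):
        sens = ps.value(f"sens_{key}_ct_{ct_label}")
        spec = ps.value(f"spec_{key}_ct_{ct_label}")
        for opt in range(n_options):
            if performed[opt]:
                t[0, ct, opt] = (sens, 1.0 - sens, 0.0)
                t[1, ct, opt] = (1.0 - spec, spec, 0.0)
            else:
                t[:, ct, opt] = (0.0, 0.0, 1.0)
    return t


def build_influence_diagram(params: ParameterSet,
                            ce: CostEffectivenessSettings = CostEffectivenessSettings(0.0),
                            ) -> InfluenceDiagram:
    """Construct the staging influence diagram from a parameter set.

    Decisions run Dec_TBNA -> Dec_PET -> Dec_EBUS_EUS -> Dec_MED ->
    Treatment; the CT result is known from the start, each test result is
    observed before the next decision, and N2_N3 and mediastinoscopy
    survival are never observed. ``ce.lambda_inverse`` enters the diagram as
    a constant utility node multiplying total cost, so 0 ignores costs.
    """
    problems = params.validate()
    if problems:
        raise MediastageError("invalid parameter set: " + "; ".join(problems))
    ps = params

    variables = [
        Variable("CT_scan", CHANCE, (POSITIVE, NEGATIVE)),
        Variable("Dec_TBNA", DECISION, ("no", "yes")),
        Variable("TBNA", CHANCE, TEST_STATES),
        Variable("Dec_PET", DECISION, ("no", "yes")),
        Variable("PET", CHANCE, TEST_STATES),
        Variable("Dec_EBUS_EUS", DECISION, ENDO_OPTIONS),
        Variable("EBUS", CHANCE, TEST_STATES),
        Variable("EUS", CHANCE, TEST_STATES),
        Variable("Dec_MED", DECISION, ("no", "yes")),
        Variable("MED", CHANCE, TEST_STATES),
        Variable("Treatment", DECISION, TREATMENTS),
        Variable("MED_Sv", CHANCE, ("yes", "no")),
        Variable("N2_N3", CHANCE, (POSITIVE, NEGATIVE)),
    ]
    variables += [Variable(n, UTILITY) for n in (
        "EC_CT_scan", "EC_TBNA", "EC_PET", "EC_EBUS", "EC_EUS", "EC_MED",
        "EC_Treatment", "TBNA_Morb", "EBUS_Morb", "EUS_Morb", "MED_Morb",
        "Surv_QALE", "MED_Survival", "Immediate_Survival", "Lambda_inv",
        "Net_QALE", "Total_QALE", "Total_Economic_Cost", "Weighted_Econ_Cost",
        "Net_Health_Benefit",
    )]

    prev = ps.value("prevalence_n2_n3")
    sens_ct, spec_ct = ps.value("sens_ct"), ps.value("spec_ct")
    med_surv = ps.value("med_survival_rate")

    ebus_performed = tuple(o in ("ebus", "ebus_eus") for o in ENDO_OPTIONS)
    eus_performed = tuple(o in ("eus", "ebus_eus") for o in ENDO_OPTIONS)

    cpts = [
        ProbabilityTable("N2_N3", (), np.array([prev, 1.0 - prev])),
        ProbabilityTable("CT_scan", ("N2_N3",), np.array(
            [[sens_ct, 1.0 - sens_ct], [1.0 - spec_ct, spec_ct]])),
        ProbabilityTable("TBNA", ("N2_N3", "CT_scan", "Dec_TBNA"),
                         _test_cpt(ps, "TBNA", (False, True), 2)),
        ProbabilityTable("PET", ("N2_N3", "CT_scan", "Dec_PET"),
                         _test_cpt(ps, "PET", (False, True), 2)),
        ProbabilityTable("EBUS", ("N2_N3", "CT_scan", "Dec_EBUS_EUS"),
                         _test_cpt(ps, "EBUS", ebus_performed, 4)),
        ProbabilityTable("EUS", ("N2_N3", "CT_scan", "Dec_EBUS_EUS"),
                         _test_cpt(ps, "EUS", eus_performed, 4)),
        ProbabilityTable("MED", ("N2_N3", "CT_scan", "Dec_MED"),
                         _test_cpt(ps, "MED", (False, True), 2)),
        ProbabilityTable("MED_Sv", ("Dec_MED",), np.array(
            [[1.0, 0.0], [med_surv, 1.0 - med_surv]])),
    ]

    def per_option(costs):
        return np.array(costs, dtype=float)

    # QALE and immediate survival by (Treatment, N2_N3); rows follow
    # TREATMENTS order, columns (positive, negative)
    surv_qale = np.array([
        [ps.value("qale_no_treatment_pos"), ps.value("qale_no_treatment_neg")],
        [ps.value("qale_chemoradio_pos"), ps.value("qale_chemoradio_neg")],
        [ps.value("qale_thoracotomy_pos"), ps.value("qale_thoracotomy_neg")],
    ])
    imm_surv = np.array([
        [1.0, 1.0],  # forgoing treatment carries no procedural mortality
        [ps.value("imm_surv_chemoradio"), ps.value("imm_surv_chemoradio")],
        [ps.value("imm_surv_thoracotomy_pos"), ps.value("imm_surv_thoracotomy_neg")],
    ])

    utilities = [
        UtilityTable("EC_CT_scan", (), np.array(ps.value("cost_ct"))),
        UtilityTable("EC_TBNA", ("Dec_TBNA",), per_option([0.0, ps.value("cost_tbna")])),
        UtilityTable("EC_PET", ("Dec_PET",), per_option([0.0, ps.value("cost_pet")])),
        UtilityTable("EC_EBUS", ("Dec_EBUS_EUS",), per_option(
            [c * ps.value("cost_ebus") for c in ebus_performed])),
        UtilityTable("EC_EUS", ("Dec_EBUS_EUS",), per_option(
            [c * ps.value("cost_eus") for c in eus_performed])),
        UtilityTable("EC_MED", ("Dec_MED",), per_option([0.0, ps.value("cost_med")])),
        UtilityTable("EC_Treatment", ("Treatment",), per_option(
            [0.0, ps.value("cost_chemoradio"), ps.value("cost_thoracotomy")])),
        UtilityTable("TBNA_Morb", ("Dec_TBNA",), per_option([0.0, -ps.value("morb_tbna")])),
        UtilityTable("EBUS_Morb", ("Dec_EBUS_EUS",), per_option(
            [-c * ps.value("morb_ebus") for c in ebus_performed])),
        UtilityTable("EUS_Morb", ("Dec_EBUS_EUS",), per_option(
            [-c * ps.value("morb_eus") for c in eus_performed])),
        UtilityTable("MED_Morb", ("Dec_MED",), per_option([0.0, -ps.value("morb_med")])),
        UtilityTable("Surv_QALE", ("Treatment", "N2_N3"), surv_qale),
        UtilityTable("MED_Survival", ("MED_Sv",), np.array([1.0, 0.0])),
        UtilityTable("Immediate_Survival", ("Treatment", "N2_N3"), imm_surv),
        UtilityTable("Lambda_inv", (), np.array(ce.lambda_inverse)),
    ]

    supervalues = [
        SuperValueSpec("Net_QALE", "product",
                       [("Surv_QALE", 1), ("MED_Survival", 1), ("Immediate_Survival", 1)]),
        SuperValueSpec("Total_QALE", "sum",
                       [("TBNA_Morb", 1), ("EBUS_Morb", 1), ("EUS_Morb", 1),
                        ("MED_Morb", 1), ("Net_QALE", 1)]),
        SuperValueSpec("Total_Economic_Cost", "sum",
                       [("EC_CT_scan", 1), ("EC_TBNA", 1), ("EC_PET", 1),
                        ("EC_EBUS", 1), ("EC_EUS", 1), ("EC_MED", 1),
                        ("EC_Treatment", 1)]),
        SuperValueSpec("Weighted_Econ_Cost", "product",
                       [("Lambda_inv", 1), ("Total_Economic_Cost", 1)]),
        SuperValueSpec("Net_Health_Benefit", "sum",
                       [("Total_QALE", 1), ("Weighted_Econ_Cost", -1)]),
    ]

    return InfluenceDiagram(
        variables=variables,
        decision_order=["Dec_TBNA", "Dec_PET", "Dec_EBUS_EUS", "Dec_MED", "Treatment"],
        observations={
            "Dec_TBNA": ("CT_scan",),
            "Dec_PET": ("TBNA",),
            "Dec_EBUS_EUS": ("PET",),
            "Dec_MED": ("EBUS", "EUS"),
            "Treatment": ("MED",),
        },
        cpts=cpts,
        utilities=utilities,
        supervalues=supervalues,
        root_value="Net_Health_Benefit",
    )


def settings_for(criterion: str, params: ParameterSet) -> CostEffectivenessSettings:
    """Criterion name -> settings; ``nhb`` uses the set's willingness to pay."""
    if criterion == "effectiveness":
        return CostEffectivenessSettings(0.0)
    if criterion == "nhb":
        lam = params.value("lambda_wtp")
        if lam <= 0:
            raise MediastageError("willingness to pay must be positive under NHB")
        return CostEffectivenessSettings(1.0 / lam)
    raise MediastageError(f"unknown criterion {criterion!r}")


# -- combinatorial size computations ---------------------------------------

def count_decision_scenarios(diag: InfluenceDiagram) -> int:
    """Cardinality of the Cartesian product of all chance and decision
    variable domains."""
    names = diag.global_order()
    return int(np.prod([diag.card(n) for n in names], dtype=object))


def count_symmetric_tree_leaves(diag: InfluenceDiagram) -> int:
    """Leaves of the equivalent symmetric decision tree: decision scenarios
    times the number of ordinary utility nodes."""
    return count_decision_scenarios(diag) * len(diag.ordinary_utility_names)


def count_policy_columns(diag: InfluenceDiagram, decision: str) -> int:
    """Columns of the decision's full policy table: the product of the
    domain sizes of its informational predecessors (no reachability
    pruning)."""
    preds = diag.informational_predecessors(decision)
    return int(np.prod([diag.card(p) for p in preds], dtype=object))


def count_test_strategies(diag: InfluenceDiagram) -> int:
    """Number of distinct contingent test plans, excluding the final
    (treatment) decision.

    A plan at a test decision picks one option and, for every joint outcome
    the tests performed under that option can produce, a continuation plan
    for the remaining test decisions. The count therefore satisfies
    f_i = Σ_options f_{i+1}^{#outcomes(option)} with f after the last test
    decision equal to 1, and the total multiplies one branch count per
    initially observed outcome (the CT scan result).
    """
    part = diag.partition()
    decisions = diag.decision_order[:-1]  # exclude treatment

    def n_outcomes(dec_idx: int, option_idx: int) -> int:
        """Joint outcomes of the variables revealed after this decision."""
        revealed = part[dec_idx + 1]
        total = 1
        for var in revealed:
            t = diag.cpts[var]
            if diag.decision_order[dec_idx] in t.parents:
                axis = t.parents.index(diag.decision_order[dec_idx])
                sub = np.moveaxis(t.table, axis, 0)[option_idx]
            else:
                sub = t.table
            # states reachable under some configuration of the other parents
            reachable = (sub > 0).any(axis=tuple(range(sub.ndim - 1)))
            total *= int(reachable.sum())
        return total

    plans = 1
    for i in reversed(range(len(decisions))):
        d = decisions[i]
        plans = sum(plans ** n_outcomes(i, o) for o in range(diag.card(d)))
    initial = int(np.prod([diag.card(v) for v in part[0]], dtype=object)) if part[0] else 1
    return int(plans ** initial)
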