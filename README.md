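# mediastage

Exact decision analysis of **mediastinal staging in non-small-cell lung
cancer** (NSCLC): which sequence of staging tests — CT, TBNA, PET, EBUS,
EUS, mediastinoscopy — should a clinician perform, for each pattern of
results, before choosing thoracotomy, chemoradiotherapy or no treatment?

The package is written for health-economics and medical-decision-making
researchers. It implements the complete analysis pipeline:

* a generic **influence-diagram** core (chance/decision/utility nodes,
  super-value nodes combining utilities by sum or product, validation,
  information partition, JSON serialization);
* the **staging model**: 46 independent parameters, each with a reference
  mean and a second-order (Beta / uniform / Gamma) distribution rebuilt
  from its raw published inputs at load time;
* two independent **exact evaluators** (factorized variable elimination
  and a symmetric-decision-tree rollback used as its oracle) computing the
  maximum expected utility and optimal policies;
* **strategy trees**: the optimal policies compacted into a single
  contingent plan with all impossible scenarios pruned;
* three **sensitivity analyses** over parameter uncertainty: per-parameter
  EVPI, strategy-change thresholds, and decision-change probabilities.

## The model in brief

Nodal involvement `N2_N3` (prevalence 0.30) is unobservable; tests carry
information at the price of cost and morbidity. Utilities decompose into
quality-adjusted life expectancy,

> Net_QALE = Surv_QALE × MED_Survival × Immediate_Survival,
> Total_QALE = Net_QALE + Σ morbidities,

total economic cost C, and the root criterion — the **net health
benefit** NHB = E − λ⁻¹·C with willingness to pay λ. λ⁻¹ enters the
diagram as a constant utility node, so λ⁻¹ = 0 yields the
effectiveness-only analysis without touching the graph. Decisions are
evaluated in temporal order Dec_TBNA → Dec_PET → Dec_EBUS_EUS → Dec_MED →
Treatment under no-forgetting. See `docs/methods.md` for the full model,
elicitation recipes, algorithms and limitations.

## Worked example

```python
import mediastage as ms

params = ms.reference_parameter_set()           # the 46 published means
diag = ms.build_influence_diagram(params, ms.settings_for("nhb", params))
result = ms.evaluate_variable_elimination(diag)
tree = ms.build_strategy_tree(diag, result)
print(f"maximum expected utility: {result.meu:.4f} NHB-QALYs")
print(ms.render(tree, "text"))
```

prints

```
maximum expected utility: 3.9845 NHB-QALYs
[CT_scan=negative]
  Dec_TBNA = no
  Dec_PET = no
  Dec_EBUS_EUS = ebus
  [EBUS=negative]
    Dec_MED = no
    Treatment = thoracotomy
  [EBUS=positive]
    Dec_MED = no
    Treatment = chemoradiotherapy
[CT_scan=positive]
  Dec_TBNA = yes
  [TBNA=negative]
    Dec_PET = no
    Dec_EBUS_EUS = ebus
    ...
  [TBNA=positive]
    Dec_PET = no
    Dec_EBUS_EUS = no_test
    Dec_MED = no
    Treatment = chemoradiotherapy
```

Read: at 30,000 EUR/QALY the expected value of following the optimal plan
is 3.98 QALYs net of cost; a positive CT scan should be followed by a
TBNA (a cheap needle test), and the expensive EBUS is reserved for
patients whose CT or TBNA was negative; PET and mediastinoscopy are never
cost-effective. With costs ignored (`settings_for("effectiveness", ...)`)
the optimum instead performs TBNA/PET plus the combined EBUS+EUS session
and uses mediastinoscopy to resolve residual conflicts — run
`python examples/evaluate_reference.py` to see both trees.

The `examples/` directory holds one short script per capability
(reference evaluation, model sizes, elicitation recipes, sensitivity
analyses, and the classic test-then-treat toy problem). The same
workflows are available from a thin CLI:

```sh
mediastage counts
mediastage evaluate --criterion nhb --lambda 30000 --out out/
mediastage sensitivity --analysis threshold --param spec_ebus_ct_neg
```

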