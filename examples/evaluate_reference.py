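"""Evaluate the reference staging model under both criteria.

Builds the influence diagram from the shipped reference parameters, solves
it exactly by variable elimination, and prints the maximum expected utility
together with the optimal strategy tree. Under the effectiveness-only
criterion the value is in QALYs; under net health benefit it is in QALYs
net of costs converted at 30,000 EUR/QALY, so the two values are not
directly comparable.
"""

import mediastage as ms

params = ms.reference_parameter_set()

for criterion in ("effectiveness", "nhb"):
    diag = ms.build_influence_diagram(params, ms.settings_for(criterion, params))
    result = ms.evaluate_variable_elimination(diag)
    tree = ms.build_strategy_tree(diag, result)
    unit = "QALYs" if criterion == "effectiveness" else "NHB-QALYs"
    print(f"== {criterion} ==")
    print(f"maximum expected utility: {result.meu:.4f} {unit}")
    print("optimal strategy (indentation = depth, [..] = observed outcome):")
    print(ms.render(tree, "text"))
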