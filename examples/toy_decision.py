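"""The classic test-then-treat problem as a two-decision influence diagram.

A disease with 10% prevalence, a test with 90% sensitivity and specificity
costing 1 utility unit of morbidity, and a treatment that helps the sick
(80 vs 20) but slightly harms the healthy (95 vs 100). The exact solution
shows when the test is worth its morbidity, and the posterior updates the
diagram performs under evidence.
"""

import mediastage as ms
from mediastage.synthetic import toy_two_decision_id

diag = toy_two_decision_id(p_disease=0.1, sens=0.9, spec=0.9,
                           test_morbidity=1.0)
result = ms.evaluate_variable_elimination(diag)
tree = ms.build_strategy_tree(diag, result)
print(f"maximum expected utility: {result.meu:.3f}")
print(ms.render(tree, "text"))

post = ms.posterior_probability(diag, result.policies,
                                {"T": "yes", "Y": "positive"}, "X")
print(f"P(disease | positive test) = {post['present']:.3f}  (prior 0.1)")

useless = toy_two_decision_id(sens=0.5, spec=0.5, test_morbidity=1.0)
res2 = ms.evaluate_variable_elimination(useless)
opt = res2.policies["T"].table
print(f"\nWith a coin-flip test the optimal first action is T = "
      f"{useless.states('T')[int(opt)]}: an uninformative test never "
      f"justifies its morbidity.")
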