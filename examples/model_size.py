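"""Why an influence diagram rather than a decision tree.

Prints the combinatorial sizes of the staging problem: the number of
decision scenarios (the Cartesian product of all chance and decision
domains), the leaves an equivalent symmetric decision tree would need,
the width of the raw policy tables, and the number of contingent test
plans the model searches over.
"""

import mediastage as ms

params = ms.reference_parameter_set()
diag = ms.build_influence_diagram(params)

print(f"independent parameters:       {len(params)}")
print(f"decision scenarios:           {ms.count_decision_scenarios(diag):,}")
print(f"ordinary utility nodes:       {len(diag.ordinary_utility_names)}")
print(f"symmetric-tree leaves:        {ms.count_symmetric_tree_leaves(diag):,}")
for d in diag.decision_order:
    print(f"policy columns [{d:>12s}]: {ms.count_policy_columns(diag, d):,}")
n = ms.count_test_strategies(diag)
print(f"contingent test strategies:   {n:,}  (~{n:.2e})")
print()
print("Most policy columns are impossible scenarios (e.g. a recorded result")
print("for a test that was never performed); the strategy tree prunes them.")
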