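# Methods

## The decision problem

The package models mediastinal staging of non-small-cell lung cancer for a
patient who is presumably operable and free of distant metastases. The
clinically decisive unknown is binary nodal involvement `N2_N3`
(prevalence 0.30): N0/N1 disease is treated surgically (thoracotomy),
N2/N3 disease with chemoradiotherapy. A CT scan is always performed; the
clinician then decides sequentially whether to perform TBNA, PET, EBUS
and/or EUS (the two endoscopic ultrasounds can be combined in one
session), and mediastinoscopy, before choosing a treatment. Each test has
a sensitivity and specificity conditional on the CT result, a monetary
cost, and (for the invasive tests) a QALY morbidity; mediastinoscopy also
carries a 0.1 % procedural mortality.

The model is an influence diagram: chance nodes `N2_N3`, `CT_scan`, the
six test results (each with a `no_result` state for tests not performed),
and mediastinoscopy survival `MED_Sv`; decision nodes `Dec_TBNA`,
`Dec_PET`, `Dec_EBUS_EUS` (options `no_test`, `ebus`, `eus`, `ebus_eus`),
`Dec_MED`, `Treatment` (options `no_treatment`, `chemoradiotherapy`,
`thoracotomy`); and twenty utility nodes. Fifteen utility nodes are
ordinary tables; five are super-value nodes combining them:

```
Net_QALE            = Surv_QALE * MED_Survival * Immediate_Survival   (product)
Total_QALE          = Net_QALE + TBNA_Morb + EBUS_Morb + EUS_Morb + MED_Morb
Total_Economic_Cost = sum of the seven EC_* cost nodes
Weighted_Econ_Cost  = Lambda_inv * Total_Economic_Cost                (product)
Net_Health_Benefit  = Total_QALE - Weighted_Econ_Cost                 (root)
```

`Lambda_inv` is a constant (parentless) utility node holding λ⁻¹, the
reciprocal willingness to pay. Setting λ⁻¹ = 0 ignores costs entirely
(the effectiveness-only criterion); λ⁻¹ = 1/30 000 QALY/EUR gives the net
health benefit NHB = E − C/λ. Representing λ⁻¹ as a node means switching
criteria never touches the graph, and it makes explicit that the
effectiveness optimum is obtainable "regardless of cost".

Costs are stored as positive numbers and subtracted through a −1 weight
on the root sum; morbidities are stored as negative QALY values and added.
A patient who dies at mediastinoscopy contributes zero QALE through the
`MED_Survival` factor of the product node but still accrues the cost of
the treatment option chosen — the literal reading of the drawn arcs (the
cost and QALE tables have only `Treatment` and `N2_N3` as parents). The
immediate survival of `no_treatment` is 1.0 (forgoing treatment carries no
procedural mortality); chemoradiotherapy's immediate survival applies to
both `N2_N3` states.

### Information structure

Decisions are totally ordered; the information partition is

C0 = {CT_scan} → Dec_TBNA → C1 = {TBNA} → Dec_PET → C2 = {PET} →
Dec_EBUS_EUS → C3 = {EBUS, EUS} → Dec_MED → C4 = {MED} → Treatment →
C5 = {MED_Sv, N2_N3}.

`MED_Sv` is modeled as never observed. Placing it before `Treatment`
would be clinically natural but would double the Treatment policy table
(31 104 instead of the model's 15 552 columns) without changing any
recommendation: a patient who dies at mediastinoscopy receives zero QALE
under every treatment, so the optimal treatment is unaffected. No-
forgetting is built into the representation: the informational
predecessors of D_i are computed as the cumulative union of earlier
observation sets and decisions.

### Problem sizes

The Cartesian product of all chance and decision domains has
2·2·3⁵·2 · 2·2·4·2·3 = 186 624 cells; an equivalent symmetric decision
tree would have 186 624 × 15 ordinary utility nodes = 2 799 360 leaves.
Counting contingent test plans recursively (a plan picks an option and a
continuation for every observable outcome combination; per CT branch the
recursion gives 2 → 26 → 702 → 493 506 across the four test decisions)
yields 493 506² ≈ 2.44 × 10¹¹ distinct strategies over the test
decisions — the space the exact evaluation searches implicitly.

## Parameters and second-order elicitation

There are 46 independent parameters (reference means in
`src/mediastage/data/reference_parameters.yaml`, grouped as: 3 baseline
probabilities; 2 × 10 test accuracies by CT context; 4 morbidities; 6 test
costs; 6 QALE values; survival rates, treatment costs and λ). Every
parameter except the costs carries a second-order distribution describing
uncertainty about the parameter itself; costs are point masses. The
configuration file stores the *raw elicitation inputs* and the fits are
recomputed at load time:

- **counts** — m events in n observations → Beta(m, n−m). For the one
  count-based entry (TBNA specificity, CT negative, 34/35) this
  reproduces the published mean 97.1 % and 95 % interval [89.7, 99.9] %.
- **mean_cv** — only a mean μ is published. σ = k·μ with k = 1/5 and the
  method of moments gives z = μ(1−μ)/σ² − 1, α = zμ, β = z−α. When
  σ² ≥ μ(1−μ) (μ near 1), k is divided by 10 until consistent. The fitted
  95 % intervals reproduce the published ones (e.g. mean 0.78 →
  [0.409, 0.985]).
- **mean_ci95 / mean_range999** — a mean plus an interval. With
  β = α(1−μ)/μ fixed by the mean, the interval mass F(u)−F(l) is
  monotone in α; bisection on an expanding bracket (α ∈ [10⁻⁶, 10⁹])
  solves F(u)−F(l) = 0.95 (a true confidence interval) or 0.999 (a
  plain published range) to 10⁻⁸. The suite cross-checks the mass by
  numerical integration of the Beta density.
- **uniform** — morbidities and QALE values: the published interval is
  the full support (its midpoint equals the published mean in every row).
- **gamma** — λ: moment-matched shape 1/k², scale μk² (k = 0.2).

Sampling clips probability draws to [0, 1] (Beta draws never need it) and
truncates morbidity-loss draws at 0 (no published interval crosses it).

## Evaluation

Two independent exact algorithms compute the maximum expected utility and
one optimal policy per decision.

**Variable elimination** (the production path). After folding the
super-value structure into a flat sum of ordinary tables — products are
distributed over sums and multiplied pointwise over the union of parents,
with a configurable size bound — elimination proceeds in reverse temporal
order: the never-observed block first, then the last decision, and so on;
within a chance block a greedy min-fill heuristic orders the variables.
Probability potentials φ and utility potentials ψ are kept separate.
Summing out a chance variable X combines the potentials mentioning X and
renormalizes the utility part: ψ′ = (Σ_X φψ)/(Σ_X φ), with ψ′ set to 0
where the marginal is 0. The zero-guard is the division-free escape for
impossible configurations: they contribute nothing downstream and their
policy entries fall to the tie-break option. Eliminating a decision takes
the argmax of the summed utility potentials; probability potentials still
carrying the decision's axis at that point are constant along it (an
exact identity — summed-out descendants integrate to one) and are
contracted after a numerical constancy check.

**Symmetric-tree rollback** (the oracle). The joint probability of all
chance variables given all decisions and the folded total utility are
materialized over the full 186 624-cell configuration space and reduced
from the leaves inward: chance axes are probability-weighted sums,
decision axes maximizations. This is a direct evaluation of the symmetric
decision tree, quadratic in memory but with no factor bookkeeping; the
suite requires bit-identical policies and MEU agreement to 10⁻⁹ against
variable elimination on 200 random diagrams and on the staging model.

**Tie-breaking.** Options within 10⁻⁹·(1+|max|) of the best are treated
as tied and the earliest declared option wins. Option orders are declared
least-invasive-first (`no`/`no_test`/`no_treatment` first), so the model
never recommends an intervention that adds no expected utility. The
tolerance matters: under the effectiveness criterion PET is *exactly*
value-neutral in scenarios where its result cannot change later play (it
has a cost but no morbidity), and accumulated rounding of order 10⁻¹⁶
would otherwise let the two algorithms resolve such ties differently.
The smallest genuine utility difference in the model (the EBUS morbidity,
2.1 × 10⁻⁵ QALYs) is four orders of magnitude above the tolerance.

Policies are materialized as full tables over every configuration of a
decision's informational predecessors — mirroring the model's published
column counts — with unreachable columns holding the tie-break option.
`consistent_configurations` enumerates the columns reachable under at
least one strategy (e.g. 6 of 12 for `Dec_PET`).

## Strategy trees

The optimal policies are compacted into a single contingent plan by
forward expansion in temporal order: each decision becomes an action node
carrying the option its policy selects given the history; each observation
block becomes a branching node over the joint outcomes that have nonzero
probability given the history (variables with a forced outcome, such as
`no_result` for an unperformed test, do not branch); sibling branches
with structurally identical subtrees are merged. EBUS and EUS observed in
one session branch as a single node over their joint outcome space,
avoiding an arbitrary serialization. Canonical form (sorted outcomes and
branches, merged identical siblings) is idempotent and underlies
`trees_equal`. Rolling the tree forward against the joint distribution
reproduces the MEU to 10⁻⁹, and every surviving branch is checked to
carry positive probability with the branch masses summing to the parent
mass (pruning soundness).

Under the effectiveness-only criterion the computed optimum performs TBNA
plus the combined EBUS+EUS session after a positive CT scan, PET plus
EBUS+EUS after a negative one, and mediastinoscopy only when the
needle/PET result was positive with both endoscopies negative, or
negative with the endoscopies in contradiction. Under NHB at
30 000 EUR/QALY the optimum is much leaner: TBNA after a positive CT,
EBUS alone when CT or TBNA is negative, PET and mediastinoscopy never.

## Sensitivity analyses

All three analyses vary one parameter at a time, the others staying at
their reference means, under the NHB criterion by default (λ is itself a
parameter, so sampling it flows into the diagram). They are pure
functions of the supplied parameter set and reproducible from their seed.

- **Per-parameter EVPI**: E_θ[max_s EU(s;θ)] − max_s E_θ[EU(s;θ)] with
  both expectations over the same n = 1000 draws. The candidate set for
  the no-information term is the distinct optima encountered across the
  draws, where strategy identity is judged on each strategy's own
  reachable scenarios (the strategy-tree notion of identity); the
  indicator array of each candidate over the configuration space is
  independent of θ and shared across draws. Degenerate parameters return
  exactly 0 without sampling. The estimate carries the Monte-Carlo
  standard error of the paired differences.
- **Threshold analysis** (deterministic): the parameter is scanned on a
  grid (default step 0.01, default range the published interval), the
  model rebuilt and re-solved at each value, and the optimal tree
  compared with the reference optimum I* via `trees_equal`. Runs of
  matching grid values are reported, along with the largest value at
  which the strategy differs; a non-grid value (such as the reference
  mean) is classified as stable when it lies strictly between a changed
  grid point and a matching one, i.e. within the scan's resolution. For
  the EBUS specificity given a negative CT the strategy still differs at
  0.99 and matches at 1.00: the reference 0.995 sits just above the
  threshold, which is why this is the one parameter the model is
  genuinely sensitive to.
- **Decision-change probability**: the fraction of draws whose optimal
  policy for a given decision differs from I*. By default the comparison
  covers all consistent policy columns; `restrict="reachable"` confines
  it to the information states the reference optimum can actually reach,
  which suppresses value-neutral flips in scenarios optimal play never
  visits and is the variant used for qualitative ranking. Under either
  variant the two QALE-with-metastasis parameters dominate and the
  decisions most affected are `Dec_EBUS_EUS`, then `Dec_TBNA`.

Monte-Carlo sizes: the analyses in the test suite use 1000 draws per
parameter for the EVPI bound and 120–300 draws for qualitative checks;
one model evaluation costs a few milliseconds, so a full 46-parameter
EVPI sweep at n = 1000 runs in minutes on one core.

## Synthetic fixtures

`toy_two_decision_id` builds the classic test-then-treat diagram (partition
∅, {Y}, {X}) with caller-supplied probabilities and utilities.
`random_influence_diagram` generates small, always-valid diagrams for the
oracle suite: chance variables are assigned uniformly to information
blocks; parents are drawn from causally earlier variables under the
constraint that an observed variable never descends from a decision made
at or after its observation; a link variable is inserted when consecutive
decisions would otherwise be disconnected; CPT columns are flat-Dirichlet
draws (exercising the full simplex without favouring determinism) and
utilities uniform, with occasional product super-value nodes and negative
sum weights. These fixtures emulate the *structure* of sequential
diagnosis problems, not clinical content: passing the oracle suite shows
algorithmic correctness on the class of small temporally sound diagrams,
not that any particular parameterization is realistic.

## Known limitations

- Decisions are totally ordered; partial orders (choosing test order
  adaptively) are out of scope.
- PET is assumed not to affect the accuracy of later tests, and repeat
  testing (restaging) is not modeled.
- Second-order distributions are independent across parameters; the
  sensitivity analyses are one-at-a-time, not a joint probabilistic
  sensitivity analysis.
- The exact evaluators materialize potentials bounded by the scenario
  count; diagrams beyond ~10⁷ scenarios need algorithms (and bounds) this
  package deliberately does not include.
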