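"""Synthetic fixtures: toy diagrams, random diagrams, parameter sampling.

The toy two-decision diagram mirrors the classic test-then-treat problem: a
patient may carry a disease X; a test decision T yields a result Y (with a
``no_result`` state when the test is skipped) before the treatment decision
D; utilities are the test morbidity U1(T) and the health outcome U2(X, D),
combined by a sum root. Random diagrams exercise the evaluators over the
whole space of small, temporally sound influence diagrams; the parameter
sampler drives the probabilistic sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram import (
    CHANCE, DECISION, UTILITY,
    InfluenceDiagram, ProbabilityTable, SuperValueSpec, UtilityTable, Variable,
)
from .elicitation import sample
from .errors import DiagramError
from .model import ParameterSet


def toy_two_decision_id(p_disease: float = 0.1,
                        sens: float = 0.9, spec: float = 0.9,
                        u_treat_sick: float = 80.0, u_treat_healthy: float = 95.0,
                        u_no_treat_sick: float = 20.0, u_no_treat_healthy: float = 100.0,
                        test_morbidity: float = 1.0) -> InfluenceDiagram:
    """Test-then-treat toy diagram (information partition ∅, {Y}, {X})."""
    for p in (p_disease, sens, spec):
        if not 0 <= p <= 1:
            raise DiagramError(f"probability {p} outside [0, 1]")
    variables = [
        Variable("T", DECISION, ("no", "yes")),
        Variable("Y", CHANCE, ("positive", "negative", "no_result")),
        Variable("D", DECISION, ("no_treat", "treat")),
        Variable("X", CHANCE, ("present", "absent")),
        Variable("U1", UTILITY), Variable("U2", UTILITY), Variable("U", UTILITY),
    ]
    y_table = np.zeros((2, 2, 3))  # parents (X, T)
    y_table[:, 0] = (0.0, 0.0, 1.0)
    y_table[0, 1] = (sens, 1.0 - sens, 0.0)
    y_table[1, 1] = (1.0 - spec, spec, 0.0)
    cpts = [
        ProbabilityTable("X", (), np.array([p_disease, 1.0 - p_disease])),
        ProbabilityTable("Y", ("X", "T"), y_table),
    ]
    utilities = [
        UtilityTable("U1", ("T",), np.array([0.0, -test_morbidity])),
        UtilityTable("U2", ("X", "D"), np.array(
            [[u_no_treat_sick, u_treat_sick],
             [u_no_treat_healthy, u_treat_healthy]])),
    ]
    return InfluenceDiagram(
        variables=variables,
        decision_order=["T", "D"],
        observations={"T": (), "D": ("Y",)},
        cpts=cpts,
        utilities=utilities,
        supervalues=[SuperValueSpec("U", "sum", [("U1", 1), ("U2", 1)])],
        root_value="U",
    )


@dataclass(frozen=True)
class RandomIdConfig:
    """Sizes and seed for :func:`random_influence_diagram`. Defaults keep
    the scenario count small enough for the brute-force oracle."""

    n_chance: int = 4
    n_decisions: int = 2
    max_states: int = 3
    max_parents: int = 2
    n_utilities: int = 2
    utility_range: tuple[float, float] = (0.0, 10.0)
    seed: int = 0


def random_influence_diagram(config: RandomIdConfig = RandomIdConfig()) -> InfluenceDiagram:
    """A random, valid, temporally sound influence diagram.

    Chance variables are assigned uniformly to information blocks; parents
    are drawn from causally earlier variables subject to the rule that a
    variable observed before decision D_i never descends from D_i or a
    later decision. CPT columns are flat-Dirichlet draws; utilities are
    uniform on ``utility_range``. About half the draws combine two utility
    nodes through a product super-value node, and sum terms occasionally
    carry weight −1.
    """
    rng = np.random.default_rng(config.seed)
    nd = config.n_decisions
    dec_names = [f"D{i}" for i in range(nd)]
    ch_names = [f"X{i}" for i in range(config.n_chance)]
    blocks = rng.integers(0, nd + 1, size=config.n_chance)
    causal = list(rng.permutation(config.n_chance))  # causal order of chance vars

    states = {}
    for d in dec_names:
        states[d] = tuple(f"d{j}" for j in range(rng.integers(2, config.max_states + 1)))
    for x in ch_names:
        states[x] = tuple(f"s{j}" for j in range(rng.integers(2, config.max_states + 1)))

    # max decision index among ancestors; -1 when none
    maxdec = {}
    cpts = []
    for pos in causal:
        x = ch_names[pos]
        b = int(blocks[pos])
        cand = [dec_names[j] for j in range(min(b, nd))]
        for q in causal[:causal.index(pos)]:
            z = ch_names[q]
            if b >= nd or maxdec[z] < b:
                cand.append(z)
        k = int(rng.integers(0, config.max_parents + 1))
        parents = tuple(rng.choice(cand, size=min(k, len(cand)), replace=False)) if cand else ()
        md = max([dec_names.index(p) for p in parents if p in dec_names] +
                 [maxdec[p] for p in parents if p not in dec_names] + [-1])
        maxdec[x] = md
        shape = tuple(len(states[p]) for p in parents)
        ncols = int(np.prod(shape)) if shape else 1
        cols = rng.dirichlet(np.ones(len(states[x])), size=ncols)
        cpts.append(ProbabilityTable(x, parents, cols.reshape(shape + (len(states[x]),))))

    # guarantee a directed path between consecutive decisions: when none
    # exists, insert a small observed link variable influenced by the
    # earlier decision
    blocks = list(int(b) for b in blocks)
    reach = {d: {c.child for c in cpts if d in c.parents} for d in dec_names}
    for i in range(nd - 1):
        earlier, later = dec_names[i], dec_names[i + 1]
        has = any(blocks[ch_names.index(c)] == i + 1
                  for c in reach[earlier] if c in ch_names)
        if not has:
            name = f"L{i}"
            states[name] = ("s0", "s1")
            cols = rng.dirichlet(np.ones(2), size=len(states[earlier]))
            cpts.append(ProbabilityTable(name, (earlier,), cols))
            ch_names.append(name)
            blocks.append(i + 1)
            maxdec[name] = i

    all_cd = dec_names + ch_names
    lo, hi = config.utility_range
    utilities = []
    for i in range(config.n_utilities):
        k = int(rng.integers(1, config.max_parents + 1))
        parents = tuple(rng.choice(all_cd, size=min(k, len(all_cd)), replace=False))
        shape = tuple(len(states[p]) for p in parents)
        utilities.append(UtilityTable(f"U{i}", parents, rng.uniform(lo, hi, size=shape)))
    supervalues = []
    util_vars = [Variable(u.node, UTILITY) for u in utilities]
    if config.n_utilities >= 2 and rng.random() < 0.5:
        supervalues.append(SuperValueSpec("Uprod", "product",
                                          [("U0", 1), ("U1", 1)]))
        terms = [("Uprod", 1)] + [(f"U{i}", 1 if rng.random() < 0.8 else -1)
                                  for i in range(2, config.n_utilities)]
        util_vars.append(Variable("Uprod", UTILITY))
    else:
        terms = [(f"U{i}", 1 if rng.random() < 0.8 else -1)
                 for i in range(config.n_utilities)]
    supervalues.append(SuperValueSpec("Uroot", "sum", terms))
    util_vars.append(Variable("Uroot", UTILITY))

    variables = [Variable(d, DECISION, states[d]) for d in dec_names]
    variables += [Variable(x, CHANCE, states[x]) for x in ch_names]
    variables += util_vars
    observations = {
        d: tuple(x for x, b in zip(ch_names, blocks) if b == i)
        for i, d in enumerate(dec_names)
    }
    return InfluenceDiagram(
        variables=variables,
        decision_order=dec_names,
        observations=observations,
        cpts=cpts,
        utilities=utilities,
        supervalues=supervalues,
        root_value="Uroot",
    )


def sample_parameter_vector(params: ParameterSet, which=None,
                            seed: int | np.random.Generator = 0) -> ParameterSet:
    """A parameter set with the listed parameters replaced by second-order
    draws (others stay at their current values).

    Probability draws are clipped to [0, 1] and QALY-loss draws truncated
    at zero; degenerate parameters (costs) are returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(which) if which is not None else params.ids()
    unknown = [i for i in ids if i not in params]
    if unknown:
        raise KeyError(f"unknown parameter ids: {unknown}")
    updates = {}
    for pid in ids:
        p = params.parameters[pid]
        if p.second_order.is_degenerate():
            continue
        x = float(sample(p.second_order, rng))
        if p.units == "probability":
            x = min(max(x, 0.0), 1.0)
        elif p.units == "QALY" and p.id.startswith("morb"):
            x = max(x, 0.0)
        updates[pid] = x
    return params.with_values(updates)
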