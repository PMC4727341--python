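"""Exact evaluation of influence diagrams.

Two independent algorithms compute the maximum expected utility (MEU) and
one optimal policy per decision:

* :func:`evaluate_variable_elimination` — factorized variable elimination.
  Variables are eliminated in reverse temporal order (C_n first, then
  D_{n-1}, C_{n-1}, ..., D_0, C_0); within each chance block a greedy
  min-fill heuristic picks the elimination order. Probability potentials φ
  and utility potentials ψ are carried separately: summing out a chance
  variable combines the potentials that mention it and renormalizes the
  utility part (zero-probability configurations keep utility 0, so they
  contribute nothing and later fall to the tie-break option); maximizing a
  decision takes the argmax of the summed utility potentials, breaking ties
  in favour of the earliest declared option.

* :func:`evaluate_brute_force` — rollback of the full symmetric decision
  tree: the joint probability and total utility are materialized over the
  whole Cartesian configuration space and reduced group by group (chance
  axes averaged, decision axes maximized). Quadratic in memory but
  transparent; serves as the oracle for the factorized algorithm.

Both return identical policies, materialized as full tables over every
configuration of the informational predecessors (reachable or not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram import (
    CHANCE, InfluenceDiagram, Policy, expand, folded_utility_tables,
)
from .errors import CapacityError, DiagramError, InconsistentEvidenceError

DEFAULT_MAX_POTENTIAL = 50_000_000
DEFAULT_MAX_SCENARIOS = 5_000_000

#: Relative tolerance for the structural constancy of probability
#: potentials along a decision axis (an exact identity up to rounding).
_CONST_TOL = 1e-9

#: Options whose value is within this tolerance of the best are treated as
#: tied, and the earliest declared (least invasive / no-test) option wins.
#: Well below any real utility difference in the staging model (the
#: smallest morbidity is ~2e-5 QALYs) but far above accumulated rounding.
TIE_TOL = 1e-9


def argmax_tiebreak(arr: np.ndarray, axis: int = -1,
                    tol: float = TIE_TOL) -> np.ndarray:
    """First index along ``axis`` whose value is within ``tol`` (scaled by
    the magnitude of the maximum) of the maximum."""
    top = arr.max(axis=axis, keepdims=True)
    near = arr >= top - tol * (1.0 + np.abs(top))
    return np.argmax(near, axis=axis)


@dataclass
class EvaluationResult:
    """MEU plus one optimal policy per decision.

    Under the effectiveness-only criterion the MEU is in QALYs; under net
    health benefit it is in NHB-QALYs (QALYs minus λ⁻¹ times cost).
    """

    meu: float
    policies: dict[str, Policy]


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars_, table):
        self.vars = tuple(vars_)
        self.table = np.asarray(table, dtype=float)


def _combine_scope(factors):
    scope = []
    for f in factors:
        for v in f.vars:
            if v not in scope:
                scope.append(v)
    return tuple(scope)


def _product(factors, scope, cards):
    out = np.ones(tuple(cards[v] for v in scope))
    for f in factors:
        out = out * expand(f.table, f.vars, scope)
    return out


def _sum(factors, scope, cards):
    out = np.zeros(tuple(cards[v] for v in scope))
    for f in factors:
        out = out + expand(f.table, f.vars, scope)
    return out


def _min_fill_order(block, factors):
    """Greedy min-fill over the moralized scope graph, restricted to the
    variables of one information block."""
    adj: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            adj.setdefault(v, set()).update(w for w in f.vars if w != v)
    remaining = [v for v in block]
    order = []
    adj = {v: set(nb) for v, nb in adj.items()}
    while remaining:
        best, best_fill = None, None
        for v in remaining:
            nbs = [w for w in adj.get(v, ()) if w != v]
            fill = sum(1 for i, a in enumerate(nbs) for b in nbs[i + 1:]
                       if b not in adj.get(a, ()))
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        remaining.remove(best)
        nbs = adj.pop(best, set())
        for a in nbs:
            adj[a].discard(best)
            adj[a].update(b for b in nbs if b != a)
    return order


def evaluate_variable_elimination(diag: InfluenceDiagram,
                                  max_potential_size: int = DEFAULT_MAX_POTENTIAL,
                                  ) -> EvaluationResult:
    """Exact MEU and optimal policies by variable elimination."""
    cards = {n: diag.card(n) for n in diag.global_order()}
    phi = [_Factor(t.parents + (t.child,), t.table) for t in diag.cpts.values()]
    # scope-free utility terms are plain additive constants
    const_total = 0.0
    psi = []
    for t in folded_utility_tables(diag):
        if t.parents:
            psi.append(_Factor(t.parents, t.table))
        else:
            const_total += float(t.table)

    policies: dict[str, Policy] = {}

    def eliminate_chance(x):
        nonlocal phi, psi
        rel_p = [f for f in phi if x in f.vars]
        rel_u = [f for f in psi if x in f.vars]
        phi = [f for f in phi if x not in f.vars]
        psi = [f for f in psi if x not in f.vars]
        scope = _combine_scope(rel_p + rel_u)
        size = int(np.prod([cards[v] for v in scope], dtype=np.int64)) if scope else 1
        if size > max_potential_size:
            raise CapacityError(
                f"potential over {scope} has {size} entries "
                f"(bound {max_potential_size})")
        axis = scope.index(x)
        p = _product(rel_p, scope, cards)
        new_p = p.sum(axis=axis)
        phi.append(_Factor(tuple(v for v in scope if v != x), new_p))
        if rel_u:
            u = _sum(rel_u, scope, cards)
            new_pu = (p * u).sum(axis=axis)
            with np.errstate(divide="ignore", invalid="ignore"):
                new_u = np.where(new_p > 0, new_pu / np.where(new_p > 0, new_p, 1.0), 0.0)
            psi.append(_Factor(tuple(v for v in scope if v != x), new_u))

    def eliminate_decision(d):
        nonlocal phi, psi
        # probability potentials mentioning d are structurally constant
        # along its axis by this point; contract them
        rel_p = [f for f in phi if d in f.vars]
        phi = [f for f in phi if d not in f.vars]
        for f in rel_p:
            axis = f.vars.index(d)
            t = np.moveaxis(f.table, axis, 0)
            dev = np.abs(t - t[0]).max()
            if dev > _CONST_TOL * (1.0 + np.abs(t).max()):
                raise DiagramError(
                    f"probability potential varies with decision {d!r} "
                    f"(deviation {dev:.3g}); the diagram is not temporally sound")
            phi.append(_Factor(tuple(v for v in f.vars if v != d), t[0]))
        rel_u = [f for f in psi if d in f.vars]
        psi = [f for f in psi if d not in f.vars]
        preds = diag.informational_predecessors(d)
        if not rel_u:
            policies[d] = Policy(d, preds, np.zeros(tuple(cards[p] for p in preds), dtype=np.int64))
            return
        scope = _combine_scope(rel_u)
        u = _sum(rel_u, scope, cards)
        axis = scope.index(d)
        moved = np.moveaxis(u, axis, -1)
        best = argmax_tiebreak(moved, axis=-1)
        new_u = np.take_along_axis(moved, best[..., None], axis=-1)[..., 0]
        rest = tuple(v for v in scope if v != d)
        unknown = [v for v in rest if v not in preds]
        if unknown:
            raise DiagramError(
                f"value potential of {d!r} depends on unobserved {unknown}")
        psi.append(_Factor(rest, new_u))
        # materialize over the full predecessor grid
        full = np.broadcast_to(expand(best, rest, preds),
                               tuple(cards[p] for p in preds))
        policies[d] = Policy(d, preds, np.array(full))

    groups = diag.temporal_groups()
    for kind, block in reversed(groups):
        if kind == CHANCE:
            block = list(block)
            while block:
                order = _min_fill_order(block, phi + psi)
                x = order[0]
                eliminate_chance(x)
                block.remove(x)
        else:
            eliminate_decision(block[0])

    meu = const_total
    for f in psi:
        if f.vars:
            raise DiagramError(f"unreduced utility potential over {f.vars}")
        meu += float(f.table)
    return EvaluationResult(meu=float(meu), policies=policies)


# -- symmetric-tree rollback (oracle) --------------------------------------

def _check_size(diag, bound):
    size = int(np.prod([diag.card(n) for n in diag.global_order()], dtype=object))
    if size > bound:
        raise CapacityError(f"{size} decision scenarios exceed the bound {bound}")
    return size


def joint_probability(diag: InfluenceDiagram,
                      max_scenarios: int = DEFAULT_MAX_SCENARIOS) -> tuple[list[str], np.ndarray]:
    """P(all chance variables | all decisions) over the temporal axis order."""
    _check_size(diag, max_scenarios)
    order = diag.global_order()
    cards = tuple(diag.card(n) for n in order)
    p = np.ones(cards)
    for t in diag.cpts.values():
        p = p * expand(t.table, t.parents + (t.child,), order)
    return order, p


def total_utility(diag: InfluenceDiagram,
                  max_scenarios: int = DEFAULT_MAX_SCENARIOS) -> np.ndarray:
    """The folded root utility over the full configuration space."""
    _check_size(diag, max_scenarios)
    order = diag.global_order()
    u = np.zeros(tuple(diag.card(n) for n in order))
    for t in folded_utility_tables(diag):
        u = u + expand(t.table, t.parents, order)
    return u


def evaluate_brute_force(diag: InfluenceDiagram,
                         max_scenarios: int = DEFAULT_MAX_SCENARIOS,
                         ) -> EvaluationResult:
    """MEU and policies by rolling back the full symmetric decision tree.

    The groups of the temporal order are reduced from the leaves inward:
    never-observed variables first (probability-weighted sum), then the last
    decision (maximization with first-option tie-break), and so on. The
    joint probability mass is carried alongside so each reduction acts on
    probability-weighted utilities.
    """
    order, p = joint_probability(diag, max_scenarios)
    pu = p * total_utility(diag, max_scenarios)
    groups = diag.temporal_groups()
    policies: dict[str, Policy] = {}
    for kind, block in reversed(groups):
        if kind == CHANCE:
            for _ in block:
                p = p.sum(axis=-1)
                pu = pu.sum(axis=-1)
            continue
        d = block[0]
        best = argmax_tiebreak(pu, axis=-1)
        pu = np.take_along_axis(pu, best[..., None], axis=-1)[..., 0]
        p = np.take_along_axis(p, best[..., None], axis=-1)[..., 0]
        preds = diag.informational_predecessors(d)
        policies[d] = Policy(d, preds, best.copy())
    return EvaluationResult(meu=float(pu), policies=policies)


# -- strategies imposed by hand --------------------------------------------

def policy_indicator(diag: InfluenceDiagram, policy: Policy, order) -> np.ndarray:
    """One-hot encoding of a deterministic policy, broadcastable over
    ``order``."""
    onehot = np.eye(diag.card(policy.decision))[policy.table]
    return expand(onehot, policy.predecessors + (policy.decision,), order)


def expected_utility(diag: InfluenceDiagram, policies: dict[str, Policy],
                     max_scenarios: int = DEFAULT_MAX_SCENARIOS) -> float:
    """Expected utility of following the given (not necessarily optimal)
    policies, one total policy per decision."""
    missing = [d for d in diag.decision_order if d not in policies]
    if missing:
        raise DiagramError(f"no policy supplied for decisions {missing}")
    order, p = joint_probability(diag, max_scenarios)
    for d in diag.decision_order:
        pol = policies[d]
        want = tuple(diag.card(v) for v in pol.predecessors)
        if tuple(pol.predecessors) != diag.informational_predecessors(d) \
                or pol.table.shape != want:
            raise DiagramError(f"policy for {d!r} is not total over its predecessors")
        p = p * policy_indicator(diag, pol, order)
    return float((p * total_utility(diag, max_scenarios)).sum())


def expected_utilities_multi(diag: InfluenceDiagram,
                             policy_sets: list[dict[str, Policy]],
                             max_scenarios: int = DEFAULT_MAX_SCENARIOS) -> list[float]:
    """Expected utility of several strategies on one diagram, sharing the
    joint probability and utility arrays across strategies."""
    order, p = joint_probability(diag, max_scenarios)
    pu = p * total_utility(diag, max_scenarios)
    out = []
    for policies in policy_sets:
        w = pu
        for d in diag.decision_order:
            w = w * policy_indicator(diag, policies[d], order)
        out.append(float(w.sum()))
    return out


def posterior_probability(diag: InfluenceDiagram, policies: dict[str, Policy],
                          evidence: dict[str, str], target: str,
                          max_scenarios: int = DEFAULT_MAX_SCENARIOS) -> dict[str, float]:
    """Posterior distribution of a chance variable given test evidence.

    Decisions follow the imposed policies (the auxiliary-network view in
    which each decision node becomes a deterministic chance node), evidence
    fixes observed states, and the remaining variables are marginalized.
    """
    if diag.variables[target].role != CHANCE:
        raise DiagramError(f"target {target!r} is not a chance variable")
    order, p = joint_probability(diag, max_scenarios)
    for d in diag.decision_order:
        if d in evidence:
            continue
        if d not in policies:
            raise DiagramError(f"no policy or evidence for decision {d!r}")
        p = p * policy_indicator(diag, policies[d], order)
    idx = []
    sum_axes = []
    target_axis = None
    k = 0
    for v in order:
        if v in evidence:
            idx.append(diag.state_index(v, evidence[v]))
        else:
            idx.append(slice(None))
            if v == target:
                target_axis = k
            else:
                sum_axes.append(k)
            k += 1
    sub = p[tuple(idx)]
    vec = sub.sum(axis=tuple(sum_axes)) if sum_axes else sub
    tot = float(vec.sum())
    if tot <= 0:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has probability zero under the imposed policies")
    return {s: float(v) / tot for s, v in zip(diag.states(target), vec)}
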