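"""Sensitivity of the optimal staging strategy to parameter uncertainty.

Three one-at-a-time analyses quantify how second-order parameter
uncertainty affects the recommended strategy, each varying a single
parameter while all others stay at their reference means:

* :func:`evpi_per_parameter` — the expected value of perfect information:
  the gain in expected utility from learning the parameter's true value
  before deciding, E_θ[max_s EU(s; θ)] − max_s E_θ[EU(s; θ)], estimated by
  Monte Carlo with common random numbers across both terms.
* :func:`threshold_intervals` — a deterministic grid scan locating the
  thresholds of strategy change: the sub-intervals of the parameter range
  on which the reference optimum I* stays optimal (judged by strategy-tree
  equality on reachable scenarios, so differences confined to impossible
  policy columns do not count).
* :func:`decision_change_probability` — the probability, under the
  parameter's second-order distribution, that the optimal policy of a given
  decision (restricted to consistent configurations) differs from its
  policy in I*.

All analyses are pure functions of the supplied parameter set and are
reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .diagram import InfluenceDiagram, consistent_mask
from .elicitation import sample
from .errors import MediastageError
from .evaluation import (
    EvaluationResult, evaluate_variable_elimination, policy_indicator,
)
from .model import ParameterSet, build_influence_diagram, settings_for
from .strategy import build_strategy_tree, trees_equal

ModelBuilder = Callable[[ParameterSet], InfluenceDiagram]


def make_model_builder(criterion: str = "nhb") -> ModelBuilder:
    """A builder closing over the criterion; under ``nhb`` the willingness
    to pay is read from the parameter set itself, so sampling λ flows into
    the diagram."""
    def build(ps: ParameterSet) -> InfluenceDiagram:
        return build_influence_diagram(ps, settings_for(criterion, ps))
    return build


def _draws(params: ParameterSet, param_id: str, n: int, seed: int) -> np.ndarray:
    p = params.parameters[param_id]
    rng = np.random.default_rng(seed)
    x = np.asarray(sample(p.second_order, rng, size=n), dtype=float)
    if p.units == "probability":
        x = np.clip(x, 0.0, 1.0)
    return x


def _structural_support(diag: InfluenceDiagram) -> np.ndarray:
    """Boolean joint support over all variables; depends only on which CPT
    entries are structurally zero, not on the parameter values."""
    from .diagram import expand
    order = diag.global_order()
    supp = np.ones(diag.cards(order), dtype=bool)
    for t in diag.cpts.values():
        supp &= expand(t.table > 0, t.parents + (t.child,), order)
    return supp


def _reachable_masks(diag: InfluenceDiagram, policies, supp: np.ndarray):
    """Per decision, the boolean predecessor-grid mask of information
    states reachable when the *earlier* decisions follow ``policies``."""
    from .diagram import expand
    order = diag.global_order()
    s = supp
    masks = {}
    for d in diag.decision_order:
        pol = policies[d]
        npred = len(pol.predecessors)
        masks[d] = s.any(axis=tuple(range(npred, s.ndim)))
        onehot = np.eye(diag.card(d), dtype=bool)[pol.table]
        s = s & expand(onehot, pol.predecessors + (d,), order)
    return masks


def _behavior_key(diag: InfluenceDiagram, result: EvaluationResult,
                  supp: np.ndarray) -> tuple:
    """Strategy identity restricted to each decision's *own* reachable
    information states (given the policies of earlier decisions), i.e. the
    strategy-tree behaviour: differences confined to unreachable policy
    columns do not distinguish strategies."""
    masks = _reachable_masks(diag, result.policies, supp)
    return tuple(result.policies[d].table[masks[d]].tobytes()
                 for d in diag.decision_order)


@dataclass
class EvpiEstimate:
    param_id: str
    evpi: float
    std_error: float
    n_samples: int
    n_strategies: int


def evpi_per_parameter(model_builder: ModelBuilder, params: ParameterSet,
                       param_id: str, n_samples: int = 1000,
                       seed: int = 0) -> EvpiEstimate:
    """Monte-Carlo per-parameter EVPI (often called EVPPI).

    Both expectations use the same ``n_samples`` draws. The no-information
    term evaluates every candidate strategy — each distinct optimum
    encountered across the draws — under every draw and takes the best
    average. A degenerate parameter returns exactly zero without sampling.
    """
    spec = params.parameters[param_id].second_order
    if spec.is_degenerate():
        return EvpiEstimate(param_id, 0.0, 0.0, n_samples, 1)
    if n_samples <= 0:
        raise MediastageError("n_samples must be positive")
    thetas = _draws(params, param_id, n_samples, seed)
    supp = None
    meus = np.empty(n_samples)
    reps = {}
    diags = []
    for i, th in enumerate(thetas):
        diag = model_builder(params.with_values({param_id: float(th)}))
        if supp is None:
            supp = _structural_support(diag)
        res = evaluate_variable_elimination(diag)
        meus[i] = res.meu
        key = _behavior_key(diag, res, supp)
        if key not in reps:
            reps[key] = res.policies
        diags.append(diag)
    if len(reps) == 1:
        # the same strategy is optimal at every draw: both terms coincide
        return EvpiEstimate(param_id, 0.0, 0.0, n_samples, 1)
    # the indicator array of each candidate strategy over the joint
    # configuration space depends only on its policies, not on the sampled
    # parameter, so it is shared across all draws
    from .evaluation import joint_probability, total_utility
    ref_diag = diags[0]
    order = ref_diag.global_order()
    indicators = []
    for pols in reps.values():
        ind = np.ones(ref_diag.cards(order))
        for d in ref_diag.decision_order:
            ind = ind * policy_indicator(ref_diag, pols[d], order)
        indicators.append(ind.ravel())
    ind_mat = np.stack(indicators)  # (k, n_configs)
    values = np.empty((n_samples, len(indicators)))
    for i, diag in enumerate(diags):
        _, p = joint_probability(diag)
        pu = (p * total_utility(diag)).ravel()
        values[i] = ind_mat @ pu
    best = int(np.argmax(values.mean(axis=0)))
    diffs = meus - values[:, best]
    evpi = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(n_samples))
    return EvpiEstimate(param_id, evpi, se, n_samples, len(reps))


@dataclass
class ThresholdScan:
    param_id: str
    grid: np.ndarray
    matches: np.ndarray  # True where the optimum equals the reference I*
    stable_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def largest_change_value(self) -> float | None:
        """Largest grid value whose optimal strategy differs from I*."""
        bad = self.grid[~self.matches]
        return float(bad.max()) if bad.size else None

    def stable_containing(self, x: float) -> tuple[float, float] | None:
        """The stable region holding ``x``, widened to grid resolution.

        Each stable run [g_i, g_j] is known to extend past its endpoints up
        to (but excluding) the neighbouring grid values where the strategy
        changed, so a value between a changed and a matching grid point
        (e.g. the reference mean, which need not lie on the grid) is
        correctly classified as stable within the scan's resolution.
        """
        g = self.grid
        for lo, hi in self.stable_intervals:
            i = int(np.searchsorted(g, lo))
            j = int(np.searchsorted(g, hi))
            open_lo = g[i - 1] if i > 0 else lo
            open_hi = g[j + 1] if j + 1 < len(g) else hi
            lo_ok = x >= lo if i == 0 else x > open_lo
            hi_ok = x <= hi if j + 1 == len(g) else x < open_hi
            if lo_ok and hi_ok:
                return (lo, hi)
        return None


def threshold_intervals(model_builder: ModelBuilder, params: ParameterSet,
                        param_id: str, grid_step: float = 0.01,
                        scan_range: tuple[float, float] | None = None) -> ThresholdScan:
    """Grid scan of one parameter; the model is rebuilt and re-evaluated at
    every grid value and its optimal strategy tree compared with the
    reference optimum. Returns the maximal runs of grid values on which I*
    stays optimal."""
    if grid_step <= 0:
        raise MediastageError("grid_step must be positive")
    lo, hi = scan_range if scan_range is not None else params.parameters[param_id].scan_range()
    if hi < lo:
        raise MediastageError(f"empty scan range [{lo}, {hi}]")
    n = int(round((hi - lo) / grid_step)) if hi > lo else 0
    grid = np.round(lo + grid_step * np.arange(n + 1), 12)
    ref_diag = model_builder(params)
    ref_tree = build_strategy_tree(ref_diag, evaluate_variable_elimination(ref_diag))
    matches = np.empty(len(grid), dtype=bool)
    for i, x in enumerate(grid):
        diag = model_builder(params.with_values({param_id: float(x)}))
        tree = build_strategy_tree(diag, evaluate_variable_elimination(diag))
        matches[i] = trees_equal(tree, ref_tree)
    intervals = []
    start = None
    for i, ok in enumerate(matches):
        if ok and start is None:
            start = i
        if (not ok or i == len(matches) - 1) and start is not None:
            end = i if ok else i - 1
            intervals.append((float(grid[start]), float(grid[end])))
            start = None
    return ThresholdScan(param_id, grid, matches, intervals)


@dataclass
class ChangeProbability:
    param_id: str
    per_decision: dict[str, float]
    any_change: float
    n_samples: int
    seed: int


def decision_change_probability(model_builder: ModelBuilder, params: ParameterSet,
                                param_id: str, decision: str | None = None,
                                n_samples: int = 1000, seed: int = 0,
                                restrict: str = "consistent"):
    """Probability that second-order uncertainty in one parameter changes
    the optimal policy of a decision.

    ``restrict`` controls which policy columns count: ``"consistent"``
    compares on every information state reachable under *some* strategy;
    ``"reachable"`` compares only on the states reachable when earlier
    decisions follow the reference optimum, i.e. on behaviour the reference
    strategy can actually exhibit (much less sensitive to value-neutral
    flips in scenarios the optimal play never visits).

    With ``decision=None`` returns a :class:`ChangeProbability` holding the
    per-decision probabilities and the any-decision aggregate; with a named
    decision returns that probability alone.
    """
    if restrict not in ("consistent", "reachable"):
        raise MediastageError(f"unknown restriction {restrict!r}")
    spec = params.parameters[param_id].second_order
    ref_diag = model_builder(params)
    decisions = ref_diag.decision_order
    if decision is not None and decision not in decisions:
        raise MediastageError(f"unknown decision {decision!r}; valid: {decisions}")
    if spec.is_degenerate():
        out = ChangeProbability(param_id, {d: 0.0 for d in decisions}, 0.0,
                                n_samples, seed)
        return out.per_decision[decision] if decision else out
    if n_samples <= 0:
        raise MediastageError("n_samples must be positive")
    ref = evaluate_variable_elimination(ref_diag)
    if restrict == "consistent":
        masks = {d: consistent_mask(ref_diag, d) for d in decisions}
    else:
        masks = _reachable_masks(ref_diag, ref.policies,
                                 _structural_support(ref_diag))
    ref_tables = {d: ref.policies[d].table[masks[d]] for d in decisions}
    thetas = _draws(params, param_id, n_samples, seed)
    changed = {d: 0 for d in decisions}
    any_changed = 0
    for th in thetas:
        diag = model_builder(params.with_values({param_id: float(th)}))
        res = evaluate_variable_elimination(diag)
        hit = False
        for d in decisions:
            if not np.array_equal(res.policies[d].table[masks[d]], ref_tables[d]):
                changed[d] += 1
                hit = True
        any_changed += hit
    per = {d: changed[d] / n_samples for d in decisions}
    out = ChangeProbability(param_id, per, any_changed / n_samples, n_samples, seed)
    return out.per_decision[decision] if decision else out


# -- batch reports ---------------------------------------------------------

def evpi_report(model_builder: ModelBuilder, params: ParameterSet,
                param_ids=None, n_samples: int = 1000, seed: int = 0) -> pd.DataFrame:
    """EVPI for every listed parameter (default: all), one row each.

    Seeds are derived per parameter from ``seed`` so rows are independent
    yet reproducible.
    """
    ids = list(param_ids) if param_ids is not None else params.ids()
    rows = []
    for j, pid in enumerate(ids):
        est = evpi_per_parameter(model_builder, params, pid, n_samples,
                                 seed=(seed * 100003 + j) % (2**31 - 1))
        rows.append({"param_id": pid, "evpi": est.evpi,
                     "std_error": est.std_error, "n_samples": est.n_samples,
                     "n_strategies": est.n_strategies})
    return pd.DataFrame(rows)


def change_probability_report(model_builder: ModelBuilder, params: ParameterSet,
                              param_ids=None, n_samples: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Per-(parameter, decision) change probabilities plus the any-decision
    aggregate, one row per parameter."""
    ids = list(param_ids) if param_ids is not None else params.ids()
    rows = []
    for j, pid in enumerate(ids):
        cp = decision_change_probability(
            model_builder, params, pid, n_samples=n_samples,
            seed=(seed * 100003 + j) % (2**31 - 1))
        row = {"param_id": pid, "any_change": cp.any_change}
        row.update({f"p_change[{d}]": v for d, v in cp.per_decision.items()})
        rows.append(row)
    return pd.DataFrame(rows)
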