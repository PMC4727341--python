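"""Strategy trees: compact contingent plans equivalent to optimal policies.

Policy tables grow exponentially with the number of observed variables and
mostly describe impossible scenarios (e.g. a recorded result for a test that
was never performed). A *strategy tree* prunes everything unreachable under
the earlier policies: decisions become action nodes carrying the chosen
option, observations become branching nodes over the outcomes that can
actually occur, and sibling branches with identical subtrees are merged.
Executing the tree achieves exactly the MEU of the evaluation it was built
from.

Simultaneously revealed observations (e.g. EBUS and EUS performed in one
session) are expanded as a single observation node over their joint outcome
space, avoiding an arbitrary serialization.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .diagram import CHANCE, InfluenceDiagram
from .errors import MediastageError
from .evaluation import EvaluationResult, joint_probability, total_utility

#: A joint outcome of an observation node: one state label per node variable.
Outcome = tuple[str, ...]


@dataclass(frozen=True)
class Action:
    """A decision together with the option the strategy selects; ``child``
    is the rest of the plan (``None`` after the final decision)."""

    decision: str
    option: str
    child: "Node"


@dataclass(frozen=True)
class Observation:
    """A branching point on one or more simultaneously observed variables.

    Each branch covers a set of joint outcomes (several when sibling
    branches with identical subtrees were merged).
    """

    variables: tuple[str, ...]
    branches: tuple[tuple[tuple[Outcome, ...], "Node"], ...]


Node = Action | Observation | None


def canonicalize(node: Node) -> Node:
    """Canonical form: subtrees canonicalized, sibling branches with equal
    subtrees merged, outcomes and branches sorted. Idempotent."""
    if node is None:
        return None
    if isinstance(node, Action):
        return Action(node.decision, node.option, canonicalize(node.child))
    groups: dict[Node, list[Outcome]] = {}
    order: list[Node] = []
    for outcomes, child in node.branches:
        c = canonicalize(child)
        if c not in groups:
            groups[c] = []
            order.append(c)
        groups[c].extend(outcomes)
    branches = tuple(
        (tuple(sorted(groups[c])), c) for c in order
    )
    return Observation(node.variables, tuple(sorted(branches, key=lambda b: b[0])))


def trees_equal(a: Node, b: Node) -> bool:
    """Structural equality after canonicalization."""
    return canonicalize(a) == canonicalize(b)


def build_strategy_tree(diag: InfluenceDiagram, result: EvaluationResult) -> Node:
    """Expand the optimal policies into a strategy tree.

    Observations are expanded in temporal order; variables whose outcome is
    forced (probability one) given the history do not branch; outcomes with
    probability zero under the history and earlier policies are dropped;
    sibling branches with identical subtrees are merged.
    """
    order, p_full = joint_probability(diag)
    axis = {v: i for i, v in enumerate(order)}
    cards = {v: diag.card(v) for v in order}
    groups = diag.temporal_groups()

    def block_distribution(block, evidence, chosen):
        """Joint probability over the block variables given the history
        (up to normalization by the history's probability)."""
        idx = []
        sum_axes = []
        k = 0
        for v in order:
            if v in evidence:
                idx.append(evidence[v])
            elif v in chosen:
                idx.append(chosen[v])
            elif v in block:
                idx.append(slice(None))
                k += 1
            elif diag.variables[v].role == CHANCE:
                idx.append(slice(None))
                sum_axes.append(k)
                k += 1
            else:
                idx.append(0)  # future decision: chance mass sums to 1 anyway
        sub = p_full[tuple(idx)]
        if sum_axes:
            sub = sub.sum(axis=tuple(sum_axes))
        # remaining axes follow the temporal order of the block variables
        return sub

    def policy_option(dec, evidence, chosen):
        pol = result.policies[dec]
        cfg = []
        for v in pol.predecessors:
            if v in evidence:
                cfg.append(evidence[v])
            elif v in chosen:
                cfg.append(chosen[v])
            else:
                raise MediastageError(
                    f"predecessor {v!r} of {dec!r} missing from the history")
        return int(pol.table[tuple(cfg)])

    def rec(gi, evidence, chosen) -> Node:
        if gi >= len(groups) - 1:  # the final block C_n is never expanded
            return None
        kind, block = groups[gi]
        if kind != CHANCE:
            dec = block[0]
            opt = policy_option(dec, evidence, chosen)
            child = rec(gi + 1, evidence, {**chosen, dec: opt})
            return Action(dec, diag.states(dec)[opt], child)
        block = [v for v in block]
        if not block:
            return rec(gi + 1, evidence, chosen)
        dist = block_distribution(block, evidence, chosen)
        support = np.argwhere(dist > 0)
        if len(support) == 0:
            raise MediastageError("history has probability zero")
        varying = [i for i in range(len(block))
                   if len({int(s[i]) for s in support}) > 1]
        forced = {block[i]: int(support[0][i]) for i in range(len(block))
                  if i not in varying}
        evidence = {**evidence, **forced}
        if not varying:
            return rec(gi + 1, evidence, chosen)
        node_vars = tuple(block[i] for i in varying)
        combos = sorted({tuple(int(s[i]) for i in varying) for s in support})
        branches = []
        for combo in combos:
            ev = {**evidence, **{v: c for v, c in zip(node_vars, combo)}}
            child = rec(gi + 1, ev, chosen)
            label = tuple(diag.states(v)[c] for v, c in zip(node_vars, combo))
            branches.append(((label,), child))
        return Observation(node_vars, tuple(branches))

    return canonicalize(rec(0, {}, {}))


def tree_expected_utility(diag: InfluenceDiagram, tree: Node) -> float:
    """Expected utility of executing the tree, by rolling the auxiliary
    network forward along its paths."""
    order, p_full = joint_probability(diag)
    pu = p_full * total_utility(diag)

    def leaf_value(evidence: dict[str, tuple[int, ...]], chosen: dict[str, int]) -> float:
        arr = pu
        # reduce trailing axes first so positions stay valid
        for ax in range(len(order) - 1, -1, -1):
            v = order[ax]
            if v in chosen:
                arr = arr.take(chosen[v], axis=ax)
            elif v in evidence:
                arr = arr.take(list(evidence[v]), axis=ax).sum(axis=ax)
            else:
                arr = arr.sum(axis=ax)
        return float(arr)

    total = 0.0
    stack = [(tree, {}, {})]
    while stack:
        node, evidence, chosen = stack.pop()
        if node is None:
            undecided = [d for d in diag.decision_order if d not in chosen]
            if undecided:
                raise MediastageError(f"tree leaves decisions {undecided} unset")
            total += leaf_value(evidence, chosen)
            continue
        if isinstance(node, Action):
            opt = diag.state_index(node.decision, node.option)
            stack.append((node.child, evidence, {**chosen, node.decision: opt}))
            continue
        for outcomes, child in node.branches:
            ev = dict(evidence)
            per_var: dict[str, set[int]] = {v: set() for v in node.variables}
            joint = []
            for out in outcomes:
                joint.append(tuple(diag.state_index(v, s)
                                   for v, s in zip(node.variables, out)))
            # merged outcomes may not factorize over the variables; handle
            # the common factorizing case axis-wise and fall back to an
            # explicit split otherwise
            if _factorizes(joint):
                for i, v in enumerate(node.variables):
                    ev[v] = tuple(sorted({j[i] for j in joint}))
                stack.append((child, ev, chosen))
            else:
                for j in joint:
                    ev2 = dict(evidence)
                    for v, s in zip(node.variables, j):
                        ev2[v] = (s,)
                    stack.append((child, ev2, chosen))
    return total


def _factorizes(joint: list[tuple[int, ...]]) -> bool:
    per_axis = [sorted({j[i] for j in joint}) for i in range(len(joint[0]))]
    return len(joint) == int(np.prod([len(a) for a in per_axis]))


# -- rendering -------------------------------------------------------------

def _branch_label(variables, outcomes) -> str:
    outs = [", ".join(f"{v}={s}" for v, s in zip(variables, out)) for out in outcomes]
    return " | ".join(outs)


def render(tree: Node, format: str = "text") -> str:
    """Deterministic serialization: ``text`` (two-space indent per level),
    ``dot`` (Graphviz) or ``json`` (round-trips via :func:`parse_json`)."""
    if format == "text":
        lines: list[str] = []

        def walk(node, depth):
            pad = "  " * depth
            if node is None:
                return
            if isinstance(node, Action):
                lines.append(f"{pad}{node.decision} = {node.option}")
                walk(node.child, depth)
                return
            for outcomes, child in node.branches:
                lines.append(f"{pad}[{_branch_label(node.variables, outcomes)}]")
                walk(child, depth + 1)

        walk(tree, 0)
        return "\n".join(lines) + "\n"

    if format == "dot":
        lines = ["digraph strategy {", "  node [fontsize=10];"]
        counter = itertools.count()

        def emit(node) -> str:
            nid = f"n{next(counter)}"
            if node is None:
                lines.append(f'  {nid} [shape=point];')
                return nid
            if isinstance(node, Action):
                lines.append(f'  {nid} [shape=box, label="{node.decision} = {node.option}"];')
                cid = emit(node.child)
                lines.append(f"  {nid} -> {cid};")
                return nid
            lines.append(f'  {nid} [shape=ellipse, label="{", ".join(node.variables)}"];')
            for outcomes, child in node.branches:
                cid = emit(child)
                lbl = _branch_label(node.variables, outcomes).replace('"', r'\"')
                lines.append(f'  {nid} -> {cid} [label="{lbl}"];')
            return nid

        emit(tree)
        lines.append("}")
        return "\n".join(lines) + "\n"

    if format == "json":
        return json.dumps(_to_doc(tree), indent=2)

    raise MediastageError(f"unknown strategy-tree format {format!r}")


def _to_doc(node: Node):
    if node is None:
        return None
    if isinstance(node, Action):
        return {"type": "action", "decision": node.decision,
                "option": node.option, "child": _to_doc(node.child)}
    return {"type": "observation", "variables": list(node.variables),
            "branches": [{"outcomes": [list(o) for o in outcomes],
                          "child": _to_doc(child)}
                         for outcomes, child in node.branches]}


def _from_doc(doc) -> Node:
    if doc is None:
        return None
    if doc["type"] == "action":
        return Action(doc["decision"], doc["option"], _from_doc(doc["child"]))
    return Observation(
        tuple(doc["variables"]),
        tuple((tuple(tuple(o) for o in b["outcomes"]), _from_doc(b["child"]))
              for b in doc["branches"]))


def parse_json(text: str) -> Node:
    return _from_doc(json.loads(text))
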