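"""Influence diagrams with ordinary and super-value utility nodes.

An influence diagram (ID) is an acyclic directed graph over three kinds of
variables: *chance* variables (uncertain events, each carrying a conditional
probability table), *decision* variables (actions, totally ordered in time),
and *utility* variables. Ordinary utility nodes map configurations of chance
and decision variables to real values; *super-value* nodes combine other
utility nodes by summation (with optional sign flips) or pointwise product.

The total order of decisions D_0 < ... < D_{n-1} partitions the chance
variables into information sets C_0, ..., C_n: C_i holds the variables first
observed before D_i, and C_n the variables that are never observed. Under the
no-forgetting assumption, the informational predecessors of D_i are
(C_0 ∪ ... ∪ C_i) ∪ {D_0, ..., D_{i-1}}.

This module provides the data model, validation, the information partition,
enumeration of consistent (reachable) information states, folding of the
super-value structure into a flat sum of ordinary tables, and a JSON
serialization that round-trips bit-exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import CapacityError, DiagramError

CHANCE = "chance"
DECISION = "decision"
UTILITY = "utility"

#: Tolerance for conditional probability tables summing to one.
CPT_TOL = 1e-12

#: Default bound on the number of entries of any materialized table.
DEFAULT_MAX_TABLE_SIZE = 50_000_000


@dataclass(frozen=True)
class Variable:
    """A node of the diagram.

    ``states`` is the ordered tuple of state labels for chance and decision
    variables and ``None`` for utility variables. State order is meaningful:
    parent configurations enumerate states in declared order with the last
    parent varying fastest, and ties in maximization are broken in favour of
    the earliest declared option.
    """

    name: str
    role: str
    states: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.role not in (CHANCE, DECISION, UTILITY):
            raise DiagramError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.states is not None:
            object.__setattr__(self, "states", tuple(self.states))


@dataclass
class ProbabilityTable:
    """P(child | parents), stored with parent axes first and the child last.

    ``table[i_1, ..., i_k, :]`` is the distribution over the child's states
    for the parent configuration (i_1, ..., i_k).
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)


@dataclass
class UtilityTable:
    """An ordinary utility function over configurations of its parents."""

    node: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)


@dataclass
class SuperValueSpec:
    """A utility node combining other utility nodes.

    ``operator`` is ``"sum"`` or ``"product"``; ``terms`` is a list of
    (utility node name, weight) with weight in {+1, -1}. Weights other than
    +1 are only meaningful under ``sum``.
    """

    node: str
    operator: str
    terms: tuple[tuple[str, int], ...]

    def __post_init__(self):
        self.terms = tuple((str(t), int(w)) for t, w in self.terms)


@dataclass(frozen=True)
class CostEffectivenessSettings:
    """Criterion settings: ``lambda_inverse`` in QALY per monetary unit.

    ``lambda_inverse = 0`` encodes the effectiveness-only criterion (costs
    are ignored); ``lambda_inverse = 1/λ`` with willingness-to-pay λ encodes
    the net-health-benefit criterion NHB = E - C/λ.
    """

    lambda_inverse: float = 0.0

    def __post_init__(self):
        if self.lambda_inverse < 0:
            raise DiagramError("lambda_inverse must be >= 0")


@dataclass
class Policy:
    """A (deterministic) policy for one decision.

    ``table`` holds option indices over the full grid of configurations of
    the decision's informational predecessors, in row-major order with the
    last predecessor varying fastest. Configurations that cannot occur under
    any strategy carry the tie-break option (index 0).
    """

    decision: str
    predecessors: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self):
        self.predecessors = tuple(self.predecessors)
        self.table = np.asarray(self.table, dtype=np.int64)


class InfluenceDiagram:
    """An influence diagram.

    Parameters
    ----------
    variables:
        Iterable of :class:`Variable`; declaration order fixes axis order of
        never-observed variables.
    decision_order:
        Decision names in temporal order D_0 ... D_{n-1}.
    observations:
        Mapping decision -> tuple of chance variables first observed before
        that decision (the sets C_0 ... C_{n-1}); chance variables absent
        from every entry form C_n.
    cpts, utilities, supervalues:
        Quantitative tables, one CPT per chance variable.
    root_value:
        The utility node whose expectation is maximized.
    """

    def __init__(self, variables, decision_order, observations, cpts,
                 utilities, supervalues=(), root_value=None):
        self.variables: dict[str, Variable] = {v.name: v for v in variables}
        self.decision_order: list[str] = list(decision_order)
        self.observations: dict[str, tuple[str, ...]] = {
            d: tuple(observations.get(d, ())) for d in self.decision_order
        }
        self.cpts: dict[str, ProbabilityTable] = {t.child: t for t in cpts}
        self.utilities: dict[str, UtilityTable] = {t.node: t for t in utilities}
        self.supervalues: dict[str, SuperValueSpec] = {s.node: s for s in supervalues}
        self.root_value: str | None = root_value

    # -- basic accessors ---------------------------------------------------

    def states(self, name: str) -> tuple[str, ...]:
        return self.variables[name].states

    def card(self, name: str) -> int:
        return len(self.variables[name].states)

    def state_index(self, name: str, state: str) -> int:
        return self.variables[name].states.index(state)

    @property
    def chance_names(self) -> list[str]:
        return [v.name for v in self.variables.values() if v.role == CHANCE]

    @property
    def utility_names(self) -> list[str]:
        return [v.name for v in self.variables.values() if v.role == UTILITY]

    @property
    def ordinary_utility_names(self) -> list[str]:
        return [n for n in self.utility_names if n not in self.supervalues]

    def partition(self) -> list[tuple[str, ...]]:
        """The information partition C_0, ..., C_n as ordered tuples."""
        observed = set()
        out = []
        for d in self.decision_order:
            block = self.observations[d]
            out.append(block)
            observed.update(block)
        tail = tuple(x for x in self.chance_names if x not in observed)
        out.append(tail)
        return out

    def temporal_groups(self):
        """Alternating [("chance", C_0), ("decision", D_0), ..., ("chance", C_n)]."""
        part = self.partition()
        groups = []
        for i, d in enumerate(self.decision_order):
            groups.append((CHANCE, part[i]))
            groups.append((DECISION, (d,)))
        groups.append((CHANCE, part[-1]))
        return groups

    def global_order(self) -> list[str]:
        """All chance and decision variables in temporal order."""
        return [v for _, block in self.temporal_groups() for v in block]

    def informational_predecessors(self, decision: str) -> tuple[str, ...]:
        """Variables known when making ``decision``, in temporal order."""
        out = []
        for kind, block in self.temporal_groups():
            if kind == DECISION and block[0] == decision:
                return tuple(out)
            out.extend(block)
        raise DiagramError(f"{decision!r} is not a decision of this diagram")

    def cards(self, names) -> tuple[int, ...]:
        return tuple(self.card(n) for n in names)


# -- broadcasting helper ---------------------------------------------------

def expand(arr: np.ndarray, arr_vars, order) -> np.ndarray:
    """Reshape ``arr`` (axes ``arr_vars``) for broadcasting over ``order``."""
    pos = {v: i for i, v in enumerate(order)}
    perm = sorted(range(len(arr_vars)), key=lambda i: pos[arr_vars[i]])
    a = np.transpose(arr, perm)
    present = set(arr_vars)
    shape = []
    it = iter(a.shape)
    for v in order:
        shape.append(next(it) if v in present else 1)
    return a.reshape(shape)


def structural_graph(diag: InfluenceDiagram) -> nx.DiGraph:
    """Directed graph of functional and informational arcs."""
    g = nx.DiGraph()
    g.add_nodes_from(diag.variables)
    for t in diag.cpts.values():
        for p in t.parents:
            g.add_edge(p, t.child)
    for t in diag.utilities.values():
        for p in t.parents:
            g.add_edge(p, t.node)
    for s in diag.supervalues.values():
        for term, _ in s.terms:
            g.add_edge(term, s.node)
    for d, block in diag.observations.items():
        for x in block:
            g.add_edge(x, d)
    return g


# -- validation ------------------------------------------------------------

def validate(diag: InfluenceDiagram) -> list[str]:
    """Check every structural invariant; return one diagnostic per violation.

    An empty list means the diagram is well formed. Diagnostics are
    human-readable strings; nothing raises.
    """
    out: list[str] = []
    roles = {}
    for name, v in diag.variables.items():
        roles[name] = v.role
        if v.role in (CHANCE, DECISION):
            if not v.states:
                out.append(f"{name}: chance/decision variable without states")
            elif len(set(v.states)) != len(v.states):
                out.append(f"{name}: duplicate state labels")
        else:
            if v.states is not None:
                out.append(f"{name}: utility variable must not carry states")

    for d in diag.decision_order:
        if roles.get(d) != DECISION:
            out.append(f"decision order contains non-decision {d!r}")
    missing = [n for n, r in roles.items() if r == DECISION and n not in diag.decision_order]
    for n in missing:
        out.append(f"decision {n!r} missing from the decision order")

    seen = {}
    for d, block in diag.observations.items():
        for x in block:
            if roles.get(x) != CHANCE:
                out.append(f"observation set of {d!r} contains non-chance {x!r}")
            if x in seen:
                out.append(f"{x!r} observed before both {seen[x]!r} and {d!r}")
            seen[x] = d

    # conditional probability tables
    for name in diag.chance_names:
        t = diag.cpts.get(name)
        if t is None:
            out.append(f"{name}: chance variable without a probability table")
            continue
        shape_ok = True
        for p in t.parents:
            if roles.get(p) not in (CHANCE, DECISION):
                out.append(f"CPT of {name}: invalid parent {p!r}")
                shape_ok = False
        if shape_ok:
            want = diag.cards(t.parents) + (diag.card(name),)
            if t.table.shape != want:
                out.append(f"CPT of {name}: shape {t.table.shape} != {want}")
                shape_ok = False
        if shape_ok:
            if np.any(t.table < -CPT_TOL) or np.any(t.table > 1 + CPT_TOL):
                out.append(f"CPT of {name}: entries outside [0, 1]")
            sums = t.table.sum(axis=-1)
            if np.any(np.abs(sums - 1.0) > CPT_TOL):
                bad = float(np.abs(sums - 1.0).max())
                out.append(
                    f"CPT of {name}: columns must sum to 1 "
                    f"(worst deviation {bad:.3g})"
                )

    # utility tables
    for name, t in diag.utilities.items():
        if roles.get(name) != UTILITY:
            out.append(f"utility table attached to non-utility {name!r}")
            continue
        ok = all(roles.get(p) in (CHANCE, DECISION) for p in t.parents)
        if not ok:
            out.append(f"utility {name}: invalid parents {t.parents}")
        elif t.table.shape != diag.cards(t.parents):
            out.append(f"utility {name}: shape {t.table.shape} != {diag.cards(t.parents)}")
        elif not np.all(np.isfinite(t.table)):
            out.append(f"utility {name}: non-finite values")

    # super-value structure
    sv_graph = nx.DiGraph()
    for name, s in diag.supervalues.items():
        if s.operator not in ("sum", "product"):
            out.append(f"super-value {name}: unknown operator {s.operator!r}")
        for term, w in s.terms:
            if roles.get(term) != UTILITY:
                out.append(f"super-value {name}: term {term!r} is not a utility node")
            if w not in (1, -1):
                out.append(f"super-value {name}: weight {w} not in {{+1, -1}}")
            elif w == -1 and s.operator == "product":
                out.append(f"super-value {name}: signed terms only allowed under sum")
            sv_graph.add_edge(term, name)
    if not nx.is_directed_acyclic_graph(sv_graph):
        out.append("super-value dependencies contain a cycle")
    for name in diag.utility_names:
        if name not in diag.utilities and name not in diag.supervalues:
            out.append(f"utility {name!r} has neither a table nor a super-value spec")
    if diag.root_value is not None and roles.get(diag.root_value) != UTILITY:
        out.append(f"root value {diag.root_value!r} is not a utility node")

    g = structural_graph(diag)
    if not nx.is_directed_acyclic_graph(g):
        out.append("the diagram graph contains a directed cycle")
        return out  # downstream checks assume acyclicity

    # a directed path must connect consecutive decisions
    for a, b in itertools.pairwise(diag.decision_order):
        if not nx.has_path(g, a, b):
            out.append(f"no directed path connects decisions {a!r} and {b!r}")

    # temporal consistency: an observed chance variable may not depend,
    # directly or through ancestors, on a decision made after it is observed
    dec_index = {d: i for i, d in enumerate(diag.decision_order)}
    part = diag.partition()
    block_of = {}
    for i, block in enumerate(part):
        for x in block:
            block_of[x] = i
    for name in diag.chance_names:
        b = block_of.get(name)
        if b is None or b >= len(diag.decision_order):
            continue  # never observed: unconstrained
        t = diag.cpts.get(name)
        if t is None:
            continue
        ancestors = nx.ancestors(g, name)
        late = sorted(d for d in ancestors if dec_index.get(d, -1) >= b)
        if late:
            out.append(
                f"{name} is observed before {diag.decision_order[b]} "
                f"but depends on later decision(s) {late}"
            )
    return out


def information_partition(diag: InfluenceDiagram) -> list[tuple[str, ...]]:
    """C_0, ..., C_n for a valid diagram (validation errors raise)."""
    problems = validate(diag)
    if problems:
        raise DiagramError("invalid diagram: " + "; ".join(problems))
    return diag.partition()


# -- reachability ----------------------------------------------------------

def _support_joint(diag: InfluenceDiagram, max_size=DEFAULT_MAX_TABLE_SIZE) -> tuple[list[str], np.ndarray]:
    """Boolean array over all chance+decision variables marking configurations
    with nonzero probability under at least one strategy."""
    order = diag.global_order()
    size = int(np.prod(diag.cards(order), dtype=np.int64))
    if size > max_size:
        raise CapacityError(f"support table of {size} entries exceeds the bound {max_size}")
    supp = np.ones(diag.cards(order), dtype=bool)
    for t in diag.cpts.values():
        supp &= expand(t.table > 0, t.parents + (t.child,), order)
    return order, supp


def consistent_configurations(diag: InfluenceDiagram, decision: str) -> set[tuple[str, ...]]:
    """Configurations of the decision's informational predecessors that have
    nonzero probability under at least one strategy.

    In the staging model this excludes, e.g., observing a test result for a
    test that was not performed.
    """
    preds = diag.informational_predecessors(decision)
    mask = consistent_mask(diag, decision)
    out = set()
    states = [diag.states(p) for p in preds]
    for idx in np.argwhere(mask):
        out.add(tuple(states[k][i] for k, i in enumerate(idx)))
    return out


def consistent_mask(diag: InfluenceDiagram, decision: str) -> np.ndarray:
    """Boolean array over the predecessor grid of ``decision``; True where
    the configuration is reachable under some strategy."""
    preds = diag.informational_predecessors(decision)
    order, supp = _support_joint(diag)
    drop = tuple(i for i, v in enumerate(order) if v not in preds)
    reduced = supp.any(axis=drop) if drop else supp
    # axes of `reduced` follow `order`; predecessors are a temporal prefix,
    # so the order already matches `preds`
    kept = [v for v in order if v in preds]
    assert kept == list(preds)
    return reduced


# -- super-value folding ---------------------------------------------------

def supervalue_utility(diag: InfluenceDiagram, config: dict[str, str],
                       node: str | None = None) -> float:
    """Recursively evaluate the (super-)utility ``node`` at a full
    configuration of chance and decision variables. Reference semantics for
    :func:`fold_supervalue`."""
    node = node or diag.root_value
    if node in diag.utilities:
        t = diag.utilities[node]
        idx = tuple(diag.state_index(p, config[p]) for p in t.parents)
        return float(t.table[idx])
    s = diag.supervalues[node]
    vals = [w * supervalue_utility(diag, config, term) for term, w in s.terms]
    if s.operator == "sum":
        return float(sum(vals))
    prod = 1.0
    for v in vals:
        prod *= v
    return float(prod)


def _fold_terms(diag, node, max_table_size) -> list[UtilityTable]:
    if node in diag.utilities:
        t = diag.utilities[node]
        return [UtilityTable(t.node, t.parents, t.table.copy())]
    s = diag.supervalues[node]
    if s.operator == "sum":
        out = []
        for term, w in s.terms:
            for sub in _fold_terms(diag, term, max_table_size):
                if w == -1:
                    sub = UtilityTable(sub.node, sub.parents, -sub.table)
                out.append(sub)
        return out
    # product: distribute over the sums of each factor
    factor_terms = [_fold_terms(diag, term, max_table_size) for term, _ in s.terms]
    out = []
    for combo in itertools.product(*factor_terms):
        parents = []
        for t in combo:
            for p in t.parents:
                if p not in parents:
                    parents.append(p)
        parents = tuple(parents)
        size = int(np.prod(diag.cards(parents), dtype=np.int64)) if parents else 1
        if size > max_table_size:
            raise CapacityError(
                f"folding product node {node!r} needs a table of {size} entries "
                f"(bound {max_table_size})"
            )
        table = np.ones(diag.cards(parents))
        for t in combo:
            table = table * expand(t.table, t.parents, parents)
        name = node if len(combo) == len(s.terms) and all(
            len(ft) == 1 for ft in factor_terms) else node + "." + "*".join(t.node for t in combo)
        out.append(UtilityTable(name, parents, table))
    return out


def fold_supervalue(diag: InfluenceDiagram,
                    max_table_size: int = 1_000_000) -> InfluenceDiagram:
    """Compile the super-value structure into a flat sum of ordinary tables.

    Product nodes are folded by pointwise multiplication over the union of
    their parents (distributing over sums), signed sum terms negate tables.
    The returned diagram has a single sum-type root over ordinary tables and
    the same expected utility for every strategy.
    """
    if diag.root_value is None:
        raise DiagramError("diagram has no root value node")
    terms = _fold_terms(diag, diag.root_value, max_table_size)
    # disambiguate duplicated names (a node may feed several sum terms)
    names = {diag.root_value}
    uniq = []
    for t in terms:
        name = t.node
        k = 1
        while name in names:
            name = f"{t.node}#{k}"
            k += 1
        names.add(name)
        uniq.append(UtilityTable(name, t.parents, t.table))
    root = diag.root_value
    variables = [v for v in diag.variables.values() if v.role != UTILITY]
    variables += [Variable(t.node, UTILITY) for t in uniq]
    variables.append(Variable(root, UTILITY))
    sv = SuperValueSpec(root, "sum", tuple((t.node, 1) for t in uniq))
    return InfluenceDiagram(
        variables=variables,
        decision_order=diag.decision_order,
        observations=diag.observations,
        cpts=list(diag.cpts.values()),
        utilities=uniq,
        supervalues=[sv],
        root_value=root,
    )


def folded_utility_tables(diag: InfluenceDiagram,
                          max_table_size: int = 1_000_000) -> list[UtilityTable]:
    """The additive terms of the folded root utility."""
    if not diag.supervalues:
        if diag.root_value in diag.utilities:
            return [diag.utilities[diag.root_value]]
        raise DiagramError("diagram has no root value structure")
    return _fold_terms(diag, diag.root_value, max_table_size)


# -- JSON serialization ----------------------------------------------------

def to_json(diag: InfluenceDiagram, indent: int | None = 2) -> str:
    """Serialize to the documented JSON schema.

    Tables are flattened row-major (last axis varying fastest), matching the
    configuration-enumeration convention used everywhere in the package.
    """
    doc = {
        "variables": [
            {"name": v.name, "role": v.role,
             "states": list(v.states) if v.states is not None else None}
            for v in diag.variables.values()
        ],
        "decision_order": list(diag.decision_order),
        "observations": {d: list(b) for d, b in diag.observations.items()},
        "cpts": [
            {"child": t.child, "parents": list(t.parents),
             "values": t.table.ravel().tolist()}
            for t in diag.cpts.values()
        ],
        "utilities": [
            {"node": t.node, "parents": list(t.parents),
             "values": t.table.ravel().tolist()}
            for t in diag.utilities.values()
        ],
        "supervalues": [
            {"node": s.node, "operator": s.operator,
             "terms": [[t, w] for t, w in s.terms]}
            for s in diag.supervalues.values()
        ],
        "root_value": diag.root_value,
    }
    return json.dumps(doc, indent=indent)


def from_json(text: str) -> InfluenceDiagram:
    doc = json.loads(text)
    variables = [
        Variable(v["name"], v["role"],
                 tuple(v["states"]) if v["states"] is not None else None)
        for v in doc["variables"]
    ]
    cards = {v.name: len(v.states) for v in variables if v.states is not None}
    cpts = []
    for t in doc["cpts"]:
        shape = tuple(cards[p] for p in t["parents"]) + (cards[t["child"]],)
        cpts.append(ProbabilityTable(t["child"], tuple(t["parents"]),
                                     np.array(t["values"]).reshape(shape)))
    utils = []
    for t in doc["utilities"]:
        shape = tuple(cards[p] for p in t["parents"])
        utils.append(UtilityTable(t["node"], tuple(t["parents"]),
                                  np.array(t["values"]).reshape(shape)))
    svs = [SuperValueSpec(s["node"], s["operator"],
                          tuple((t, w) for t, w in s["terms"]))
           for s in doc["supervalues"]]
    return InfluenceDiagram(
        variables=variables,
        decision_order=doc["decision_order"],
        observations={d: tuple(b) for d, b in doc["observations"].items()},
        cpts=cpts,
        utilities=utils,
        supervalues=svs,
        root_value=doc["root_value"],
    )
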