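"""Conditional probability rules, BKB validity, and inference enumeration.

A Bayesian knowledge base (BKB) is a finite set of conditional probability
rules (CPRs) over discrete random-variable assignments.  Unlike a Bayesian
network it tolerates cycles between variables and incompletely specified
distributions; validity instead demands that rules sharing a consequent
variable be mutually exclusive through their antecedents, and that weights
of consequent-bound rule cliques sum to at most one.

States may be plain tokens (strings, ints) or :class:`~bkofusion.concepts.
Assertion` objects.  When an axiom store is supplied, validity checks also
recognise exclusivity carried by *inconsistent assertion states* (the same
individual pinned into declared-disjoint classes), which is how source
conjuncts from different fused fragments keep parallel rules exclusive.
Inference enumeration deliberately stays at the plain rv level — see
docs/methods.md for why the two levels differ.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Hashable, Iterable, List, Optional, Tuple

import networkx as nx

from .concepts import Assertion, AxiomStore, assertions_consistent

#: tolerance on every Σ ≤ 1 check (floating weights accumulate error;
#: exact fractions pass untouched)
SUM_TOLERANCE = 1e-9

UNSPECIFIED = None  # probability placeholder for reasoning-anchor rules


def as_probability(p) -> Optional[Fraction]:
    """Coerce a weight to an exact fraction; ``None`` stays unspecified.

    Strings and floats go through their decimal representation so that the
    weight printed in an exchange file survives bit-exactly.
    """
    if p is None:
        return None
    if isinstance(p, Fraction):
        value = p
    elif isinstance(p, int):
        value = Fraction(p)
    elif isinstance(p, float):
        value = Fraction(str(p))
    elif isinstance(p, str):
        value = Fraction(p) if "/" in p else Fraction(str(p))
    else:
        raise TypeError(f"cannot interpret probability: {p!r}")
    if not 0 <= value <= 1:
        raise ValueError(f"probability out of [0, 1]: {p}")
    return value


@dataclass(frozen=True)
class RVAssignment:
    """One random variable pinned to one of its states."""

    rv: str
    state: Hashable

    def __str__(self) -> str:
        return f"{self.rv}={self.state}"

    def __lt__(self, other: "RVAssignment") -> bool:
        return str(self) < str(other)


@dataclass(frozen=True)
class CPR:
    """If-then rule P(consequent | antecedent) = p.

    An empty antecedent is a prior.  Antecedent rvs are pairwise distinct
    and distinct from the consequent rv.  ``rule_id`` is a stable hash of
    the canonical form so provenance survives round-trips; ``source`` is
    fusion metadata (fragment label), not identity.
    """

    antecedent: FrozenSet[RVAssignment]
    consequent: RVAssignment
    p: Optional[Fraction]
    source: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        rvs = [a.rv for a in self.antecedent]
        if len(set(rvs)) != len(rvs):
            raise ValueError("antecedent rvs must be pairwise distinct")
        if self.consequent.rv in set(rvs):
            raise ValueError("consequent rv cannot appear in the antecedent")
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValueError(f"probability out of [0, 1]: {self.p}")

    @property
    def rule_id(self) -> str:
        return hashlib.sha1(str(self).encode()).hexdigest()[:12]

    def __str__(self) -> str:
        ant = "∧".join(sorted(str(a) for a in self.antecedent))
        p = "?" if self.p is None else str(self.p)
        return f"P({self.consequent}|{ant})={p}" if ant else f"P({self.consequent})={p}"

    def __lt__(self, other: "CPR") -> bool:
        return str(self) < str(other)


def cpr(antecedent: Iterable[RVAssignment], consequent: RVAssignment, p,
        source: Optional[str] = None) -> CPR:
    """Convenience constructor coercing ``p`` to an exact fraction."""
    return CPR(frozenset(antecedent), consequent, as_probability(p), source)


def _states_conflict(s1: Hashable, s2: Hashable, axioms: Optional[AxiomStore]) -> bool:
    """States of *different* rvs can still be exclusive when they are
    assertions the governing axioms declare inconsistent."""
    if axioms is None:
        return False
    if isinstance(s1, Assertion) and isinstance(s2, Assertion):
        return not assertions_consistent(s1, s2, axioms)
    return False


def _assignments_conflict(a1: RVAssignment, a2: RVAssignment,
                          axioms: Optional[AxiomStore]) -> bool:
    if a1.rv == a2.rv:
        return a1.state != a2.state
    return _states_conflict(a1.state, a2.state, axioms)


def cpr_mutually_exclusive(r1: CPR, r2: CPR,
                           axioms: Optional[AxiomStore] = None) -> bool:
    """Can the two antecedents never be satisfied together?"""
    for a1 in r1.antecedent:
        for a2 in r2.antecedent:
            if _assignments_conflict(a1, a2, axioms):
                return True
    return False


def cpr_consequent_bound(r1: CPR, r2: CPR,
                         axioms: Optional[AxiomStore] = None) -> bool:
    """Compatible antecedents, conflicting consequents on the same variable."""
    if cpr_mutually_exclusive(r1, r2, axioms):
        return False
    return _assignments_conflict(r1.consequent, r2.consequent, axioms)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a validity check; violations are data, not exceptions."""

    mutex_violations: Tuple[Tuple[CPR, CPR], ...]
    sum_violations: Tuple[Tuple[Tuple[CPR, ...], Fraction], ...]

    @property
    def valid(self) -> bool:
        return not self.mutex_violations and not self.sum_violations

    def __str__(self) -> str:
        if self.valid:
            return "valid"
        lines = []
        for r1, r2 in self.mutex_violations:
            lines.append(f"exclusivity violation: {r1}  //  {r2}")
        for clique, total in self.sum_violations:
            lines.append(
                f"weight-sum violation (Σ={float(total):.6g}): "
                + "; ".join(str(r) for r in clique)
            )
        return "\n".join(lines)


def validate_bkb(rules: Iterable[CPR],
                 axioms: Optional[AxiomStore] = None) -> ValidationReport:
    """Check the two BKB validity conditions.

    (i) distinct rules with the same consequent assignment must be mutually
    exclusive; (ii) every set of mutually consequent-bound rules has weight
    sum ≤ 1, checked on maximal cliques of the pairwise consequent-bound
    graph (subset sums are maximized there).

    Two refinements for knowledge bases over membership assertions: rules
    with unspecified weights (reasoning anchors) are query scaffolding and
    skipped, and a non-exclusive pair concluding the *identical assertion*
    is redundant support rather than a conflict (several support nodes
    feeding one instantiation node).  Token-state rule sets get the strict
    check.
    """
    rules = sorted(r for r in set(rules) if r.p is not None)
    mutex_violations = []
    bound_graph = nx.Graph()
    bound_graph.add_nodes_from(range(len(rules)))
    for i, r1 in enumerate(rules):
        for j in range(i + 1, len(rules)):
            r2 = rules[j]
            if r1.consequent == r2.consequent:
                if isinstance(r1.consequent.state, Assertion):
                    continue
                if not cpr_mutually_exclusive(r1, r2, axioms):
                    mutex_violations.append((r1, r2))
            elif cpr_consequent_bound(r1, r2, axioms):
                bound_graph.add_edge(i, j)

    sum_violations = []
    for clique in nx.find_cliques(bound_graph):
        if len(clique) < 2:
            continue
        members = tuple(rules[i] for i in sorted(clique))
        total = sum((r.p for r in members if r.p is not None), Fraction(0))
        if float(total) > 1 + SUM_TOLERANCE:
            sum_violations.append((members, Fraction(total)))
    return ValidationReport(tuple(mutex_violations), tuple(sorted(
        sum_violations, key=lambda v: str(v[0]))))


class BKB:
    """A set of CPRs with a derived rv registry and optional axiom store."""

    def __init__(self, rules: Iterable[CPR] = (),
                 axioms: Optional[AxiomStore] = None) -> None:
        self.rules: Tuple[CPR, ...] = tuple(sorted(set(rules)))
        self.axioms = axioms
        self.rv_registry: Dict[str, set] = {}
        for r in self.rules:
            for a in r.antecedent | {r.consequent}:
                self.rv_registry.setdefault(a.rv, set()).add(a.state)

    def validate(self) -> ValidationReport:
        return validate_bkb(self.rules, self.axioms)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __contains__(self, rule: CPR) -> bool:
        return rule in set(self.rules)


# ---------------------------------------------------------------------------
# Inferences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Inference:
    """An acyclic, mutually compatible deductive rule set.

    Every antecedent assignment is supported by exactly one rule's
    consequent; the probability is the product of the member weights
    (unspecified anchor weights contribute no factor).
    """

    rules: FrozenSet[CPR]

    @property
    def induced(self) -> FrozenSet[RVAssignment]:
        return frozenset(r.consequent for r in self.rules)

    @property
    def probability(self) -> Fraction:
        return inference_probability(self)

    def __str__(self) -> str:
        return "{" + ", ".join(sorted(str(a) for a in self.induced)) + "}"

    def __len__(self) -> int:
        return len(self.rules)

    def __lt__(self, other: "Inference") -> bool:
        return str(self) < str(other)


EMPTY_INFERENCE = Inference(frozenset())


def inference_probability(inference: Inference) -> Fraction:
    """P(I) = ∏ P(R), an exact product over specified weights."""
    prob = Fraction(1)
    for r in inference.rules:
        if r.p is not None:
            prob *= r.p
    return prob


def inferences_compatible(i1: Inference, i2: Inference) -> bool:
    """Compatible inferences agree on every shared random variable."""
    v1 = {a.rv: a.state for a in i1.induced}
    for a in i2.induced:
        if a.rv in v1 and v1[a.rv] != a.state:
            return False
    return True


@dataclass(frozen=True)
class InferenceSet:
    """Enumeration result; ``truncated`` flags a hit size cap."""

    inferences: Tuple[Inference, ...]
    truncated: bool = False

    def __iter__(self):
        return iter(self.inferences)

    def __len__(self) -> int:
        return len(self.inferences)


def enumerate_inferences(bkb: Iterable[CPR],
                         anchor: Optional[Iterable[RVAssignment]] = None,
                         max_rules: Optional[int] = None) -> InferenceSet:
    """Every inference over the rule set, in deterministic order.

    Grown forward from the empty inference: a rule may join once its whole
    antecedent is already induced and its consequent variable is still
    free, which makes acyclicity and mutual compatibility structural.
    When ``anchor`` is given only inferences whose induced set contains it
    are returned (the search itself is unrestricted, so partially anchored
    prefixes are still explored).
    """
    rules = sorted(set(bkb))
    anchor = frozenset(anchor or ())
    truncated = False
    seen = {frozenset()}
    frontier: List[FrozenSet[CPR]] = [frozenset()]
    while frontier:
        current = frontier.pop()
        assigned = {r.consequent.rv: r.consequent.state for r in current}
        induced = frozenset(r.consequent for r in current)
        for rule in rules:
            if rule in current or rule.consequent.rv in assigned:
                continue
            if not all(a in induced for a in rule.antecedent):
                continue
            if max_rules is not None and len(current) >= max_rules:
                truncated = True
                continue
            grown = current | {rule}
            if grown not in seen:
                seen.add(grown)
                frontier.append(grown)
    out = [Inference(s) for s in seen]
    if anchor:
        out = [i for i in out if anchor <= i.induced]
    return InferenceSet(tuple(sorted(out)), truncated)


def is_maximal(inference: Inference, bkb: Iterable[CPR]) -> bool:
    """No compatible rule can extend the inference."""
    assigned = {r.consequent.rv for r in inference.rules}
    induced = inference.induced
    for rule in bkb:
        if rule in inference.rules or rule.consequent.rv in assigned:
            continue
        if all(a in induced for a in rule.antecedent):
            return False
    return True


# ---------------------------------------------------------------------------
# Minimal-support inferences (the unit of posterior mass)
# ---------------------------------------------------------------------------

def support_inferences(bkb: Iterable[CPR],
                       targets: Iterable[RVAssignment]) -> List[Inference]:
    """All minimal inferences whose induced set contains ``targets``.

    Backward chaining: each needed assignment picks one supporting rule
    (a rule whose consequent *is* that assignment), recursively, keeping
    one rule per variable; cyclic support closures are discarded.  Distinct
    results differ in at least one support choice, so in a valid BKB they
    are pairwise incompatible and their probabilities may be summed.
    """
    rules = sorted(set(bkb))
    by_consequent: Dict[RVAssignment, List[CPR]] = {}
    for r in rules:
        by_consequent.setdefault(r.consequent, []).append(r)

    targets = sorted(set(targets))
    results: set[FrozenSet[CPR]] = set()

    def extend(chosen: Dict[str, CPR], pending: Tuple[RVAssignment, ...]) -> None:
        if not pending:
            closure = frozenset(chosen.values())
            if _support_acyclic(closure):
                results.add(closure)
            return
        need, rest = pending[0], pending[1:]
        if need.rv in chosen:
            if chosen[need.rv].consequent == need:
                extend(chosen, rest)
            return  # variable already supported with a different state
        for rule in by_consequent.get(need, []):
            nxt = dict(chosen)
            nxt[need.rv] = rule
            extend(nxt, tuple(sorted(rule.antecedent)) + rest)

    extend({}, tuple(targets))
    return sorted(Inference(s) for s in results)


def _support_acyclic(rules: FrozenSet[CPR]) -> bool:
    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(rules)))
    ordered = sorted(rules)
    for i, r1 in enumerate(ordered):
        for j, r2 in enumerate(ordered):
            if i != j and r1.consequent in r2.antecedent:
                graph.add_edge(i, j)
    return nx.is_directed_acyclic_graph(graph)


def joint_mass(bkb: Iterable[CPR],
               assignments: Iterable[RVAssignment]) -> Optional[Fraction]:
    """Probability mass the rule set assigns to a conjunction of states.

    Σ P(I) over the minimal-support inferences of the conjunction; the
    empty conjunction has mass 1 (the empty inference).  ``None`` when no
    support exists (the mass is incalculable, not zero).
    """
    assignments = frozenset(assignments)
    if not assignments:
        return Fraction(1)
    supports = support_inferences(bkb, assignments)
    if not supports:
        return None
    return sum((i.probability for i in supports), Fraction(0))
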