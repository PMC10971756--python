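"""Probabilistic assertional and terminological axioms, and BKO validity.

A Bayesian knowledge-driven ontology (BKO) holds two kinds of rule:

* **PAA** — a probabilistic assertional axiom, a conditional probability
  rule whose random-variable states are class-membership assertions about
  specific individuals.  A PAA *is* a CPR and converts to one.
* **PTA** — a probabilistic terminological axiom, the first-order
  counterpart quantifying over variable individuals; instantiating it with
  a one-to-one substitution yields a PAA with the same weight.

Validity generalizes BKB validity: distinct rules must either be mutually
exclusive (their antecedents cannot hold together), or their consequents
must tolerate each other's negation; consequent-bound groups must have
weight sums at most one.  Quantified conditions on PTAs are decided by
enumerating substitutions over the finite individual pool, which is
exhaustive (hence sound and complete) for the restricted constructor
grammar used here.

Two deliberate refinements, documented in docs/methods.md:

* rules whose instantiated consequents are the *identical assertion* are
  tolerated — parallel derivations of one membership fact are redundancy,
  not contradiction (graphically: several support nodes feeding one
  instantiation node);
* rules with unspecified (anchor) weights are query scaffolding and are
  skipped by validity checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple, Union

from .bkb import CPR, RVAssignment, as_probability
from .concepts import (
    Assertion,
    AxiomStore,
    ConceptExpr,
    DomainLexicon,
    EMPTY_AXIOMS,
    Individual,
    VariableIndividual,
    assertion_rv_key,
    assertions_consistent,
    concept_individuals,
    concept_variables,
    negate,
    set_consistent,
    sets_consistent,
    substitute_concept,
)


class CompatibilityError(ValueError):
    """An instantiation function does not fit the rule it is applied to."""


class ConversionError(ValueError):
    """A classical axiom form that has no probabilistic encoding here."""


# ---------------------------------------------------------------------------
# Variable assertions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableAssertion:
    """ŷ ∈ Ĉ — membership of an unspecified individual; the concept may mix
    variable and specific individuals."""

    subject: VariableIndividual
    concept: ConceptExpr

    def variables(self) -> FrozenSet[VariableIndividual]:
        return frozenset({self.subject}) | concept_variables(self.concept)

    def __str__(self) -> str:
        return f"{self.subject}∈{self.concept}"

    def __lt__(self, other) -> bool:
        return str(self) < str(other)


PTAClause = Union[VariableAssertion, Assertion]


def substitute(clause: PTAClause, mapping: Dict[VariableIndividual, Individual]):
    """Apply a variable→individual mapping to a clause; ground clauses pass
    through, and a fully mapped variable assertion grounds to an Assertion."""
    if isinstance(clause, Assertion):
        return Assertion(clause.individual, substitute_concept(clause.concept, mapping))
    subject = mapping.get(clause.subject, clause.subject)
    concept = substitute_concept(clause.concept, mapping)
    if isinstance(subject, Individual) and not concept_variables(concept):
        return Assertion(subject, concept)
    return VariableAssertion(subject, concept)


# ---------------------------------------------------------------------------
# PAA / PTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PAA:
    """P(consequent | antecedent) = p over membership assertions.

    ``source`` and ``provenance`` (the originating PTA id and substitution)
    are metadata, not identity.
    """

    antecedent: FrozenSet[Assertion]
    consequent: Assertion
    p: Optional[Fraction]
    source: Optional[str] = field(default=None, compare=False)
    provenance: Optional[Tuple] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValueError(f"probability out of [0, 1]: {self.p}")

    @property
    def assertions(self) -> FrozenSet[Assertion]:
        return self.antecedent | {self.consequent}

    def to_cpr(self, axioms: AxiomStore = EMPTY_AXIOMS) -> CPR:
        """Re-type as a CPR over partition-induced random variables."""
        ant = frozenset(
            RVAssignment(assertion_rv_key(a, axioms), a) for a in self.antecedent
        )
        con = RVAssignment(assertion_rv_key(self.consequent, axioms), self.consequent)
        return CPR(ant, con, self.p, self.source)

    def __str__(self) -> str:
        ant = "∧".join(sorted(str(a) for a in self.antecedent))
        p = "?" if self.p is None else str(self.p)
        return f"P({self.consequent}|{ant})={p}" if ant else f"P({self.consequent})={p}"

    def __lt__(self, other) -> bool:
        return str(self) < str(other)


def paa(antecedent: Iterable[Assertion], consequent: Assertion, p,
        source: Optional[str] = None, provenance: Optional[Tuple] = None) -> PAA:
    return PAA(frozenset(antecedent), consequent, as_probability(p), source, provenance)


@dataclass(frozen=True)
class PTA:
    """First-order rule over variable assertions.

    The consequent's variable individual must be bound in the antecedent —
    either as the subject of an antecedent clause or inside one of their
    concept formulas.  Ground clauses (e.g. source assertions added by
    fusion) are permitted in the antecedent.
    """

    antecedent: FrozenSet[PTAClause]
    consequent: VariableAssertion
    p: Optional[Fraction]
    pta_id: str = field(default="", compare=False)
    source: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValueError(f"probability out of [0, 1]: {self.p}")
        subject = self.consequent.subject
        bound = False
        for clause in self.antecedent:
            if isinstance(clause, VariableAssertion):
                if clause.subject == subject or subject in concept_variables(clause.concept):
                    bound = True
        if not bound:
            raise ValueError(
                f"consequent variable {subject} is not bound in the antecedent"
            )

    def variables(self) -> FrozenSet[VariableIndividual]:
        """I(T): every variable individual occurring in the rule."""
        out = self.consequent.variables()
        for clause in self.antecedent:
            if isinstance(clause, VariableAssertion):
                out |= clause.variables()
        return out

    def __str__(self) -> str:
        ant = "∧".join(sorted(str(a) for a in self.antecedent))
        p = "?" if self.p is None else str(self.p)
        return f"P({self.consequent}|{ant})={p}"

    def __lt__(self, other) -> bool:
        return str(self) < str(other)


def pta(antecedent: Iterable[PTAClause], consequent: VariableAssertion, p,
        pta_id: str = "", source: Optional[str] = None) -> PTA:
    return PTA(frozenset(antecedent), consequent, as_probability(p), pta_id, source)


# ---------------------------------------------------------------------------
# Instantiation functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstantiationFunction:
    """One-to-one mapping of variable individuals to specific individuals."""

    pairs: FrozenSet[Tuple[VariableIndividual, Individual]]

    def __post_init__(self) -> None:
        variables = [v for v, _ in self.pairs]
        targets = [a for _, a in self.pairs]
        if len(set(variables)) != len(variables):
            raise CompatibilityError("mapping assigns a variable twice")
        if len(set(targets)) != len(targets):
            raise CompatibilityError("instantiation function must be one-to-one")

    @classmethod
    def from_mapping(cls, mapping: Dict[VariableIndividual, Individual]
                     ) -> "InstantiationFunction":
        return cls(frozenset(mapping.items()))

    @property
    def mapping(self) -> Dict[VariableIndividual, Individual]:
        return dict(self.pairs)

    def __str__(self) -> str:
        items = sorted(f"{v}→{a}" for v, a in self.pairs)
        return "{" + ", ".join(items) + "}"


def instantiate_pta(t: PTA, g: InstantiationFunction) -> PAA:
    """T|g: substitute every variable individual, keeping the weight.

    ``g`` must cover I(T) exactly and be injective (probabilistic universal
    instantiation); the result records (pta_id, g) provenance.
    """
    mapping = g.mapping
    missing = t.variables() - set(mapping)
    if missing:
        raise CompatibilityError(
            f"unmapped variables: {', '.join(sorted(map(str, missing)))}"
        )
    extra = set(mapping) - t.variables()
    if extra:
        raise CompatibilityError(
            f"mapping covers variables foreign to the rule: "
            f"{', '.join(sorted(map(str, extra)))}"
        )
    antecedent = frozenset(substitute(c, mapping) for c in t.antecedent)
    consequent = substitute(t.consequent, mapping)
    assert isinstance(consequent, Assertion)
    return PAA(antecedent, consequent, t.p, t.source, (t.pta_id, g))


# ---------------------------------------------------------------------------
# Classical axioms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassAssertion:
    assertion: Assertion


@dataclass(frozen=True)
class Subsumption:
    sub: ConceptExpr
    sup: ConceptExpr


@dataclass(frozen=True)
class Equivalence:
    left: ConceptExpr
    right: ConceptExpr


@dataclass(frozen=True)
class Disjointness:
    left: ConceptExpr
    right: ConceptExpr


ClassicalAxiom = Union[ClassAssertion, Subsumption, Equivalence, Disjointness]

_X = VariableIndividual("x")


def from_classical(axiom: ClassicalAxiom,
                   axioms: Optional[AxiomStore] = None) -> FrozenSet[Union[PAA, PTA]]:
    """Encode a crisp axiom as certainty-weighted probabilistic rules.

    Assertions become unconditional PAAs with weight 1; C ⊆ D becomes
    P(x̂∈D | x̂∈C)=1; equivalence gives both directions; disjointness gives
    the two zero-weight rules and, when a store is supplied, a declared
    disjoint pair so consistency checking can use it.
    """
    if isinstance(axiom, ClassAssertion):
        return frozenset({paa((), axiom.assertion, 1)})
    if isinstance(axiom, Subsumption):
        return frozenset({
            pta((VariableAssertion(_X, axiom.sub),),
                VariableAssertion(_X, axiom.sup), 1)
        })
    if isinstance(axiom, Equivalence):
        return frozenset({
            pta((VariableAssertion(_X, axiom.left),),
                VariableAssertion(_X, axiom.right), 1),
            pta((VariableAssertion(_X, axiom.right),),
                VariableAssertion(_X, axiom.left), 1),
        })
    if isinstance(axiom, Disjointness):
        if axioms is not None:
            axioms.declare_disjoint(axiom.left, axiom.right)
        return frozenset({
            pta((VariableAssertion(_X, axiom.left),),
                VariableAssertion(_X, axiom.right), 0),
            pta((VariableAssertion(_X, axiom.right),),
                VariableAssertion(_X, axiom.left), 0),
        })
    raise ConversionError(f"unsupported axiom form: {axiom!r}")


# ---------------------------------------------------------------------------
# Rule relations (mutual exclusivity, consequent boundedness, ...)
# ---------------------------------------------------------------------------

class RuleRelation(Enum):
    MUTEX = "mutually exclusive"
    CONSEQUENT_BOUND = "consequent bound"
    NEGATION_CONSISTENT = "negation consistent"
    IDENTICAL = "identical"
    OTHER = "other"


Rule = Union[PAA, PTA]


def _paa_mutex(r1: PAA, r2: PAA, axioms: AxiomStore) -> bool:
    """Antecedent disaggregations inconsistent with each other."""
    return not sets_consistent(r1.antecedent, r2.antecedent, axioms)


def _paa_bound(r1: PAA, r2: PAA, axioms: AxiomStore) -> bool:
    if _paa_mutex(r1, r2, axioms):
        return False
    return not assertions_consistent(r1.consequent, r2.consequent, axioms)


def _paa_neg_consistent(r1: PAA, r2: PAA, axioms: AxiomStore) -> bool:
    return (
        assertions_consistent(r1.consequent, negate(r2.consequent), axioms)
        and assertions_consistent(r2.consequent, negate(r1.consequent), axioms)
    )


def _instantiation_pool(rules: Iterable[Rule],
                        lexicon: Optional[DomainLexicon],
                        n_fresh: int) -> List[Individual]:
    """Individuals over which quantified PTA conditions are enumerated:
    everything mentioned or registered, plus fresh generics so that maps
    onto entirely new individuals are represented."""
    pool: set[Individual] = set()
    for rule in rules:
        clauses = (
            rule.assertions if isinstance(rule, PAA)
            else set(rule.antecedent) | {rule.consequent}
        )
        for clause in clauses:
            if isinstance(clause, Assertion):
                pool.add(clause.individual)
                pool |= concept_individuals(clause.concept)
            else:
                pool |= concept_individuals(clause.concept)
    if lexicon is not None:
        pool |= lexicon.individuals
    fresh = [Individual(f"_fresh{i}", namespace="_pool") for i in range(n_fresh)]
    return sorted(pool) + fresh


def candidate_substitutions(t: PTA, pool: List[Individual]
                            ) -> List[InstantiationFunction]:
    """Every injective mapping of I(T) into the pool (deterministic order)."""
    variables = sorted(t.variables())
    out = []
    for targets in itertools.permutations(pool, len(variables)):
        out.append(InstantiationFunction(frozenset(zip(variables, targets))))
    return out


def rule_relation(q1: Rule, q2: Rule,
                  axioms: AxiomStore = EMPTY_AXIOMS,
                  lexicon: Optional[DomainLexicon] = None) -> RuleRelation:
    """Classify a rule pair; quantified cases are decided exhaustively over
    the finite instantiation pool.

    MUTEX: every instantiation pair has conflicting antecedents.
    CONSEQUENT_BOUND: some non-exclusive instantiation pair has
    inconsistent consequents (it competes for probability mass).
    NEGATION_CONSISTENT: every non-exclusive pair's consequents tolerate
    each other's negation.  IDENTICAL: structurally the same rule, or a
    PTA against one of its own instantiations.
    """
    if q1 == q2:
        return RuleRelation.IDENTICAL
    pairs = _instantiated_pairs(q1, q2, axioms, lexicon)
    if isinstance(q1, PAA) and isinstance(q2, PAA):
        r1, r2 = q1, q2
        if _paa_mutex(r1, r2, axioms):
            return RuleRelation.MUTEX
        if _paa_bound(r1, r2, axioms):
            return RuleRelation.CONSEQUENT_BOUND
        if _paa_neg_consistent(r1, r2, axioms):
            return RuleRelation.NEGATION_CONSISTENT
        return RuleRelation.OTHER
    if any(r1 == r2 for r1, r2 in pairs):
        return RuleRelation.IDENTICAL
    if all(_paa_mutex(r1, r2, axioms) for r1, r2 in pairs):
        return RuleRelation.MUTEX
    if any(_paa_bound(r1, r2, axioms) for r1, r2 in pairs):
        return RuleRelation.CONSEQUENT_BOUND
    if all(
        _paa_mutex(r1, r2, axioms) or _paa_neg_consistent(r1, r2, axioms)
        for r1, r2 in pairs
    ):
        return RuleRelation.NEGATION_CONSISTENT
    return RuleRelation.OTHER


def _instantiated_pairs(q1: Rule, q2: Rule, axioms: AxiomStore,
                        lexicon: Optional[DomainLexicon]) -> List[Tuple[PAA, PAA]]:
    n1 = len(q1.variables()) if isinstance(q1, PTA) else 0
    n2 = len(q2.variables()) if isinstance(q2, PTA) else 0
    pool = _instantiation_pool((q1, q2), lexicon, n1 + n2)
    left = (
        [instantiate_pta(q1, g) for g in candidate_substitutions(q1, pool)]
        if isinstance(q1, PTA) else [q1]
    )
    right = (
        [instantiate_pta(q2, g) for g in candidate_substitutions(q2, pool)]
        if isinstance(q2, PTA) else [q2]
    )
    return [(r1, r2) for r1 in left for r2 in right]


# ---------------------------------------------------------------------------
# BKO container and validation
# ---------------------------------------------------------------------------

class BKO:
    """A finite set of PAAs and PTAs over a lexicon and axiom store."""

    def __init__(self, paas: Iterable[PAA] = (), ptas: Iterable[PTA] = (),
                 lexicon: Optional[DomainLexicon] = None,
                 axioms: Optional[AxiomStore] = None,
                 source_order: Tuple[str, ...] = ()) -> None:
        self.paas: Tuple[PAA, ...] = tuple(sorted(set(paas)))
        self.ptas: Tuple[PTA, ...] = tuple(sorted(set(ptas)))
        self.lexicon = lexicon if lexicon is not None else DomainLexicon()
        self.axioms = axioms if axioms is not None else AxiomStore()
        #: fusion input order; instantiation processes rules fragment-first
        self.source_order = source_order

    @property
    def rules(self) -> Tuple[Rule, ...]:
        return self.paas + self.ptas

    def abox(self) -> Tuple[PAA, ...]:
        return self.paas

    def tbox(self) -> Tuple[PTA, ...]:
        return self.ptas

    def validate(self) -> "BKOValidationReport":
        return validate_bko(self)

    def __len__(self) -> int:
        return len(self.paas) + len(self.ptas)


@dataclass(frozen=True)
class BKOValidationReport:
    """Violations of the four BKO validity conditions."""

    pair_violations: Tuple[Tuple[Rule, Rule], ...]
    sum_violations: Tuple[Tuple[Tuple[Rule, ...], Fraction], ...]
    inconsistent_rules: Tuple[Rule, ...]

    @property
    def valid(self) -> bool:
        return not (self.pair_violations or self.sum_violations
                    or self.inconsistent_rules)

    def __str__(self) -> str:
        if self.valid:
            return "valid"
        lines = [f"internally inconsistent rule: {r}" for r in self.inconsistent_rules]
        lines += [f"pair violation: {a}  //  {b}" for a, b in self.pair_violations]
        lines += [
            f"weight-sum violation (Σ={float(t):.6g}): " + "; ".join(map(str, c))
            for c, t in self.sum_violations
        ]
        return "\n".join(lines)


def _pair_acceptable(q1: Rule, q2: Rule, axioms: AxiomStore,
                     lexicon: Optional[DomainLexicon]) -> bool:
    """One pairwise validity condition, uniform across PAA/PTA pairs:
    every instantiation pair must be mutually exclusive, tolerate each
    other's negated consequent, conclude the identical assertion, or (PTA
    against PAA) reproduce the PAA itself."""
    pairs = _instantiated_pairs(q1, q2, axioms, lexicon)
    for r1, r2 in pairs:
        if r1 == r2:
            continue
        if _paa_mutex(r1, r2, axioms):
            continue
        if r1.consequent == r2.consequent:
            continue  # parallel derivation of one assertion
        if _paa_neg_consistent(r1, r2, axioms):
            continue
        return False
    return True


def validate_bko(b: BKO) -> BKOValidationReport:
    """Check the BKO validity conditions pairwise plus clique weight sums.

    Rules with unspecified weights (reasoning anchors) are scaffolding and
    excluded.  The consequent-bound weight-sum condition is checked on
    maximal cliques of the pairwise consequent-bound graph.
    """
    import networkx as nx

    rules: List[Rule] = [r for r in b.rules if r.p is not None]
    inconsistent = tuple(
        r for r in rules
        if isinstance(r, PAA) and not set_consistent(r.assertions, b.axioms)
    )
    pair_violations = []
    bound_graph = nx.Graph()
    bound_graph.add_nodes_from(range(len(rules)))
    for i, q1 in enumerate(rules):
        for j in range(i + 1, len(rules)):
            q2 = rules[j]
            if not _pair_acceptable(q1, q2, b.axioms, b.lexicon):
                pair_violations.append((q1, q2))
            if _ever_bound(q1, q2, b.axioms, b.lexicon):
                bound_graph.add_edge(i, j)

    from .bkb import SUM_TOLERANCE

    sum_violations = []
    for clique in nx.find_cliques(bound_graph):
        if len(clique) < 2:
            continue
        members = tuple(rules[i] for i in sorted(clique))
        total = sum((r.p for r in members if r.p is not None), Fraction(0))
        if float(total) > 1 + SUM_TOLERANCE:
            sum_violations.append((members, Fraction(total)))
    return BKOValidationReport(
        tuple(pair_violations),
        tuple(sorted(sum_violations, key=lambda v: str(v[0]))),
        inconsistent,
    )


def _ever_bound(q1: Rule, q2: Rule, axioms: AxiomStore,
                lexicon: Optional[DomainLexicon]) -> bool:
    """Is some instantiation pair consequent bound?  (The weight-sum
    condition must hold for the substitution that maximizes competition.)"""
    return any(
        _paa_bound(r1, r2, axioms)
        for r1, r2 in _instantiated_pairs(q1, q2, axioms, lexicon)
    )
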