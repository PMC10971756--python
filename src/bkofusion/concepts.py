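"""Concept-expression algebra, individuals, assertions, and consistency.

The vocabulary here is a deliberately small description logic: atomic
classes (optionally namespaced, optionally carrying a CURIE identifier),
complement, intersection, union, and role-filler membership.  Disjointness
between classes is decided from *declared* axioms only — syntactic
complements, declared disjoint pairs, and subsumption lifting — never by a
tableau reasoner.  Absence of a declaration means "not disjoint"
(open-world default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional, Tuple, Union


class RegistrationError(KeyError):
    """A concept or individual was used before being registered."""


class PartitionError(ValueError):
    """A class set offered as a partition is not pairwise disjoint."""


# ---------------------------------------------------------------------------
# Individuals (specific and variable)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Individual:
    """A named member of the domain; identity is (namespace, name)."""

    name: str
    namespace: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("individual name must be non-empty")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.name}" if self.namespace else self.name


@dataclass(frozen=True, order=True)
class VariableIndividual:
    """An unspecified individual (the x-hat of first-order rules)."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")

    def __str__(self) -> str:
        return f"?{self.name}"


IndividualTerm = Union[Individual, VariableIndividual]


# ---------------------------------------------------------------------------
# Concept expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptExpr:
    """Base class for concept expressions; subclasses are frozen values."""

    def __str__(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError

    # Lexicographic ordering on the canonical string keeps every iteration
    # order in the package deterministic.
    def __lt__(self, other: "ConceptExpr") -> bool:
        return str(self) < str(other)


@dataclass(frozen=True)
class Atomic(ConceptExpr):
    name: str
    namespace: Optional[str] = None
    identifier: Optional[str] = None  # CURIE, e.g. "MONDO:0006960"

    def __str__(self) -> str:
        return f"{self.name}({self.namespace})" if self.namespace else self.name

    def __eq__(self, other: object) -> bool:
        # identifier is display metadata, not identity
        return (
            isinstance(other, Atomic)
            and self.name == other.name
            and self.namespace == other.namespace
        )

    def __hash__(self) -> int:
        return hash(("Atomic", self.name, self.namespace))


TOP = Atomic("⊤")
BOTTOM = Atomic("⊥")


@dataclass(frozen=True)
class Complement(ConceptExpr):
    inner: ConceptExpr

    def __str__(self) -> str:
        return f"¬{self.inner}"


@dataclass(frozen=True)
class Intersection(ConceptExpr):
    parts: FrozenSet[ConceptExpr]

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("intersection needs at least one part")

    def __str__(self) -> str:
        return "(" + "∩".join(sorted(str(p) for p in self.parts)) + ")"


@dataclass(frozen=True)
class UnionExpr(ConceptExpr):
    parts: FrozenSet[ConceptExpr]

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("union needs at least one part")

    def __str__(self) -> str:
        return "(" + "∪".join(sorted(str(p) for p in self.parts)) + ")"


@dataclass(frozen=True)
class RoleFiller(ConceptExpr):
    """Membership in the class of owners related to ``filler`` by ``role``.

    Encodes role assertions bRc as concept membership: b ∈ R(b, c).  Either
    term may be a variable individual inside first-order rules.
    """

    role: str
    owner: IndividualTerm
    filler: IndividualTerm

    def __str__(self) -> str:
        return f"{self.role}({self.owner},{self.filler})"


def complement(c: ConceptExpr) -> ConceptExpr:
    """Complement with involution: ¬¬C normalizes back to C."""
    if isinstance(c, Complement):
        return c.inner
    if c == TOP:
        return BOTTOM
    if c == BOTTOM:
        return TOP
    return Complement(c)


def intersection(parts: Iterable[ConceptExpr]) -> ConceptExpr:
    parts = frozenset(parts)
    if len(parts) == 1:
        return next(iter(parts))
    return Intersection(parts)


def union(parts: Iterable[ConceptExpr]) -> ConceptExpr:
    parts = frozenset(parts)
    if len(parts) == 1:
        return next(iter(parts))
    return UnionExpr(parts)


def base_concept(c: ConceptExpr) -> ConceptExpr:
    """Strip an outer complement: the positive class underlying C or ¬C."""
    return c.inner if isinstance(c, Complement) else c


def concept_variables(c: ConceptExpr) -> FrozenSet[VariableIndividual]:
    """All variable individuals occurring inside a concept formula."""
    if isinstance(c, RoleFiller):
        return frozenset(
            t for t in (c.owner, c.filler) if isinstance(t, VariableIndividual)
        )
    if isinstance(c, Complement):
        return concept_variables(c.inner)
    if isinstance(c, (Intersection, UnionExpr)):
        out: FrozenSet[VariableIndividual] = frozenset()
        for p in c.parts:
            out |= concept_variables(p)
        return out
    return frozenset()


def concept_individuals(c: ConceptExpr) -> FrozenSet[Individual]:
    """All specific individuals occurring inside a concept formula."""
    if isinstance(c, RoleFiller):
        return frozenset(t for t in (c.owner, c.filler) if isinstance(t, Individual))
    if isinstance(c, Complement):
        return concept_individuals(c.inner)
    if isinstance(c, (Intersection, UnionExpr)):
        out: FrozenSet[Individual] = frozenset()
        for p in c.parts:
            out |= concept_individuals(p)
        return out
    return frozenset()


def substitute_concept(c: ConceptExpr, mapping) -> ConceptExpr:
    """Replace individual terms inside a concept per ``mapping``."""
    if isinstance(c, RoleFiller):
        return RoleFiller(
            c.role, mapping.get(c.owner, c.owner), mapping.get(c.filler, c.filler)
        )
    if isinstance(c, Complement):
        return complement(substitute_concept(c.inner, mapping))
    if isinstance(c, Intersection):
        return Intersection(frozenset(substitute_concept(p, mapping) for p in c.parts))
    if isinstance(c, UnionExpr):
        return UnionExpr(frozenset(substitute_concept(p, mapping) for p in c.parts))
    return c


# ---------------------------------------------------------------------------
# Assertions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Assertion:
    """Membership of one specific individual in one concept: a ∈ C."""

    individual: Individual
    concept: ConceptExpr

    def __str__(self) -> str:
        return f"{self.individual}∈{self.concept}"

    def __lt__(self, other: "Assertion") -> bool:
        return str(self) < str(other)


def negate(a: Assertion) -> Assertion:
    """The negation of a ∈ C is a ∈ ¬C; applying twice restores the original."""
    return Assertion(a.individual, complement(a.concept))


# ---------------------------------------------------------------------------
# Lexicon and axiom store
# ---------------------------------------------------------------------------

class DomainLexicon:
    """The finite universe of discourse: registered individuals and classes."""

    def __init__(self) -> None:
        self.individuals: set[Individual] = set()
        self.classes: set[ConceptExpr] = {TOP, BOTTOM}

    def register_individual(self, ind: Individual) -> Individual:
        self.individuals.add(ind)
        return ind

    def register_class(self, c: ConceptExpr) -> ConceptExpr:
        self.classes.add(base_concept(c))
        return c

    def require_class(self, c: ConceptExpr) -> None:
        if base_concept(c) not in self.classes:
            raise RegistrationError(f"unregistered concept: {c}")

    def require_individual(self, ind: Individual) -> None:
        if ind not in self.individuals:
            raise RegistrationError(f"unregistered individual: {ind}")


class AxiomStore:
    """Declared terminological facts: disjointness, subsumption, partitions.

    Only what is declared (plus syntactic complements and subsumption
    lifting) is ever used to derive disjointness.
    """

    def __init__(self) -> None:
        self.disjoint_pairs: set[FrozenSet[ConceptExpr]] = set()
        self.subsumptions: set[Tuple[ConceptExpr, ConceptExpr]] = set()
        self.partitions: list[FrozenSet[ConceptExpr]] = []

    def declare_disjoint(self, c1: ConceptExpr, c2: ConceptExpr) -> None:
        if c1 == c2 and c1 != BOTTOM:
            raise ValueError(f"a class cannot be disjoint with itself: {c1}")
        self.disjoint_pairs.add(frozenset((c1, c2)))

    def declare_subsumption(self, sub: ConceptExpr, sup: ConceptExpr) -> None:
        self.subsumptions.add((sub, sup))

    def declare_partition(self, classes: Iterable[ConceptExpr]) -> FrozenSet[ConceptExpr]:
        part = frozenset(classes)
        for c1 in part:
            for c2 in part:
                if c1 != c2:
                    self.declare_disjoint(c1, c2)
        self.partitions.append(part)
        return part

    def ancestors(self, c: ConceptExpr) -> FrozenSet[ConceptExpr]:
        """Reflexive-transitive closure of declared subsumption above ``c``."""
        seen = {c}
        frontier = [c]
        while frontier:
            cur = frontier.pop()
            for sub, sup in self.subsumptions:
                if sub == cur and sup not in seen:
                    seen.add(sup)
                    frontier.append(sup)
        return frozenset(seen)

    def merge(self, other: "AxiomStore") -> None:
        self.disjoint_pairs |= other.disjoint_pairs
        self.subsumptions |= other.subsumptions
        for part in other.partitions:
            if part not in self.partitions:
                self.partitions.append(part)

    def copy(self) -> "AxiomStore":
        out = AxiomStore()
        out.merge(self)
        return out


EMPTY_AXIOMS = AxiomStore()


def are_disjoint(
    c1: ConceptExpr,
    c2: ConceptExpr,
    axioms: AxiomStore = EMPTY_AXIOMS,
    lexicon: Optional[DomainLexicon] = None,
) -> bool:
    """Is C ∩ D = ⊥ derivable from declared axioms and syntactic complements?

    True iff some ancestor (under declared subsumption) of ``c1`` and some
    ancestor of ``c2`` are syntactic complements of each other, a declared
    disjoint pair, or Bottom.  Anything else is non-disjoint by default.
    """
    if lexicon is not None:
        lexicon.require_class(c1)
        lexicon.require_class(c2)
    anc1 = axioms.ancestors(c1)
    anc2 = axioms.ancestors(c2)
    for a1 in anc1:
        for a2 in anc2:
            if a1 == BOTTOM or a2 == BOTTOM:
                return True
            if complement(a1) == a2:
                return True
            if frozenset((a1, a2)) in axioms.disjoint_pairs:
                return True
    return False


def assertions_consistent(
    a1: Assertion, a2: Assertion, axioms: AxiomStore = EMPTY_AXIOMS
) -> bool:
    """Two assertions conflict only when they pin the same individual into
    provably disjoint classes."""
    if a1.individual != a2.individual:
        return True
    return not are_disjoint(a1.concept, a2.concept, axioms)


def set_consistent(
    assertions: Iterable[Assertion], axioms: AxiomStore = EMPTY_AXIOMS
) -> bool:
    """Pairwise consistency of a set of assertions; the empty set is consistent."""
    items = sorted(set(assertions))
    for i, x in enumerate(items):
        for y in items[i + 1 :]:
            if not assertions_consistent(x, y, axioms):
                return False
    return True


def sets_consistent(
    left: Iterable[Assertion],
    right: Iterable[Assertion],
    axioms: AxiomStore = EMPTY_AXIOMS,
) -> bool:
    """Two individually consistent assertion sets are consistent with each
    other iff their union is consistent."""
    return set_consistent(set(left) | set(right), axioms)


# ---------------------------------------------------------------------------
# Partition-induced random variables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomVariable:
    """A discrete rv whose states are assertions about one individual."""

    id: str
    states: Tuple[Assertion, ...]

    def __post_init__(self) -> None:
        inds = {s.individual for s in self.states}
        if len(inds) > 1:
            raise ValueError("all states of an assertion rv must share one individual")


def induce_rv(
    partition: Iterable[ConceptExpr],
    individual: Individual,
    axioms: AxiomStore = EMPTY_AXIOMS,
) -> RandomVariable:
    """The rv induced by a disjoint class family for one individual.

    Only pairwise disjointness is verified; whether the family actually
    covers its parent class is an open-world trust assumption.
    """
    classes = sorted(set(partition))
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1 :]:
            if not are_disjoint(c1, c2, axioms):
                raise PartitionError(f"classes not declared disjoint: {c1} / {c2}")
    states = tuple(Assertion(individual, c) for c in classes)
    rv_id = f"{individual}|{{{','.join(str(c) for c in classes)}}}"
    return RandomVariable(rv_id, states)


def assertion_rv_key(a: Assertion, axioms: AxiomStore = EMPTY_AXIOMS) -> str:
    """The rv an assertion belongs to, keyed by (individual, partition).

    A declared multi-class partition containing the assertion's base class
    wins; otherwise every class defaults to its own binary {C, ¬C}
    membership variable.
    """
    base = base_concept(a.concept)
    for part in axioms.partitions:
        if base in part:
            classes = sorted(part)
            return f"{a.individual}|{{{','.join(str(c) for c in classes)}}}"
    return f"{a.individual}|{{{base}}}"
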