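"""Belief updating, belief revision, and probabilistic membership queries.

Posterior probabilities are mass ratios.  The joint mass of a conjunction
of rv states is the summed probability of its *minimal-support*
inferences — every way of choosing exactly one supporting rule per needed
variable and closing the choice under antecedents (the empty conjunction
is supported by the empty inference, mass 1).  Distinct support closures
differ in the rule chosen for some variable and are treated as exclusive
alternatives, so their masses add.  On complete conditional tables this
reproduces the full-joint posterior exactly; on incomplete rule sets it
leaves unassigned mass unassigned instead of renormalizing it away.

Belief revision ranks maximal inferences (most-probable-explanation
style); partial belief revision ranks the supports of a chosen target set
given evidence, which is the right lens for comparing contradictory
conclusions in a fused model.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import FrozenSet, Iterable, List, Optional, Tuple, Union

from .bkb import (
    BKB,
    CPR,
    Inference,
    RVAssignment,
    enumerate_inferences,
    is_maximal,
    joint_mass,
    support_inferences,
)
from .bko import BKO
from .concepts import Assertion, assertion_rv_key
from .instantiation import ReasoningAnchor, extract_abox, full_instantiate


class UndefinedPosteriorError(ZeroDivisionError):
    """The evidence itself has zero probability mass."""


class QueryError(ValueError):
    """A query references states the knowledge base cannot ground."""


class _Incalculable:
    """Singleton marker: the posterior exists but the pmf is too
    incomplete to compute it (e.g. an ungrounded target)."""

    def __repr__(self) -> str:
        return "INCALCULABLE"

    def __bool__(self) -> bool:
        return False


INCALCULABLE = _Incalculable()


@dataclass(frozen=True)
class Query:
    """Evidence (the query antecedent) and targets (the reasoning target)."""

    evidence: FrozenSet[RVAssignment]
    targets: FrozenSet[RVAssignment]


def query(evidence: Iterable[RVAssignment], targets: Iterable[RVAssignment]) -> Query:
    return Query(frozenset(evidence), frozenset(targets))


@dataclass(frozen=True)
class PosteriorResult:
    probability: Union[Fraction, _Incalculable]
    supporting_inferences: Tuple[Inference, ...]
    evidence_mass: Fraction

    @property
    def calculable(self) -> bool:
        return not isinstance(self.probability, _Incalculable)


_QUERY_RV = "VQ"
_QUERY_TRUE = "True"


def belief_update(b: Union[BKB, Iterable[CPR]], q: Query) -> PosteriorResult:
    """P(targets | evidence) as a ratio of joint masses.

    Mechanically a query variable VQ with states {True, False} and a query
    rule P(VQ=True | targets) = 1 are added, and the mass of
    {VQ=True} ∪ evidence is divided by the mass of the evidence.  Targets
    that are nowhere concluded make the posterior INCALCULABLE (a result,
    not an exception); evidence with zero mass raises, since conditioning
    on it is undefined.
    """
    rules = tuple(b)
    concluded = {r.consequent for r in rules}
    if not q.targets <= concluded:
        return PosteriorResult(INCALCULABLE, (), Fraction(0))

    query_rule = CPR(frozenset(q.targets),
                     RVAssignment(_QUERY_RV, _QUERY_TRUE), Fraction(1))
    numerator_supports = support_inferences(
        rules + (query_rule,),
        set(q.evidence) | {RVAssignment(_QUERY_RV, _QUERY_TRUE)},
    )
    denominator = joint_mass(rules, q.evidence)
    if denominator is None:
        return PosteriorResult(INCALCULABLE, (), Fraction(0))
    if denominator == 0:
        raise UndefinedPosteriorError("evidence has zero probability mass")
    if not numerator_supports:
        # provably impossible only when the conjunction conflicts on a
        # variable; otherwise the mass is unknown, not zero
        by_rv: dict = {}
        for assignment in set(q.evidence) | set(q.targets):
            if by_rv.setdefault(assignment.rv, assignment.state) \
                    != assignment.state:
                return PosteriorResult(Fraction(0), (), denominator)
        return PosteriorResult(INCALCULABLE, (), denominator)
    numerator = sum((i.probability for i in numerator_supports), Fraction(0))
    ranked = tuple(sorted(numerator_supports,
                          key=lambda i: (-i.probability, str(i))))
    return PosteriorResult(numerator / denominator, ranked, denominator)


def belief_revision(b: Union[BKB, Iterable[CPR]],
                    evidence: Iterable[RVAssignment] = (),
                    max_rules: Optional[int] = None) -> List[Inference]:
    """All maximal inferences containing the evidence, most probable
    first; ties broken on the canonical string of the induced set."""
    rules = tuple(b)
    enumerated = enumerate_inferences(rules, anchor=evidence, max_rules=max_rules)
    maximal = [i for i in enumerated if is_maximal(i, rules)]
    return sorted(maximal, key=lambda i: (-i.probability, str(i)))


def partial_belief_revision(b: Union[BKB, Iterable[CPR]],
                            evidence: Iterable[RVAssignment],
                            targets: Iterable[RVAssignment]) -> List[Inference]:
    """Supports of targets ∪ evidence ranked by probability — the
    explanations of a specific conclusion under the given evidence."""
    supports = support_inferences(tuple(b), set(targets) | set(evidence))
    return sorted(supports, key=lambda i: (-i.probability, str(i)))


# ---------------------------------------------------------------------------
# Probabilistic membership queries over BKOs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipQuery:
    """A PMQ phrased directly in assertions; conversion to rv assignments
    follows the knowledge base's partition keying."""

    evidence: Tuple[Assertion, ...]
    targets: Tuple[Assertion, ...]


def membership_query(evidence: Iterable[Assertion],
                     targets: Iterable[Assertion]) -> MembershipQuery:
    return MembershipQuery(tuple(sorted(set(evidence))), tuple(sorted(set(targets))))


def answer_pmq(b: BKO, q: MembershipQuery, anchored: bool = False) -> PosteriorResult:
    """Posterior probability of the target memberships given the evidence.

    Grounded variant: fully instantiate, then run belief updating on the
    extracted BKB (every evidence and target clause must be concluded by
    some PAA).  Anchored variant: the evidence clauses are first installed
    as anchor rules with unspecified weights, instantiation proceeds from
    that anchor, and the anchors are treated as the sole support of the
    evidence — their unspecified weights contribute no factor, so the
    result is invariant to any number one might imagine for them.
    """
    if anchored:
        anchor = ReasoningAnchor.from_assertions(q.evidence)
        full, _ = full_instantiate(b, anchor)
        anchor_rules = {r.to_cpr(full.axioms) for r in anchor.paas}
        bkb = extract_abox(full)
        evidence_assignments = {
            RVAssignment(assertion_rv_key(a, full.axioms), a) for a in q.evidence
        }
        # evidence variables are clamped to their anchors: alternative
        # derivations of an observed assertion must not inflate its mass
        rules = tuple(
            r for r in bkb
            if r in anchor_rules or r.consequent not in evidence_assignments
        )
    else:
        full, _ = full_instantiate(b)
        rules = tuple(extract_abox(full))
        evidence_assignments = {
            RVAssignment(assertion_rv_key(a, full.axioms), a) for a in q.evidence
        }
    target_assignments = {
        RVAssignment(assertion_rv_key(a, full.axioms), a) for a in q.targets
    }
    concluded = {r.consequent for r in rules}
    if not target_assignments <= concluded:
        return PosteriorResult(INCALCULABLE, (), Fraction(0))
    return belief_update(rules, Query(frozenset(evidence_assignments),
                                      frozenset(target_assignments)))
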