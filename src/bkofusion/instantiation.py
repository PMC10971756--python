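"""Generalization, groundedness, and the full-instantiation fixed point.

A BKO's terminological rules (PTAs) describe the probability mass function
only implicitly; reasoning needs the assertional rules (PAAs) they imply.
Full instantiation repeatedly applies probabilistic universal
instantiation: starting from an initial reasoning anchor it absorbs every
already-supported assertional rule, then instantiates every PTA whose
antecedent clauses can each be matched against a currently concluded
assertion by a compatible (injective, conflict-free) substitution.  The
loop runs to a fixed point, so instantiation is idempotent and the result
maximizes the set of grounded PAAs.

Pattern matching binds a clause's variables to the individuals of a ground
assertion by one-way unification; specific individuals embedded in a
clause must match exactly.  Matching through generalization equality and
matching through unification coincide on all-variable clauses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .bkb import BKB
from .bko import (
    BKO,
    InstantiationFunction,
    PAA,
    PTA,
    VariableAssertion,
    instantiate_pta,
    paa,
    substitute,
)
from .concepts import (
    Assertion,
    Atomic,
    Complement,
    ConceptExpr,
    Individual,
    Intersection,
    RoleFiller,
    UnionExpr,
    VariableIndividual,
    concept_individuals,
    substitute_concept,
)

Binding = Dict[VariableIndividual, Individual]


# ---------------------------------------------------------------------------
# Generalization and equivalence of variable assertions
# ---------------------------------------------------------------------------

def generalize(a: Assertion) -> VariableAssertion:
    """gen(a ∈ C): replace the subject and every distinct specific
    individual in the concept formula by fresh, canonically named
    variables (x1 for the subject, then x2, x3, ... in sorted order)."""
    order: List[Individual] = [a.individual]
    for ind in sorted(concept_individuals(a.concept)):
        if ind not in order:
            order.append(ind)
    mapping = {ind: VariableIndividual(f"x{i + 1}") for i, ind in enumerate(order)}
    concept = substitute_concept(a.concept, mapping)
    return VariableAssertion(mapping[a.individual], concept)


def var_assertions_equivalent(v1: VariableAssertion, v2: VariableAssertion) -> bool:
    """Equivalent variable assertions instantiate identically for every
    choice of individuals — i.e. they are equal up to a bijective renaming
    of their variables."""
    vs1, vs2 = sorted(v1.variables()), sorted(v2.variables())
    if len(vs1) != len(vs2):
        return False
    probes = [Individual(f"_probe{i}", namespace="_eq") for i in range(len(vs1))]
    grounded1 = substitute(v1, dict(zip(vs1, probes)))
    for perm in itertools.permutations(probes):
        if substitute(v2, dict(zip(vs2, perm))) == grounded1:
            return True
    return False


# ---------------------------------------------------------------------------
# One-way unification of a clause against a ground assertion
# ---------------------------------------------------------------------------

def _extend(binding: Binding, var_or_ind, target: Individual) -> Optional[Binding]:
    if isinstance(var_or_ind, VariableIndividual):
        bound = binding.get(var_or_ind)
        if bound is None:
            out = dict(binding)
            out[var_or_ind] = target
            return out
        return binding if bound == target else None
    return binding if var_or_ind == target else None


def _match_concept(pattern: ConceptExpr, ground: ConceptExpr,
                   binding: Binding) -> List[Binding]:
    if isinstance(pattern, RoleFiller) and isinstance(ground, RoleFiller):
        if pattern.role != ground.role:
            return []
        if not (isinstance(ground.owner, Individual)
                and isinstance(ground.filler, Individual)):
            return []
        b = _extend(binding, pattern.owner, ground.owner)
        if b is None:
            return []
        b = _extend(b, pattern.filler, ground.filler)
        return [] if b is None else [b]
    if isinstance(pattern, Complement) and isinstance(ground, Complement):
        return _match_concept(pattern.inner, ground.inner, binding)
    if isinstance(pattern, (Intersection, UnionExpr)) and type(pattern) is type(ground):
        if len(pattern.parts) != len(ground.parts):
            return []
        return _match_parts(sorted(pattern.parts), list(ground.parts), binding)
    if isinstance(pattern, Atomic):
        return [binding] if pattern == ground else []
    return []


def _match_parts(patterns: List[ConceptExpr], grounds: List[ConceptExpr],
                 binding: Binding) -> List[Binding]:
    """Backtracking set matching for intersection/union parts."""
    if not patterns:
        return [binding]
    head, rest = patterns[0], patterns[1:]
    out: List[Binding] = []
    for i, g in enumerate(grounds):
        for b in _match_concept(head, g, binding):
            out.extend(_match_parts(rest, grounds[:i] + grounds[i + 1:], b))
    return out


def match_clause(pattern: VariableAssertion, ground: Assertion) -> List[Binding]:
    """Bindings σ with pattern|σ = ground, if any."""
    base = _extend({}, pattern.subject, ground.individual)
    if base is None:
        return []
    seen, out = set(), []
    for b in _match_concept(pattern.concept, ground.concept, base):
        key = frozenset(b.items())
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# Support and groundedness
# ---------------------------------------------------------------------------

def is_grounded(r: PAA, b: Union[BKO, Iterable[PAA]]) -> bool:
    """A PAA is grounded when it is a prior or every antecedent assertion
    is concluded by some PAA of the knowledge base."""
    paas = b.paas if isinstance(b, BKO) else tuple(b)
    if not r.antecedent:
        return True
    concluded = {s.consequent for s in paas}
    return all(a in concluded for a in r.antecedent)


def prune_ungrounded(b: BKO) -> BKO:
    """Drop PAAs that stay ungrounded at the fixed point; posteriors that
    were computable are unchanged because no complete support chain ever
    passes through an ungrounded rule."""
    grounded: set[PAA] = set()
    changed = True
    while changed:
        changed = False
        concluded = {r.consequent for r in grounded}
        for r in b.paas:
            if r in grounded:
                continue
            if not r.antecedent or all(a in concluded for a in r.antecedent):
                grounded.add(r)
                changed = True
    return BKO(sorted(grounded), b.ptas, b.lexicon, b.axioms)


# ---------------------------------------------------------------------------
# The full-instantiation fixed point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReasoningAnchor:
    """Seed PAAs for instantiation; weights may be UNSPECIFIED (None)."""

    paas: Tuple[PAA, ...] = ()

    @classmethod
    def from_assertions(cls, assertions: Iterable[Assertion]) -> "ReasoningAnchor":
        return cls(tuple(paa((), a, None) for a in sorted(set(assertions))))

    def __len__(self) -> int:
        return len(self.paas)


EMPTY_ANCHOR = ReasoningAnchor()


@dataclass(frozen=True)
class PassRecord:
    index: int
    absorbed: Tuple[PAA, ...]      # pre-existing assertional rules now supported
    instantiated: Tuple[PAA, ...]  # fresh PAAs produced from PTAs this pass


@dataclass(frozen=True)
class InstantiationTrace:
    """Pass-by-pass account of what full instantiation added.

    ``seed`` is the initial reasoning anchor; each pass records absorbed
    assertional rules separately from fresh PTA instantiations, so the
    narrative "pass 1 instantiated two PAAs" is machine-checkable.
    """

    seed: Tuple[PAA, ...]
    passes: Tuple[PassRecord, ...]
    truncated: bool = False

    @property
    def instantiated_counts(self) -> Tuple[int, ...]:
        counts = [len(p.instantiated) for p in self.passes]
        while counts and counts[-1] == 0:
            counts.pop()
        return tuple(counts)

    @property
    def all_added(self) -> Tuple[PAA, ...]:
        out: List[PAA] = []
        for p in self.passes:
            out.extend(p.absorbed)
            out.extend(p.instantiated)
        return tuple(out)


def _candidate_substitutions(t: PTA, concluded: Sequence[Assertion]
                             ) -> List[InstantiationFunction]:
    """Algorithm core: match each antecedent clause of ``t`` against the
    currently concluded assertions, then join the partial bindings,
    keeping only conflict-free, injective unions covering I(T)."""
    per_clause: List[List[Binding]] = []
    for clause in sorted(t.antecedent, key=str):
        if isinstance(clause, Assertion):
            if clause not in concluded:
                return []
            continue
        options: List[Binding] = []
        for d in concluded:
            options.extend(match_clause(clause, d))
        if not options:
            return []
        per_clause.append(options)

    results: List[InstantiationFunction] = []
    seen: set = set()
    needed = t.variables()
    for combo in itertools.product(*per_clause) if per_clause else [()]:
        merged: Binding = {}
        ok = True
        for b in combo:
            for var, ind in b.items():
                if merged.get(var, ind) != ind:
                    ok = False
                    break
                merged[var] = ind
            if not ok:
                break
        if not ok or set(merged) != set(needed):
            continue
        if len(set(merged.values())) != len(merged):
            continue  # instantiation functions are one-to-one
        key = frozenset(merged.items())
        if key not in seen:
            seen.add(key)
            results.append(InstantiationFunction(key))
    return sorted(results, key=str)


def full_instantiate(b: BKO, anchor: ReasoningAnchor = EMPTY_ANCHOR,
                     max_passes: int = 1000, max_paas: int = 100_000
                     ) -> Tuple[BKO, InstantiationTrace]:
    """Run the instantiation loop to its fixed point.

    Each pass first absorbs assertional rules of ``b`` supported by the
    accumulated set, then instantiates PTAs against the consequents as
    they stood at that point — matching is snapshotted per pass, which is
    what makes the pass counts well defined.  Within a pass each
    assertion gains at most one *new* supporting rule: a candidate whose
    conclusion was already reached earlier in the same pass waits for the
    next pass (breadth-first growth of the support graph; parallel
    derivations attach on later passes, and the fixed point is
    unchanged).  PTAs are processed fragment-first when the BKO records a
    fusion order.  The output BKO contains all of ``b`` plus everything
    added; running it again adds nothing.
    """
    h: set[PAA] = set(anchor.paas)
    existing = set(b.paas)  # re-derivations of these are absorbed, not added
    records: List[PassRecord] = []
    truncated = False

    order = {label: i for i, label in enumerate(b.source_order)}

    def pta_key(t: PTA):
        return (order.get(t.source, len(order)), t.pta_id, str(t))

    for index in range(1, max_passes + 1):
        size_before = len(h)
        concluded_set = {r.consequent for r in h}

        absorbed = []
        for r in b.paas:
            if r in h:
                continue
            if not r.antecedent or all(a in concluded_set for a in r.antecedent):
                absorbed.append(r)
        h.update(absorbed)
        # PTAs match against consequents including this pass's absorptions
        concluded = sorted({r.consequent for r in h})

        instantiated = []
        claimed: set = set()
        for t in sorted(b.ptas, key=pta_key):
            for g in _candidate_substitutions(t, concluded):
                candidate = instantiate_pta(t, g)
                if candidate in h or candidate in existing:
                    continue
                if candidate.consequent in claimed:
                    continue  # second support this pass; retried next pass
                h.add(candidate)
                claimed.add(candidate.consequent)
                instantiated.append(candidate)
                if len(h) > max_paas:
                    truncated = True
                    break
            if truncated:
                break
        records.append(PassRecord(index, tuple(sorted(absorbed)),
                                  tuple(sorted(instantiated))))
        if truncated or len(h) == size_before:
            break
    else:
        truncated = True

    out = BKO(sorted(set(b.paas) | h), b.ptas, b.lexicon, b.axioms)
    trace = InstantiationTrace(anchor.paas, tuple(records), truncated)
    return out, trace


def extract_abox(b: BKO) -> BKB:
    """Re-type the assertional rules as CPRs over partition-induced
    random variables; for a fully instantiated BKO the result carries the
    same probability mass function."""
    return BKB((r.to_cpr(b.axioms) for r in b.paas), b.axioms)
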