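"""Fusion of BKO fragments with per-fragment source classes.

Each fragment (B, s, w) contributes a fresh *source class* C_s, a shared
source individual a_s, and a source prior P(a_s ∈ C_s) = w / Σw.  The
source assertion is conjoined to every rule of the fragment: as a random
variable assignment on each PAA antecedent and as a ground clause on each
PTA antecedent (so it survives every instantiation).  Source classes are
declared pairwise disjoint among themselves — an assertion can only have
come from the source that asserted it — but never disjoint with any
domain class, implementing the default that classes from different
ontologies are assumed non-conflicting unless an alignment fragment says
otherwise.

Validity checks consequently treat rules from different fragments as
mutually exclusive, while inference enumeration (which works per source
*variable*) still allows reasoning chains that borrow from several
sources at once; see docs/methods.md for the semantics of that split.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

from .bkb import Inference
from .bkb_fusion import FusionError
from .bko import BKO, PAA, PTA, paa, validate_bko
from .concepts import (
    Assertion,
    Atomic,
    AxiomStore,
    ConceptExpr,
    DomainLexicon,
    Individual,
    RandomVariable,
)

#: the one individual all source assertions are about
SOURCE_INDIVIDUAL = Individual("as", namespace="source")
SOURCE_NAMESPACE = "source"


class AttributionError(KeyError):
    """A rule without source metadata was asked for its source."""


@dataclass(frozen=True)
class SourceTag:
    """The source machinery of one fragment: its class, the shared source
    individual, and the induced single-state source variable."""

    source_class: ConceptExpr
    source_individual: Individual
    source_rv: RandomVariable

    @classmethod
    def for_label(cls, label: str) -> "SourceTag":
        c = Atomic(label, namespace=SOURCE_NAMESPACE)
        assertion = Assertion(SOURCE_INDIVIDUAL, c)
        rv = RandomVariable(f"{SOURCE_INDIVIDUAL}|{{{c}}}", (assertion,))
        return cls(c, SOURCE_INDIVIDUAL, rv)

    @property
    def assertion(self) -> Assertion:
        return self.source_rv.states[0]


@dataclass(frozen=True)
class BKOFragment:
    """(B, s, w): a BKO, its source label, and a positive reliability."""

    bko: BKO
    source: str
    weight: Fraction

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise FusionError(f"fragment weight must be positive: {self.weight}")


def bko_fragment(bko: BKO, source: str, weight) -> BKOFragment:
    w = Fraction(str(weight)) if isinstance(weight, float) else Fraction(weight)
    return BKOFragment(bko, source, w)


def fuse_bkos(fragments: Sequence[BKOFragment],
              require_valid: bool = True) -> BKO:
    """The BKO fusion algorithm.

    Adds one normalized source prior per fragment and conjoins the
    fragment's source assertion to every one of its rules; the union of
    the augmented fragments is returned over the merged lexicon and axiom
    store.  Weights only matter relative to each other.
    """
    if not fragments:
        raise FusionError("at least one fragment is required")
    labels = [f.source for f in fragments]
    if len(set(labels)) != len(labels):
        raise FusionError(f"duplicate source labels: {sorted(labels)}")
    if require_valid:
        for f in fragments:
            report = validate_bko(f.bko)
            if not report.valid:
                raise FusionError(
                    f"fragment {f.source!r} is not a valid BKO:\n{report}"
                )

    total = sum((f.weight for f in fragments), Fraction(0))
    lexicon = DomainLexicon()
    axioms = AxiomStore()
    tags = [SourceTag.for_label(f.source) for f in fragments]
    for t1 in tags:
        for t2 in tags:
            if t1.source_class != t2.source_class:
                axioms.declare_disjoint(t1.source_class, t2.source_class)
    lexicon.register_individual(SOURCE_INDIVIDUAL)

    paas: List[PAA] = []
    ptas: List[PTA] = []
    for f, tag in zip(fragments, tags):
        lexicon.individuals |= f.bko.lexicon.individuals
        lexicon.classes |= f.bko.lexicon.classes
        lexicon.register_class(tag.source_class)
        axioms.merge(f.bko.axioms)
        paas.append(paa((), tag.assertion, f.weight / total, source=f.source))
        for r in f.bko.paas:
            paas.append(PAA(r.antecedent | {tag.assertion}, r.consequent,
                            r.p, f.source, r.provenance))
        for t in f.bko.ptas:
            ptas.append(PTA(t.antecedent | {tag.assertion}, t.consequent,
                            t.p, t.pta_id, f.source))
    return BKO(paas, ptas, lexicon, axioms,
               source_order=tuple(f.source for f in fragments))


def attribute_sources(b: BKO, inference: Inference) -> Dict[str, Tuple[str, ...]]:
    """Map each rule of an inference to the fragment it came from.

    Sourced rules carry their fragment's assertion in the antecedent (and
    label metadata); source priors are attributed to themselves.  Returns
    {source label: canonical rule strings}, raising when a rule has no
    source trace at all.
    """
    out: Dict[str, List[str]] = {}
    for rule in sorted(inference.rules):
        label = rule.source
        if label is None:
            state = rule.consequent.state
            if isinstance(state, Assertion) \
                    and state.individual == SOURCE_INDIVIDUAL \
                    and isinstance(state.concept, Atomic):
                label = state.concept.name
        if label is None:
            for a in rule.antecedent:
                s = a.state
                if isinstance(s, Assertion) and s.individual == SOURCE_INDIVIDUAL \
                        and isinstance(s.concept, Atomic):
                    label = s.concept.name
                    break
        if label is None and rule.p is None and not rule.antecedent:
            label = "anchor"  # query scaffolding, not fused knowledge
        if label is None:
            raise AttributionError(f"rule carries no source metadata: {rule}")
        out.setdefault(label, []).append(str(rule))
    return {k: tuple(v) for k, v in sorted(out.items())}
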