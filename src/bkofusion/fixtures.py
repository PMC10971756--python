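"""Packaged fixtures, seeded random generators, and the brute-force oracle.

Three groups of things live here:

* the worked sciatic-nerve example — MONDO and Human Disease Ontology
  (DO) is-a subsets around the sciatic nerve plus the OxO cross-reference
  bridge between them, with the standard two-assertion reasoning anchor;
* seeded generators of random valid BKBs and BKOs for property testing
  (valid by construction and re-validated, reproducible per seed);
* a brute-force joint-distribution oracle that enumerates every world of
  a small complete conditional-table model, the independent reference for
  the belief-updating machinery.

The MONDO subset carries a known quirk of its source listing: the rule
concluding Inflammatory Disease is labelled "TM4" like its sibling and
names its antecedent inconsistently; it is shipped under the internal id
TM4b with the Mononeuritis Simplex term (MONDO:0002121) as antecedent,
which preserves the is-a chain from sciatic neuropathy through the bridge
up to Inflammatory Disease.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field as dataclasses_field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Tuple

from .bkb import BKB, CPR, RVAssignment, SUM_TOLERANCE, cpr
from .bkb_fusion import BKBFragment, bkb_fragment
from .bko import BKO, PAA, PTA, VariableAssertion, paa as make_paa, pta as make_pta
from .bko_fusion import BKOFragment, bko_fragment
from .concepts import (
    Assertion,
    Atomic,
    AxiomStore,
    DomainLexicon,
    Individual,
    VariableIndividual,
    complement,
    set_consistent,
)
from .instantiation import ReasoningAnchor
from .ontology_io import TermRecord
from .reasoning import Query, UndefinedPosteriorError


class OracleError(ValueError):
    """The oracle's preconditions (small, complete, acyclic) do not hold."""


class GenerationError(RuntimeError):
    """The generator could not satisfy validity within its retry budget."""


# ---------------------------------------------------------------------------
# The sciatic-nerve worked example
# ---------------------------------------------------------------------------

SCIATIC_TERMS: Tuple[TermRecord, ...] = (
    TermRecord("MONDO:0006960", "Sciatic Neuropathy", "MONDO"),
    TermRecord("MONDO:0001543", "Lesion of Sciatic Nerve", "MONDO"),
    TermRecord("MONDO:0001397", "Mononeuropathy", "MONDO"),
    TermRecord("MONDO:0002121", "Mononeuritis Simplex", "MONDO"),
    TermRecord("MONDO:0002122", "Neuritis", "MONDO"),
    TermRecord("MONDO:0021166", "Inflammatory Disease", "MONDO"),
    TermRecord("DOID:114466", "Sciatic Neuropathy", "DO"),
    TermRecord("DOID:12528", "Lesion of Sciatic Nerve", "DO"),
    TermRecord("DOID:9473", "Mononeuritis of Lower Limb", "DO"),
    TermRecord("DOID:1188", "Mononeuropathy", "DO"),
    TermRecord("DOID:1802", "Mononeuritis", "DO"),
)

_ATOMS: Dict[Tuple[str, str], Atomic] = {
    (t.namespace, t.atomic.name): t.atomic for t in SCIATIC_TERMS
}


def _atom(namespace: str, name: str) -> Atomic:
    return _ATOMS[(namespace, name)]


_X = VariableIndividual("x")


def _edge(pta_id: str, source: str, child: Atomic, parent: Atomic) -> PTA:
    return make_pta((VariableAssertion(_X, child),),
                    VariableAssertion(_X, parent), 1, pta_id=pta_id, source=source)


def sciatic_fixture() -> Tuple[Tuple[BKOFragment, BKOFragment, BKOFragment],
                               ReasoningAnchor, Tuple[TermRecord, ...]]:
    """The three fragments (MONDO, DO, OxO bridge, weight 1 each), the
    two-assertion anchor on individual ``a``, and the 11-row term table."""
    mondo = [
        _edge("TM1", "MONDO", _atom("MONDO", "LesionofSciaticNerve"),
              _atom("MONDO", "SciaticNeuropathy")),
        _edge("TM2", "MONDO", _atom("MONDO", "SciaticNeuropathy"),
              _atom("MONDO", "Mononeuropathy")),
        _edge("TM3", "MONDO", _atom("MONDO", "MononeuritisSimplex"),
              _atom("MONDO", "Mononeuropathy")),
        _edge("TM4a", "MONDO", _atom("MONDO", "MononeuritisSimplex"),
              _atom("MONDO", "Neuritis")),
        # duplicate "TM4" label in the source listing; see module docstring
        _edge("TM4b", "MONDO", _atom("MONDO", "MononeuritisSimplex"),
              _atom("MONDO", "InflammatoryDisease")),
    ]
    do = [
        _edge("TD1", "DO", _atom("DO", "SciaticNeuropathy"),
              _atom("DO", "LesionofSciaticNerve")),
        _edge("TD2", "DO", _atom("DO", "LesionofSciaticNerve"),
              _atom("DO", "MononeuritisofLowerLimb")),
        _edge("TD3", "DO", _atom("DO", "MononeuritisofLowerLimb"),
              _atom("DO", "Mononeuritis")),
        _edge("TD4", "DO", _atom("DO", "Mononeuritis"),
              _atom("DO", "Mononeuropathy")),
    ]
    bridge = [
        _edge("TB1", "BRIDGE", _atom("DO", "LesionofSciaticNerve"),
              _atom("MONDO", "LesionofSciaticNerve")),
        _edge("TB2", "BRIDGE", _atom("MONDO", "LesionofSciaticNerve"),
              _atom("DO", "LesionofSciaticNerve")),
        _edge("TB3", "BRIDGE", _atom("DO", "SciaticNeuropathy"),
              _atom("MONDO", "SciaticNeuropathy")),
        _edge("TB4", "BRIDGE", _atom("MONDO", "SciaticNeuropathy"),
              _atom("DO", "SciaticNeuropathy")),
        _edge("TB5", "BRIDGE", _atom("DO", "Mononeuropathy"),
              _atom("MONDO", "Mononeuropathy")),
        _edge("TB6", "BRIDGE", _atom("MONDO", "Mononeuropathy"),
              _atom("DO", "Mononeuropathy")),
        _edge("TB7", "BRIDGE", _atom("DO", "Mononeuritis"),
              _atom("MONDO", "MononeuritisSimplex")),
        _edge("TB8", "BRIDGE", _atom("MONDO", "MononeuritisSimplex"),
              _atom("DO", "Mononeuritis")),
    ]

    a = Individual("a")

    def fragment(ptas: List[PTA], label: str) -> BKOFragment:
        lexicon = DomainLexicon()
        lexicon.register_individual(a)
        for t in ptas:
            for clause in tuple(t.antecedent) + (t.consequent,):
                lexicon.register_class(clause.concept)
        return bko_fragment(BKO((), ptas, lexicon, AxiomStore()), label, 1)

    fragments = (fragment(mondo, "MONDO"), fragment(do, "DO"),
                 fragment(bridge, "BRIDGE"))
    anchor = ReasoningAnchor.from_assertions([
        Assertion(a, _atom("MONDO", "LesionofSciaticNerve")),
        Assertion(a, _atom("DO", "SciaticNeuropathy")),
    ])
    return fragments, anchor, SCIATIC_TERMS


def naive_fusion_fixture() -> Tuple[BKBFragment, BKBFragment]:
    """The two toy CPR fragments whose naive union breaks mutual
    exclusivity: F1 = {P(B=b)=0.2, P(A=a|B=b)=0.8} and
    F2 = {P(C=c)=0.4, P(A=a|C=c)=0.35}."""
    A, B, C = (RVAssignment("A", "a"), RVAssignment("B", "b"),
               RVAssignment("C", "c"))
    f1 = bkb_fragment([cpr((), B, "0.2"), cpr((B,), A, "0.8")], "F1", "0.5")
    f2 = bkb_fragment([cpr((), C, "0.4"), cpr((C,), A, "0.35")], "F2", "0.5")
    return f1, f2


# ---------------------------------------------------------------------------
# Random valid BKBs
# ---------------------------------------------------------------------------

def _random_weights(rng: random.Random, n: int,
                    full: bool = False) -> List[Fraction]:
    """n positive fractional weights with sum ≤ 1 (= 1 when ``full``)."""
    grain = 16
    cuts = sorted(rng.randint(1, grain - 1) for _ in range(n - 1)) if n > 1 else []
    pieces = []
    prev = 0
    for c in cuts + [grain]:
        pieces.append(Fraction(max(c - prev, 1), grain))
        prev = c
    total = sum(pieces, Fraction(0))
    pieces = [p / total for p in pieces]
    if not full:
        scale = Fraction(rng.randint(grain // 2, grain), grain)
        pieces = [p * scale for p in pieces]
    return pieces


def random_bkb(seed: int, n_rvs: int = 5, n_states: int = 2,
               extra_rules: int = 2) -> BKB:
    """A seeded valid BKB: a layered rule structure (priors for roots,
    per-parent-state conditional blocks below) with weight sums kept
    under 1 by construction; validity is asserted, not assumed."""
    rng = random.Random(seed)
    rvs = [f"V{i}" for i in range(rng.randint(2, n_rvs))]
    states = {rv: [f"s{j}" for j in range(rng.randint(2, n_states))] for rv in rvs}
    rules: List[CPR] = []
    for i, rv in enumerate(rvs):
        if i == 0 or rng.random() < 0.4:
            chosen = [s for s in states[rv] if rng.random() < 0.8] or [states[rv][0]]
            for s, w in zip(chosen, _random_weights(rng, len(chosen))):
                rules.append(CPR(frozenset(), RVAssignment(rv, s), w))
        else:
            parent = rvs[rng.randrange(i)]
            for ps in states[parent]:
                if rng.random() < 0.3:
                    continue  # incompleteness is legal
                chosen = [s for s in states[rv] if rng.random() < 0.8] \
                    or [states[rv][0]]
                weights = _random_weights(rng, len(chosen))
                for s, w in zip(chosen, weights):
                    rules.append(CPR(frozenset({RVAssignment(parent, ps)}),
                                     RVAssignment(rv, s), w))
    # occasional long-antecedent rules, each concluding its own fresh rv
    for k in range(extra_rules):
        if len(rvs) < 3 or rng.random() < 0.5:
            continue
        others = rng.sample(rvs, k=2)
        ant = frozenset(
            RVAssignment(o, rng.choice(states[o])) for o in others
        )
        rules.append(CPR(ant, RVAssignment(f"W{k}", "t"),
                         Fraction(rng.randint(1, 8), 16)))
    bkb = BKB(rules)
    report = bkb.validate()
    if not report.valid:  # pragma: no cover - construction guarantees this
        raise GenerationError(f"seed {seed} produced an invalid BKB:\n{report}")
    return bkb


# ---------------------------------------------------------------------------
# Random valid BKOs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    n_individuals: int = 3
    n_classes: int = 4
    n_partitions: int = 0
    n_ptas: int = 3
    rule_density: float = 0.5
    max_antecedent: int = 2
    seed: int = 0


def random_bko(config: GeneratorConfig) -> BKO:
    """A seeded valid BKO.

    Base-class priors and short conditional PAAs over a small lexicon,
    plus a chain of terminological rules whose consequent classes are
    fresh (so instantiation has work to do and pairwise conditions hold
    structurally).  Optionally some declared 3-class partitions with
    weight-sum-1 priors over their states.  Output always validates.
    """
    rng = random.Random(config.seed)
    individuals = [Individual(f"a{i}") for i in range(config.n_individuals)]
    base = [Atomic(f"B{i}") for i in range(config.n_classes)]
    lexicon = DomainLexicon()
    axioms = AxiomStore()
    for ind in individuals:
        lexicon.register_individual(ind)
    for c in base:
        lexicon.register_class(c)

    paas: List[PAA] = []
    used_consequents: set[Assertion] = set()
    n_paas = max(1, int(config.rule_density * config.n_individuals
                        * config.n_classes * 0.5))
    attempts = 0
    while len(paas) < n_paas and attempts < 50 * n_paas:
        attempts += 1
        ind = rng.choice(individuals)
        con = Assertion(ind, rng.choice(base))
        if con in used_consequents:
            continue
        ant: set[Assertion] = set()
        if rng.random() < 0.5:
            for _ in range(rng.randint(1, config.max_antecedent)):
                c = rng.choice(base)
                cand = Assertion(rng.choice(individuals),
                                 c if rng.random() < 0.8 else complement(c))
                ant.add(cand)
        if not set_consistent(ant | {con}, axioms):
            continue
        if any(a.individual == con.individual
               and a.concept in (con.concept, complement(con.concept))
               for a in ant):
            continue  # antecedent must not restate or negate the consequent
        paas.append(make_paa(ant, con, Fraction(rng.randint(1, 16), 16)))
        used_consequents.add(con)

    for j in range(config.n_partitions):
        part = [Atomic(f"P{j}_{k}") for k in range(3)]
        for c in part:
            lexicon.register_class(c)
        axioms.declare_partition(part)
        ind = rng.choice(individuals)
        for c, w in zip(part, _random_weights(rng, 3, full=True)):
            paas.append(make_paa((), Assertion(ind, c), w))

    ptas: List[PTA] = []
    sources = list(base)
    for j in range(config.n_ptas):
        child = rng.choice(sources)
        parent = Atomic(f"D{config.seed % 997}_{j}")
        lexicon.register_class(parent)
        ptas.append(make_pta((VariableAssertion(_X, child),),
                             VariableAssertion(_X, parent),
                             Fraction(rng.randint(1, 16), 16),
                             pta_id=f"T{j}"))
        sources.append(parent)

    bko = BKO(paas, ptas, lexicon, axioms)
    report = bko.validate()
    if not report.valid:
        raise GenerationError(
            f"seed {config.seed} produced an invalid BKO:\n{report}"
        )
    return bko


# ---------------------------------------------------------------------------
# The brute-force joint-distribution oracle
# ---------------------------------------------------------------------------

def brute_force_posterior(rules: Iterable[CPR], q: Query) -> Fraction:
    """Exact posterior on a complete, acyclic conditional-table model.

    Enumerates every joint world, multiplying one applicable rule weight
    per variable; demands that in every world each variable has exactly
    one applicable rule per state with the block summing to 1.  This is
    the independent reference the reasoning code is tested against — it
    shares no machinery with inference enumeration.
    """
    rules = sorted(set(rules))
    registry: Dict[str, List] = {}
    for r in rules:
        for a in r.antecedent | {r.consequent}:
            registry.setdefault(a.rv, [])
            if a.state not in registry[a.rv]:
                registry[a.rv].append(a.state)
    for rv in registry:
        registry[rv] = sorted(registry[rv], key=str)
    rvs = sorted(registry)
    if len(rvs) > 12:
        raise OracleError("oracle limited to small domains")

    worlds = [dict(zip(rvs, combo))
              for combo in itertools.product(*(registry[rv] for rv in rvs))]

    def factor(world: Dict[str, object], rv: str) -> Fraction:
        applicable = [
            r for r in rules
            if r.consequent.rv == rv
            and all(world.get(a.rv) == a.state for a in r.antecedent)
        ]
        block = [r for r in applicable]
        total = sum((r.p for r in block if r.p is not None), Fraction(0))
        covered = {r.consequent.state for r in block}
        if covered != set(registry[rv]) or abs(float(total) - 1) > SUM_TOLERANCE:
            raise OracleError(
                f"incomplete conditional table for {rv} in world {world}"
            )
        matching = [r for r in block if r.consequent.state == world[rv]]
        if len(matching) != 1:
            raise OracleError(f"ambiguous table for {rv}")
        assert matching[0].p is not None
        return matching[0].p

    def mass(required: FrozenSet[RVAssignment]) -> Fraction:
        out = Fraction(0)
        for world in worlds:
            if any(world.get(a.rv) != a.state for a in required):
                continue
            p = Fraction(1)
            for rv in rvs:
                p *= factor(world, rv)
            out += p
        return out

    denominator = mass(q.evidence)
    if denominator == 0:
        raise UndefinedPosteriorError("evidence has zero mass under the oracle")
    return mass(q.evidence | q.targets) / denominator


# ---------------------------------------------------------------------------
# Toy instantiation spaces (Ω at desk scale)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyDomain:
    """A domain small enough to materialize every instantiation: each
    (individual, class) pair resolves to membership or complement."""

    individuals: Tuple[Individual, ...]
    classes: Tuple[Atomic, ...]
    axioms: AxiomStore = dataclasses_field(default_factory=AxiomStore)

    def omega(self) -> List[FrozenSet[Assertion]]:
        pairs = [(i, c) for i in self.individuals for c in self.classes]
        if len(pairs) > 20:
            raise OracleError("instantiation space capped at 2^20 states")
        worlds = []
        for bits in itertools.product((True, False), repeat=len(pairs)):
            world = frozenset(
                Assertion(i, c if member else complement(c))
                for (i, c), member in zip(pairs, bits)
            )
            if set_consistent(world, self.axioms):
                worlds.append(world)
        return worlds
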