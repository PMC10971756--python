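"""Shared fixtures: the fused sciatic-nerve pipeline and generators of
small complete conditional-table models for oracle comparisons."""

from __future__ import annotations

import itertools
import random
from fractions import Fraction
from types import SimpleNamespace

import pytest

from bkofusion import (
    Assertion,
    Atomic,
    CPR,
    Individual,
    RVAssignment,
    assertion_rv_key,
    extract_abox,
    full_instantiate,
    fuse_bkos,
    sciatic_fixture,
)


@pytest.fixture(scope="session")
def sciatic():
    """The fused and fully instantiated sciatic-nerve model."""
    fragments, anchor, terms = sciatic_fixture()
    fused = fuse_bkos(fragments)
    full, trace = full_instantiate(fused, anchor)
    bkb = extract_abox(full)
    evidence = [
        RVAssignment(assertion_rv_key(r.consequent, full.axioms), r.consequent)
        for r in anchor.paas
    ]
    a = Individual("a")

    def assignment(name: str, namespace: str) -> RVAssignment:
        assertion = Assertion(a, Atomic(name, namespace))
        return RVAssignment(assertion_rv_key(assertion, full.axioms), assertion)

    return SimpleNamespace(
        fragments=fragments, anchor=anchor, terms=terms, fused=fused,
        full=full, trace=trace, bkb=bkb, evidence=evidence,
        individual=a, assignment=assignment,
    )


def complete_binary_bkb(rng: random.Random, n_rvs: int):
    """A random acyclic model with full binary conditional tables — the
    kind of BKB whose pmf the brute-force oracle can evaluate exactly."""
    rvs = [f"X{i}" for i in range(n_rvs)]
    rules = []
    for i, rv in enumerate(rvs):
        n_parents = min(i, rng.randint(0, 2))
        parents = rng.sample(rvs[:i], k=n_parents)
        contexts = itertools.product(
            *[[(p, "t"), (p, "f")] for p in parents]
        )
        for ctx in contexts:
            p_true = Fraction(rng.randint(1, 15), 16)
            ant = frozenset(RVAssignment(p, s) for p, s in ctx)
            rules.append(CPR(ant, RVAssignment(rv, "t"), p_true))
            rules.append(CPR(ant, RVAssignment(rv, "f"), 1 - p_true))
    return rules, rvs
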