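"""Fusion of BKB fragments with per-consequent-variable source nodes.

Rules from several sources are combined without deleting or altering any
of them.  For every random variable X concluded by some fragment a source
variable S[X] is created with one state per contributing fragment; its
prior is the fragment's reliability normalized by the total reliability,
and the matching source state is conjoined to each contributing rule's
antecedent.  Rules from different fragments that conclude the same
variable then condition on different states of S[X] and are mutually
exclusive, which is what makes the union a valid BKB again.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Sequence, Tuple

from .bkb import BKB, CPR, RVAssignment, validate_bkb


class FusionError(ValueError):
    """Ill-formed fusion input (duplicate sources, bad weights, invalid
    fragments)."""


@dataclass(frozen=True)
class BKBFragment:
    """A rule set contributed by one source with a positive reliability."""

    rules: Tuple[CPR, ...]
    source: str
    weight: Fraction

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise FusionError(f"fragment weight must be positive: {self.weight}")


def bkb_fragment(rules: Iterable[CPR], source: str, weight) -> BKBFragment:
    w = Fraction(str(weight)) if isinstance(weight, float) else Fraction(weight)
    return BKBFragment(tuple(sorted(set(rules))), source, w)


def source_rv_name(rv: str) -> str:
    return f"S[{rv}]"


def fuse_bkbs(fragments: Sequence[BKBFragment],
              require_valid: bool = True) -> BKB:
    """Bayesian knowledge fusion over CPR fragments.

    Source states are fragment ordinals (1-based, in input order); source
    priors are w_i / Σw.  Every input rule reappears with its original
    weight and antecedent plus exactly one source assignment.
    """
    if not fragments:
        raise FusionError("at least one fragment is required")
    labels = [f.source for f in fragments]
    if len(set(labels)) != len(labels):
        raise FusionError(f"duplicate source labels: {sorted(labels)}")
    if require_valid:
        for f in fragments:
            report = validate_bkb(f.rules)
            if not report.valid:
                raise FusionError(
                    f"fragment {f.source!r} is not a valid BKB:\n{report}"
                )

    total = sum((f.weight for f in fragments), Fraction(0))
    fused: List[CPR] = []
    contributors: dict[str, List[int]] = {}
    for ordinal, f in enumerate(fragments, start=1):
        for r in f.rules:
            contributors.setdefault(r.consequent.rv, []).append(ordinal)

    for ordinal, f in enumerate(fragments, start=1):
        for r in f.rules:
            source_state = RVAssignment(source_rv_name(r.consequent.rv), ordinal)
            fused.append(CPR(r.antecedent | {source_state}, r.consequent,
                             r.p, f.source))
    for rv in sorted(contributors):
        for ordinal in sorted(set(contributors[rv])):
            fused.append(CPR(frozenset(),
                             RVAssignment(source_rv_name(rv), ordinal),
                             fragments[ordinal - 1].weight / total,
                             fragments[ordinal - 1].source))
    return BKB(fused)
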