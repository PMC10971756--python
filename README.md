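# bkofusion

Probabilistic fusion of ontologies with Bayesian knowledge bases.

Biomedical knowledge is spread over many overlapping ontologies — MONDO
and the Human Disease Ontology (DO) both describe sciatic-nerve disease,
and they disagree about it.  Classical ontology merging must delete or
rewrite statements until the result is consistent.  `bkofusion` instead
represents terminological axioms as probabilistic conditional rules,
fuses fragments from different sources under reliability weights without
altering a single statement, and ranks contradictory conclusions instead
of discarding one.  It is a library plus a small `bko` command-line tool
for researchers who integrate curated ontologies (or any rule-structured
probabilistic knowledge) and want a calibrated, backtraceable answer to
"how strongly does the combined knowledge support this membership
claim?".

## The model in brief

A **BKB** (Bayesian knowledge base) is a finite set of conditional
probability rules `P(X = x | Y₁ = y₁ ∧ … ∧ Yₖ = yₖ) = p` over discrete
variables.  Unlike a Bayesian network it admits cycles and incomplete
distributions; validity instead requires that rules concluding the same
assignment be mutually exclusive through their antecedents, and that
competing rules' weights sum to at most 1.  An **inference** is an
acyclic rule set in which every antecedent is concluded by exactly one
member; its probability is `∏ p`, and posteriors are ratios of summed
inference masses.

A **BKO** (Bayesian knowledge-driven ontology) lifts this to ontology
content.  Membership assertions `a ∈ C` are the variable states; a
**PAA** is a rule over assertions, a **PTA** is its first-order form
over variable individuals `x̂`.  A subsumption axiom `C ⊆ D` is the
certainty rule `P(x̂∈D | x̂∈C) = 1`.  The *full instantiation* algorithm
grounds every PTA whose antecedents are supported, to a fixed point,
producing an equivalent BKB.  *Fusion* of fragments `(Bᵢ, sᵢ, wᵢ)` adds
a source prior `P(a_s ∈ C_sᵢ) = wᵢ/Σw` per fragment and conjoins the
source assertion to every rule, so contradictory fragments coexist and
every conclusion is attributable to the sources that produced it.

## Worked example

Fuse the MONDO, DO and OxO-bridge subsets around the sciatic nerve
(weight 1 each), instantiate from the anchor
`{a ∈ LesionofSciaticNerve(MONDO), a ∈ SciaticNeuropathy(DO)}`, and
compare the two contradictory subsumption conclusions:

```python
from fractions import Fraction
from bkofusion import (RVAssignment, assertion_rv_key, extract_abox,
                       full_instantiate, fuse_bkos,
                       partial_belief_revision, sciatic_fixture)

fragments, anchor, terms = sciatic_fixture()
fused = fuse_bkos(fragments)                  # 3 source priors, 17 PTAs
full, trace = full_instantiate(fused, anchor)
print("instantiations per pass:", trace.instantiated_counts)

bkb = extract_abox(full)
evidence = [RVAssignment(assertion_rv_key(r.consequent, full.axioms),
                         r.consequent) for r in anchor.paas]
for claim in sorted({r.consequent for r in full.paas
                     if r.provenance and r.provenance[0] in ("TM1", "TD1")}):
    target = RVAssignment(assertion_rv_key(claim, full.axioms), claim)
    best = partial_belief_revision(bkb, evidence, [target])[0]
    print(f"{claim}: best explanation {float(best.probability):.2f}")
```

prints

```
instantiations per pass: (2, 6, 2, 3, 4)
a∈LesionofSciaticNerve(DO): best explanation 0.33
a∈SciaticNeuropathy(MONDO): best explanation 0.33
```

The first pass grounds the two contradictory direction rules (MONDO says
a lesion of the sciatic nerve *is a* sciatic neuropathy; DO says the
reverse), the second pass the bridge equivalences, and the fixed point
holds 22 assertional rules.  Each contradictory conclusion is explained
with probability 1/3 ≈ 0.33 — the normalized reliability of its source
times a chain of certainty rules — so neither claim is discarded and a
higher-weighted source would visibly win.  The fused model also contains
an emergent chain from sciatic neuropathy through the bridge to MONDO's
Inflammatory Disease that exists in none of the three inputs alone.

The same pipeline from the shell:

```bash
bko pipeline --fragment mondo.yaml --fragment do.yaml --fragment bridge.yaml \
    --anchor anchor.yaml --out-prefix results/sciatic
bko validate results/sciatic.full.yaml
bko export-graph --bko results/sciatic.full.yaml -o sciatic.dot
```

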