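# Methods

`bkofusion` implements Bayesian knowledge-driven ontologies (BKOs): a
representation in which ontology axioms are probabilistic conditional
rules, several (possibly contradictory) ontology fragments can be fused
under source-reliability weights without deleting or altering any
statement, and membership questions are answered by enumerating
inferences over the resulting Bayesian knowledge base (BKB).  This note
records the model, the semantic choices that were genuinely open, the
numerical conventions, and what the shipped tests do and do not show.

## The model

**Domain.**  A finite lexicon of individuals and classes under a small
description logic: atomic classes (optionally namespaced, optionally
carrying a CURIE), complement, intersection, union, and role-filler
membership `b ∈ R(b, c)`.  An *assertion* `a ∈ C` is the atom of all
rules; its negation is `a ∈ ¬C`.  Two assertions conflict only when they
pin the same individual into provably disjoint classes, and disjointness
is decided purely from declarations: syntactic complements, declared
disjoint pairs, and subsumption lifting (`C ⊆ C′`, `C′` disjoint `D` ⇒
`C` disjoint `D`).  There is no tableau reasoner; anything underivable is
non-disjoint by the open-world default.  Whether a declared partition
actually covers its parent class is not checked — coverage is
undecidable open-world and is treated as a trust assumption.

**Random variables.**  A family of pairwise disjoint classes induces,
for each individual, a discrete variable whose states are the membership
assertions.  By default every class `C` contributes the binary variable
`{a∈C, a∈¬C}` per individual; an explicitly declared multi-class
partition overrides the binary default for its members.

**Rules.**  A conditional probability rule (CPR) is
`P(consequent | antecedent) = p` over variable assignments, with an
empty antecedent a prior.  A PAA is a CPR whose states are assertions; a
PTA is its first-order counterpart over variable individuals (`x̂`),
instantiated by injective substitutions into PAAs with the same weight.
Crisp axioms embed as certainty rules: an assertion is a weight-1 prior,
`C ⊆ D` is `P(x̂∈D | x̂∈C) = 1`, disjointness is the two weight-0 rules
plus a declared disjoint pair.  Weights are stored as exact
`fractions.Fraction` values from the moment they are parsed (decimal
strings in the exchange format), so `1/3` survives to the printed
`0.33` without drift; the `1e-9` tolerance on weight-sum checks only
matters for weights that arrive as binary floats.

**Validity.**  A rule set is a valid BKB/BKO when (i) distinct rules
concluding the same assignment are mutually exclusive through their
antecedents, (ii) competing rules (consequent-bound: compatible
antecedents, conflicting consequents) have weight sums at most one —
checked on maximal cliques of the pairwise consequent-bound graph, which
is where subset sums are maximized — and (iii) for assertion-valued
rules, every pair either excludes the other or tolerates the negation of
the other's conclusion.  Quantified conditions on PTA pairs are decided
by exhaustively enumerating injective substitutions into the pool of
mentioned and registered individuals plus enough fresh ones; over the
restricted constructor grammar this enumeration is equivalent to the
quantifier and is exact.  It is exponential in the number of variables
per rule, which is 1–2 for subsumption-style ontology rules; validation
of rules with many variables is correspondingly expensive and not the
intended use.

Two deliberate refinements:

* Rules with *unspecified* weights (reasoning anchors, see below) are
  query scaffolding, not knowledge; validity checks skip them.
* A non-exclusive pair concluding the *identical assertion* is treated
  as redundant parallel support, not a conflict.  Any is-a hierarchy in
  which a class has two children produces such pairs after
  instantiation, and the support-graph picture (several support nodes
  feeding one instantiation node) makes the intent plain.  Token-state
  CPR sets keep the strict check — there, two compatible rules with one
  consequent are exactly the pathology that source nodes exist to fix.

## Reasoning semantics

**Inferences.**  An inference is an acyclic rule set in which every
antecedent assignment is concluded by exactly one member rule and all
rules are mutually compatible; its probability is the product of its
weights.  Enumeration grows inferences forward from the empty set (a
rule may join once its antecedent is induced and its consequent variable
is free), which makes acyclicity and compatibility structural rather
than checked.

**Posterior masses.**  The joint mass of a conjunction of assignments is
the summed probability of its *minimal-support* inferences: every way of
choosing one supporting rule per needed variable, closed under
antecedents, cycles discarded.  The empty conjunction is supported by
the empty inference (mass 1).  Distinct support closures differ in the
rule chosen for some variable and are treated as exclusive alternatives,
so masses add.  Belief updating returns the ratio
`mass(targets ∪ evidence) / mass(evidence)` via an auxiliary query
variable; on complete conditional tables this equals the full-joint
posterior exactly (tested against an independent world-enumeration
oracle), and on incomplete rule sets it leaves unassigned mass
unassigned instead of renormalizing.  A target concluded nowhere, or one
with no complete support chain, is INCALCULABLE — a result, not an
exception — while evidence of mass zero raises, since conditioning on it
is undefined.  Belief revision ranks maximal inferences (most probable
explanation); partial belief revision ranks the supports of a chosen
target set given evidence, the right lens for comparing contradictory
conclusions.

**Anchors and anchored queries.**  A reasoning anchor is a set of prior
PAAs whose weights may be UNSPECIFIED (`None`); they participate in
support and groundedness but contribute no factor to any product, and
the anchored-query tests sweep numeric stand-ins to confirm no
placeholder can leak into a posterior.  In anchored membership queries
the evidence variables are clamped to their anchors: alternative
derivations of an observed assertion must not inflate its mass.

**Groundedness.**  A PAA is grounded when it is a prior or every
antecedent assertion is concluded by some rule.  Ungrounded rules
contribute nothing to the mass function; pruning them changes no
computable posterior and rescues no incalculable one (verified by paired
runs), because no complete support chain ever passes through one.

## Full instantiation

The fixed-point loop starts from the anchor; each pass first absorbs
every already-supported assertional rule of the knowledge base, then
matches each PTA's antecedent clauses against the consequents as they
stand at that point.  Matching is one-way unification: clause variables
bind to the ground assertion's individuals, embedded specific
individuals must match exactly, and the per-clause bindings are joined
into conflict-free injective substitutions covering the rule's
variables.  (Matching via generalization equality coincides with
unification on all-variable clauses but cannot handle clauses that
embed specific individuals, so unification is the primitive.)
Ground clauses in a PTA antecedent — source assertions after fusion —
must themselves be concluded.

Two scheduling conventions define the pass accounting:

* matching is snapshotted per pass (no intra-pass growth of the
  consequent set beyond the absorption step), and
* within one pass each assertion gains at most one new supporting rule;
  a candidate concluding an assertion already derived earlier in the
  same pass waits for the next pass.

The second convention makes a pass read as one breadth-first layer of
the support graph: new conclusions first, parallel derivations
afterwards.  Both conventions affect only how additions distribute over
passes; the fixed point — every instantiation that would be grounded,
and no other — is the same under any fair schedule, and rerunning the
loop on its own output adds nothing.  PTAs are processed in fusion input
order (then by rule id), so the worked example's first pass derives the
MONDO-direction and DO-direction conclusions exactly as published.

The number of instantiations of a rule is bounded by the product of its
per-clause support counts; shared variables between clauses prune the
product because the join must agree on them.  Both facts are exercised
directly: an unshared three-clause rule with 3/4/3 supporters grounds
exactly 36 ways, a shared-variable variant on the same support multiset
strictly fewer.

## Fusion

**CPR fragments** fuse with one source variable per *consequent
variable* `X`: states are the 1-based ordinals of the contributing
fragments, the prior of state `i` is `w_i / Σw`, and the matching source
assignment is conjoined to each contributing rule.  Rules from different
fragments concluding the same variable then condition on different
source states and are mutually exclusive, which is the whole point.

**BKO fragments** fuse with one source *class* per fragment: a fresh
atomic `C_s` in the reserved `source` namespace, a single shared source
individual `a_s`, a source prior `P(a_s ∈ C_s) = w / Σw`, and the source
assertion conjoined to every rule of the fragment (as an rv assignment
on PAAs, as a ground clause on PTAs so it survives instantiation).
Source classes are declared pairwise disjoint among themselves — a rule
can only have come from the source that asserted it — but never disjoint
with any domain class, which implements the default that classes from
different ontologies are assumed compatible unless an alignment
fragment declares otherwise.  Bridge (cross-reference) ontologies are
ordinary fragments of paired directional certainty rules.

This source model has a deliberate two-level semantics.  *Validation*
works at the assertion level, where the disjoint source classes make
rules from different fragments mutually exclusive; that is what lets the
fused and fully instantiated disease-ontology model pass both the BKO
and the BKB validity checks even though, e.g., the MONDO direction rule
and the bridge rule conclude the same assertion.  *Inference
enumeration* works at the variable level, where each source class is its
own binary variable; an inference may therefore assume several sources
at once, paying the product of their reliabilities.  The two levels
coincide whenever fragments do not share conclusion classes (the
assumption under which the fusion validity theorem is stated) and
diverge exactly for bridge-style overlapping fragments — where the
divergence is what produces the emergent cross-ontology chains that are
fusion's purpose.  Treating exclusivity strictly during inference would
forbid any reasoning chain that borrows from two sources, including the
published chain from sciatic neuropathy to inflammatory disease.

Contradictions are not resolved but ranked: with equal weights the two
inverse subsumption claims between MONDO's and DO's sciatic-nerve terms
each receive a best explanation of probability 1/3 (their shared
normalized reliability), and a user who trusted one source more would
see that in the ratio.

## Synthetic data

`random_bkb` builds layered token-state rule sets (priors at the roots,
per-parent-state conditional blocks below, occasional long-antecedent
rules on fresh variables) whose construction keeps every weight-sum
under one, so instances are valid by design and re-validated; sizes
default to 2–5 variables with 2 states, small enough that inference
enumeration and clique checks stay exhaustive.  `random_bko` builds
base-class priors and short conditional PAAs over 3 individuals and 4
classes, a chain of fresh-consequent terminological rules so
instantiation has work to do, and optionally declared 3-class partitions
with weight-1 priors.  These generators emulate the *structure* the
theory quantifies over — mutual exclusivity patterns, consequent-bound
competition, support chains — not any real ontology's content: they
contain no contradictory cross-fragment claims, no noisy weights
estimated from data, and no large-fanout hierarchies, so passing
property tests shows the structural theorems hold at desk scale, not
that the method is robust on a production ontology.  The complete
conditional-table generator used for oracle comparisons is the one place
where the full joint distribution exists in closed form; the
brute-force oracle enumerates its worlds independently of all inference
machinery.

## Problem sizes and numerics

All shipped computations are exact rational arithmetic end to end.  The
property suites run at the sizes the exhaustive checks can afford —
maximal-clique families of the inference incompatibility graph grow
combinatorially with independent variables, so the sweep sizes keep
every instance fully checkable: 1000 seeded random BKBs (2–3 variables,
every incompatible family summed) for the inference-mass bounds, 500
fragment pairs for fusion validity, 500 random BKOs for instantiation
closure and extraction, 100 oracle comparisons, 200 paired pruning
runs.  The worked disease-ontology model is 22 assertional rules after
instantiation and runs end to end in well under a second.  Determinism
is total: every container sorts on canonical string forms, ties in
rankings break lexicographically, and the generators are seeded.

## Known limitations

* The governing logic is the declared-axiom closure; consistency between
  constructed classes beyond complements/declarations is not decided.
* Quantified PTA checks enumerate substitutions and are exponential in
  variables-per-rule; fine for ontology-style rules, wrong tool for
  rules with many variables.
* Exact enumeration only: no approximate or anytime inference, no
  search heuristics.  Models beyond desk scale need the `max_rules` /
  `max_paas` caps, which truncate with a flag rather than degrade
  gracefully.
* Posterior masses treat alternative supports of one conclusion as
  exclusive; in fused models with parallel derivations this is the
  source-exclusivity reading, and masses are upper bounds under readings
  that allow co-derivation.
* OBO ingestion is minimal (id, name, namespace, is_a); reliabilities
  are inputs, never learned; alignment generation is out of scope.
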