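"""Generalization, matching, the instantiation fixed point, pruning."""

import itertools
import random
from fractions import Fraction

import pytest

from bkofusion import (
    Assertion,
    Atomic,
    AxiomStore,
    BKO,
    DomainLexicon,
    GeneratorConfig,
    Individual,
    PAA,
    ReasoningAnchor,
    RoleFiller,
    VariableAssertion,
    VariableIndividual,
    belief_update,
    extract_abox,
    full_instantiate,
    generalize,
    is_grounded,
    match_clause,
    paa,
    prune_ungrounded,
    pta,
    query,
    random_bko,
    validate_bkb,
    validate_bko,
    var_assertions_equivalent,
)
from bkofusion.concepts import assertion_rv_key

a, b, c = Individual("a"), Individual("b"), Individual("c")
x, y = VariableIndividual("x"), VariableIndividual("y")
C1, C2 = Atomic("C1"), Atomic("C2")


class TestGeneralize:
    def test_atomic_concept(self):
        g = generalize(Assertion(a, C1))
        assert g.concept == C1
        assert var_assertions_equivalent(g, VariableAssertion(x, C1))

    def test_role_filler_with_two_individuals(self):
        g = generalize(Assertion(a, RoleFiller("R", a, b)))
        expected = VariableAssertion(x, RoleFiller("R", x, y))
        assert var_assertions_equivalent(g, expected)
        # the subject variable reappears inside the concept
        assert g.subject in g.variables()
        assert len(g.variables()) == 2

    def test_repeated_individual_maps_to_one_variable(self):
        g = generalize(Assertion(a, RoleFiller("R", a, a)))
        assert len(g.variables()) == 1

    def test_idempotent_up_to_renaming(self):
        for assertion in (Assertion(a, C1),
                          Assertion(a, RoleFiller("R", a, b))):
            g1 = generalize(assertion)
            probe = Individual("_probe0", namespace="_eq")
            # generalizing any instantiation of g yields an equivalent form
            from bkofusion.bko import substitute
            grounded = substitute(
                g1, {v: Individual(f"p{i}") for i, v in
                     enumerate(sorted(g1.variables()))})
            assert var_assertions_equivalent(g1, generalize(grounded))


class TestEquivalence:
    def test_renaming_is_equivalence(self):
        assert var_assertions_equivalent(VariableAssertion(x, C1),
                                         VariableAssertion(y, C1))

    def test_argument_order_matters(self):
        v1 = VariableAssertion(x, RoleFiller("R", x, y))
        v2 = VariableAssertion(x, RoleFiller("R", y, x))
        assert not var_assertions_equivalent(v1, v2)

    def test_specific_versus_variable_filler(self):
        """Substitution oracle over a 2-individual pool: the forms behave
        differently, so they must not be equivalent."""
        v1 = VariableAssertion(x, RoleFiller("R", x, b))
        v2 = VariableAssertion(x, RoleFiller("R", x, y))
        assert not var_assertions_equivalent(v1, v2)
        # v2 matches a ground assertion with any filler, v1 only filler b
        g1 = Assertion(a, RoleFiller("R", a, c))
        assert match_clause(v2, g1) and not match_clause(v1, g1)
        g2 = Assertion(a, RoleFiller("R", a, b))
        assert match_clause(v1, g2) and match_clause(v2, g2)


class TestGroundedness:
    def test_priors_are_grounded(self):
        assert is_grounded(paa((), Assertion(a, C1), "0.5"), [])

    def test_supported_rule_is_grounded(self):
        support = paa((), Assertion(a, C1), "0.5")
        rule = paa((Assertion(a, C1),), Assertion(a, C2), "0.5")
        assert is_grounded(rule, [support])

    def test_unconcluded_antecedent_is_ungrounded(self):
        rule = paa((Assertion(a, C1),), Assertion(a, C2), "0.5")
        assert not is_grounded(rule, [])


def unshared_combinatorics_bko():
    """One rule whose three antecedent clauses share no variables, with
    3 / 4 / 3 matching priors: every combination joins, so the rule must
    ground exactly 3·4·3 = 36 ways."""
    x1, x2, x4, x5, x6, x7 = (VariableIndividual(f"v{i}")
                              for i in (1, 2, 4, 5, 6, 7))
    t = pta(
        (VariableAssertion(x1, RoleFiller("R2", x1, x2)),
         VariableAssertion(x4, RoleFiller("R3", x4, x5)),
         VariableAssertion(x6, RoleFiller("R4", x6, x7))),
        VariableAssertion(x1, RoleFiller("R1", x1, x2)),
        "0.5", pta_id="T",
    )
    priors = []
    idx = itertools.count()
    for role, count in (("R2", 3), ("R3", 4), ("R4", 3)):
        for _ in range(count):
            owner = Individual(f"o{next(idx)}")
            filler = Individual(f"f{next(idx)}")
            priors.append(paa((), Assertion(owner, RoleFiller(role, owner, filler)),
                              "0.5"))
    return BKO(priors, [t]), t


def shared_combinatorics_bko():
    """Same 3/4/3 support multiset, but two antecedent clauses share a
    variable, so only join-compatible combinations ground."""
    x1, x2, x3, x4 = (VariableIndividual(f"v{i}") for i in (1, 2, 3, 4))
    t = pta(
        (VariableAssertion(x1, RoleFiller("R2", x1, x3)),
         VariableAssertion(x4, RoleFiller("R3", x4, x2)),
         VariableAssertion(x3, RoleFiller("R4", x3, x2))),
        VariableAssertion(x1, RoleFiller("R1", x1, x2)),
        "0.5", pta_id="T",
    )
    a1, a2, a3 = Individual("a1"), Individual("a2"), Individual("a3")
    b1, b2, b3 = Individual("b1"), Individual("b2"), Individual("b3")
    m1, m2, m3 = Individual("m1"), Individual("m2"), Individual("m3")
    cs = [Individual(f"c{i}") for i in range(4)]
    q = Individual("q")
    z = Individual("z")
    priors = [
        # R2 owners a_i with fillers b_i (3 supporters)
        paa((), Assertion(a1, RoleFiller("R2", a1, b1)), "0.5"),
        paa((), Assertion(a2, RoleFiller("R2", a2, b2)), "0.5"),
        paa((), Assertion(a3, RoleFiller("R2", a3, b3)), "0.5"),
        # R3 supporters (4), two pointing at m1, one at m2, one elsewhere
        paa((), Assertion(cs[0], RoleFiller("R3", cs[0], m1)), "0.5"),
        paa((), Assertion(cs[1], RoleFiller("R3", cs[1], m2)), "0.5"),
        paa((), Assertion(cs[2], RoleFiller("R3", cs[2], m1)), "0.5"),
        paa((), Assertion(cs[3], RoleFiller("R3", cs[3], q)), "0.5"),
        # R4 supporters (3): only b1 and b2 can serve the shared x3
        paa((), Assertion(b1, RoleFiller("R4", b1, m1)), "0.5"),
        paa((), Assertion(b2, RoleFiller("R4", b2, m2)), "0.5"),
        paa((), Assertion(z, RoleFiller("R4", z, m3)), "0.5"),
    ]
    return BKO(priors, [t]), t


class TestCombinatorics:
    def test_unshared_variables_instantiate_the_full_product(self):
        bko, t = unshared_combinatorics_bko()
        full, trace = full_instantiate(bko)
        instantiated = [r for r in full.paas if r.provenance]
        assert len(instantiated) == 36

    def test_shared_variables_prune_the_product(self):
        bko, t = shared_combinatorics_bko()
        full, trace = full_instantiate(bko)
        instantiated = [r for r in full.paas if r.provenance]
        assert 0 < len(instantiated) < 36

    def test_product_upper_bound_on_random_instances(self):
        """|S_T| never exceeds the product of per-clause support counts."""
        for seed in range(20):
            rng = random.Random(seed)
            roles = ["Ra", "Rb"]
            x1, x2, x3 = (VariableIndividual(f"w{i}") for i in range(3))
            t = pta(
                (VariableAssertion(x1, RoleFiller("Ra", x1, x2)),
                 VariableAssertion(x3, RoleFiller("Rb", x3,
                                                  x2 if rng.random() < 0.5
                                                  else x1))),
                VariableAssertion(x1, RoleFiller("Rc", x1, x2)),
                "0.5", pta_id="T",
            )
            priors = []
            counts = {}
            for role in roles:
                counts[role] = rng.randint(1, 4)
                for i in range(counts[role]):
                    owner = Individual(f"{role}o{i}{seed}")
                    filler = Individual(
                        rng.choice([f"{role}o{i}{seed}x", f"shared{seed}",
                                    f"shared2{seed}"]))
                    priors.append(
                        paa((), Assertion(owner, RoleFiller(role, owner, filler)),
                            "0.5"))
            full, _ = full_instantiate(BKO(priors, [t]))
            instantiated = [r for r in full.paas if r.provenance]
            assert len(instantiated) <= counts["Ra"] * counts["Rb"], seed


class TestFixedPoint:
    def test_idempotence(self):
        bko, _ = unshared_combinatorics_bko()
        once, _ = full_instantiate(bko)
        twice, trace = full_instantiate(once)
        assert set(twice.paas) == set(once.paas)
        assert sum(len(p.instantiated) for p in trace.passes) == 0

    def test_anchor_monotonicity(self):
        """Enlarging the anchor never shrinks the instantiated set."""
        lex = DomainLexicon()
        lex.register_individual(a)
        lex.register_individual(b)
        t1 = pta((VariableAssertion(x, C1),), VariableAssertion(x, C2), 1,
                 pta_id="T1")
        bko = BKO((), [t1], lex)
        small, _ = full_instantiate(
            bko, ReasoningAnchor.from_assertions([Assertion(a, C1)]))
        large, _ = full_instantiate(
            bko, ReasoningAnchor.from_assertions([Assertion(a, C1),
                                                  Assertion(b, C1)]))
        assert set(small.paas) <= set(large.paas)
        assert len(large.paas) == len(small.paas) + 2

    def test_output_contains_every_grounded_instantiation_and_no_other(self):
        lex = DomainLexicon()
        lex.register_individual(a)
        t1 = pta((VariableAssertion(x, C1),), VariableAssertion(x, C2), 1,
                 pta_id="T1")
        t2 = pta((VariableAssertion(x, Atomic("C9")),),
                 VariableAssertion(x, C1), 1, pta_id="T2")
        bko = BKO([paa((), Assertion(a, C1), "0.5")], [t1, t2], lex)
        full, _ = full_instantiate(bko)
        instantiated = {r for r in full.paas if r.provenance}
        assert {r.consequent for r in instantiated} == {Assertion(a, C2)}


class TestExtraction:
    def test_empty_bko_extracts_to_empty_bkb(self):
        assert len(extract_abox(BKO())) == 0

    def test_random_instantiated_bkos_extract_to_valid_bkbs(self):
        for seed in range(40):
            bko = random_bko(GeneratorConfig(seed=seed, n_partitions=1))
            full, _ = full_instantiate(bko)
            assert validate_bko(full).valid, seed
            assert extract_abox(full).validate().valid, seed


class TestPruning:
    def test_ungrounded_rule_is_removed_and_posteriors_survive(self):
        support = paa((), Assertion(a, C1), "0.5")
        chained = paa((Assertion(a, C1),), Assertion(a, C2), "0.8")
        orphan = paa((Assertion(b, Atomic("C9")),), Assertion(b, C1), "0.9")
        bko = BKO([support, chained, orphan])
        pruned = prune_ungrounded(bko)
        assert orphan not in pruned.paas
        assert set(pruned.paas) == {support, chained}
        for model in (bko, pruned):
            rules = [r.to_cpr(model.axioms) for r in model.paas]
            tgt = Assertion(a, C2)
            result = belief_update(
                rules,
                query([], [type(rules[0].consequent)(
                    assertion_rv_key(tgt, model.axioms), tgt)]),
            )
            assert result.probability == Fraction(2, 5)

    def test_fully_grounded_bko_is_unchanged(self):
        support = paa((), Assertion(a, C1), "0.5")
        chained = paa((Assertion(a, C1),), Assertion(a, C2), "0.8")
        bko = BKO([support, chained])
        assert set(prune_ungrounded(bko).paas) == set(bko.paas)

    def test_anchor_supported_rules_survive(self):
        anchor_rule = paa((), Assertion(a, C1), None)
        chained = paa((Assertion(a, C1),), Assertion(a, C2), "0.8")
        bko = BKO([anchor_rule, chained])
        assert set(prune_ungrounded(bko).paas) == {anchor_rule, chained}

    def test_pruning_preserves_posteriors_on_random_models(self):
        from bkofusion import RVAssignment

        for seed in range(30):
            bko = random_bko(GeneratorConfig(seed=seed))
            full, _ = full_instantiate(bko)
            pruned = prune_ungrounded(full)
            rng = random.Random(seed)
            targets = sorted(r.consequent for r in full.paas)
            if not targets:
                continue
            tgt = rng.choice(targets)
            posteriors = []
            for model in (full, pruned):
                rules = [r.to_cpr(model.axioms) for r in model.paas]
                assignment = RVAssignment(
                    assertion_rv_key(tgt, model.axioms), tgt)
                posteriors.append(
                    belief_update(rules, query([], [assignment])).probability
                )
            assert posteriors[0] == posteriors[1], seed
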