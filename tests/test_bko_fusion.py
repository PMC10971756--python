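"""BKO fusion with per-fragment source classes and reliabilities."""

import random
from fractions import Fraction

import pytest

from bkofusion import (
    Assertion,
    Atomic,
    BKO,
    FusionError,
    GeneratorConfig,
    Individual,
    PAA,
    SOURCE_INDIVIDUAL,
    attribute_sources,
    bko_fragment,
    extract_abox,
    full_instantiate,
    fuse_bkos,
    partial_belief_revision,
    random_bko,
    sciatic_fixture,
    validate_bko,
)
from bkofusion.concepts import assertion_rv_key
from bkofusion.bkb import RVAssignment


class TestWorkedExample:
    def test_equal_weights_normalize_to_thirds(self, sciatic):
        priors = [r for r in sciatic.fused.paas if not r.antecedent]
        assert len(priors) == 3
        assert all(r.p == Fraction(1, 3) for r in priors)
        assert sum(r.p for r in priors) == 1

    def test_every_pta_gains_its_source_assertion(self, sciatic):
        for t in sciatic.fused.ptas:
            ground = [c for c in t.antecedent if isinstance(c, Assertion)]
            assert len(ground) == 1
            (src,) = ground
            assert src.individual == SOURCE_INDIVIDUAL
            assert src.concept.name == t.source

    def test_scaled_weights_produce_identical_probabilities(self):
        fragments, anchor, _ = sciatic_fixture()
        doubled = [bko_fragment(f.bko, f.source, 2) for f in fragments]
        fused1, fused2 = fuse_bkos(fragments), fuse_bkos(doubled)
        assert {(r.consequent, r.p) for r in fused1.paas} == \
            {(r.consequent, r.p) for r in fused2.paas}

    def test_single_fragment_keeps_its_semantics(self):
        fragments, _, _ = sciatic_fixture()
        fused = fuse_bkos([fragments[0]])
        (prior,) = [r for r in fused.paas if not r.antecedent]
        assert prior.p == 1
        assert len(fused.ptas) == len(fragments[0].bko.ptas)

    def test_fused_model_validates(self, sciatic):
        assert validate_bko(sciatic.fused).valid


class TestKnowledgePreservation:
    def test_rule_counts_and_recoverability(self, sciatic):
        fragments = sciatic.fragments
        fused = sciatic.fused
        total_in = sum(len(f.bko.paas) + len(f.bko.ptas) for f in fragments)
        assert len(fused.paas) + len(fused.ptas) == total_in + len(fragments)
        # stripping the source conjunct recovers each original rule
        for f in fragments:
            for t in f.bko.ptas:
                recovered = [
                    u for u in fused.ptas
                    if u.consequent == t.consequent and u.p == t.p
                    and {c for c in u.antecedent
                         if not isinstance(c, Assertion)} == set(t.antecedent)
                ]
                assert recovered, t


class TestContradictionTolerance:
    def test_contradictory_fragments_fuse_and_tie(self, sciatic):
        """Mutually inverse subsumption claims both survive fusion; their
        best explanations from the anchor tie at the shared source
        reliability 1/3."""
        bkb = sciatic.bkb
        mondo_claim = sciatic.assignment("SciaticNeuropathy", "MONDO")
        do_claim = sciatic.assignment("LesionofSciaticNerve", "DO")
        tops = [
            partial_belief_revision(bkb, sciatic.evidence, [claim])[0]
            for claim in (mondo_claim, do_claim)
        ]
        assert tops[0].probability == tops[1].probability == Fraction(1, 3)


class TestEmergence:
    def test_inflammatory_disease_is_reachable_only_by_fusion(self, sciatic):
        target = sciatic.assignment("InflammatoryDisease", "MONDO")
        supports = partial_belief_revision(sciatic.bkb, sciatic.evidence,
                                           [target])
        assert supports
        contributions = attribute_sources(sciatic.full, supports[0])
        assert {"MONDO", "DO", "BRIDGE"} <= set(contributions)
        # no single fragment, even with the anchor, concludes it
        for fragment in sciatic.fragments:
            alone, _ = full_instantiate(fragment.bko, sciatic.anchor)
            concluded = {r.consequent for r in alone.paas}
            assert target.state not in concluded, fragment.source


class TestMembershipQueryOnFusedModel:
    def test_anchored_query_sums_the_source_branches(self, sciatic):
        """Asking for MONDO's Mononeuropathy given the anchor evidence
        sums the exclusive source-branch explanations: the direct MONDO
        chain (1/3) plus every bridge detour, each discounted by the
        reliabilities of the sources it borrows."""
        from bkofusion import answer_pmq, membership_query
        from bkofusion.concepts import Assertion, Atomic

        evidence = [r.consequent for r in sciatic.anchor.paas]
        target = Assertion(sciatic.individual,
                           Atomic("Mononeuropathy", "MONDO"))
        result = answer_pmq(sciatic.fused,
                            membership_query(evidence, [target]),
                            anchored=True)
        assert result.calculable
        assert result.evidence_mass == 1
        # the sum over its ranked supporting inferences is the posterior
        total = sum((i.probability for i in result.supporting_inferences),
                    Fraction(0))
        assert result.probability == total
        assert Fraction(1, 3) <= result.probability <= 1
        assert result.supporting_inferences[0].probability == Fraction(1, 3)


class TestAttribution:
    def test_source_priors_attribute_to_themselves(self, sciatic):
        from bkofusion import support_inferences

        prior = next(r for r in sciatic.bkb
                     if not r.antecedent and r.source == "MONDO")
        (inference,) = support_inferences(sciatic.bkb, [prior.consequent])
        contributions = attribute_sources(sciatic.full, inference)
        assert set(contributions) == {"MONDO"}

    def test_single_fragment_fusion_attributes_one_source(self):
        fragments, anchor, _ = sciatic_fixture()
        fused = fuse_bkos([fragments[0]])
        full, _ = full_instantiate(fused, anchor)
        bkb = extract_abox(full)
        target = next(r.consequent for r in bkb if r.antecedent)
        from bkofusion import support_inferences

        for inference in support_inferences(bkb, [target]):
            labels = set(attribute_sources(full, inference)) - {"anchor"}
            assert labels == {"MONDO"}


class TestErrors:
    def test_duplicate_sources_rejected(self):
        fragments, _, _ = sciatic_fixture()
        with pytest.raises(FusionError, match="duplicate"):
            fuse_bkos([fragments[0],
                       bko_fragment(fragments[1].bko, "MONDO", 1)])

    def test_nonpositive_weight_rejected(self):
        fragments, _, _ = sciatic_fixture()
        with pytest.raises(FusionError, match="positive"):
            bko_fragment(fragments[0].bko, "X", -1)


class TestRandomFragmentPairs:
    def test_fusion_of_random_valid_pairs_validates(self):
        for seed in range(25):
            f1 = bko_fragment(random_bko(GeneratorConfig(seed=seed)), "s1", 1)
            f2 = bko_fragment(
                random_bko(GeneratorConfig(seed=seed + 500)), "s2", 2)
            fused = fuse_bkos([f1, f2])
            assert validate_bko(fused).valid, seed

    def test_three_way_fusion_validates(self):
        for seed in range(10):
            fragments = [
                bko_fragment(random_bko(GeneratorConfig(seed=seed + k * 300)),
                             f"s{k}", k + 1)
                for k in range(3)
            ]
            fused = fuse_bkos(fragments)
            assert validate_bko(fused).valid, seed
            priors = [r for r in fused.paas if not r.antecedent
                      and r.consequent.individual == SOURCE_INDIVIDUAL]
            assert sum(r.p for r in priors) == 1
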