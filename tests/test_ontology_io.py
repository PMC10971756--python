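"""Exchange round-trips, OBO/bridge ingestion, graph export."""

from fractions import Fraction

import networkx as nx
import pytest

from bkofusion import (
    Assertion,
    Atomic,
    Individual,
    LinkError,
    ParseError,
    RVAssignment,
    cpr,
    full_instantiate,
    fuse_bkos,
    paa,
    read_bridge,
    read_exchange,
    read_obo_subset,
    sciatic_fixture,
    to_digraph,
    validate_bko,
    write_exchange,
    write_graph,
)

OBO_TEXT = """format-version: 1.2

[Term]
id: MONDO:0001543
name: lesion of sciatic nerve
is_a: MONDO:0006960 ! sciatic neuropathy

[Term]
id: MONDO:0006960
name: sciatic neuropathy
is_a: MONDO:0001397 ! mononeuropathy

[Term]
id: MONDO:0002121
name: mononeuritis simplex
is_a: MONDO:0001397 ! mononeuropathy
is_a: MONDO:0002122 ! neuritis

[Term]
id: MONDO:0001397
name: mononeuropathy

[Term]
id: MONDO:0002122
name: neuritis
is_a: MONDO:0021166 ! inflammatory disease

[Term]
id: MONDO:0021166
name: inflammatory disease
"""


class TestExchangeRoundTrip:
    def test_fused_model_survives_read_write(self, sciatic, tmp_path):
        path = tmp_path / "fused.yaml"
        write_exchange(sciatic.fused, path, source="fused", weight=Fraction(1))
        loaded, source, weight = read_exchange(path)
        assert source == "fused" and weight == 1
        assert set(loaded.paas) == set(sciatic.fused.paas)
        assert set(loaded.ptas) == set(sciatic.fused.ptas)
        assert loaded.axioms.disjoint_pairs == sciatic.fused.axioms.disjoint_pairs
        assert loaded.lexicon.individuals == sciatic.fused.lexicon.individuals

    def test_probabilities_survive_bit_exactly(self, tmp_path):
        from bkofusion import BKO

        a = Individual("a")
        weights = ["0.35", "1/3", "0.1", "1"]
        rules = [paa((), Assertion(a, Atomic(f"C{i}")), w)
                 for i, w in enumerate(weights)]
        path = tmp_path / "probs.yaml"
        write_exchange(BKO(rules), path)
        loaded, _, _ = read_exchange(path)
        assert sorted(r.p for r in loaded.paas) == \
            sorted(Fraction(w) for w in weights)

    def test_empty_file_reads_as_empty_bko(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        bko, source, weight = read_exchange(path)
        assert len(bko) == 0 and source is None


class TestOboIngestion:
    def test_obo_terms_become_certainty_rules(self, tmp_path):
        path = tmp_path / "mondo.obo"
        path.write_text(OBO_TEXT)
        fragment = read_obo_subset(path, namespace="MONDO")
        assert len(fragment.bko.ptas) == 5
        assert all(t.p == 1 for t in fragment.bko.ptas)
        concluded = {t.consequent.concept.name for t in fragment.bko.ptas}
        assert "SciaticNeuropathy" in concluded or \
            "sciaticneuropathy" in {c.lower() for c in concluded}

    def test_tsv_edge_table(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("Lesion\tSciaticNeuropathy\n"
                        "SciaticNeuropathy\tMononeuropathy\n")
        fragment = read_obo_subset(path, namespace="DO")
        assert len(fragment.bko.ptas) == 2
        assert validate_bko(fragment.bko).valid

    def test_non_isa_relations_are_skipped(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tis_a\tB\nA\tpart_of\tC\n")
        fragment = read_obo_subset(path, namespace="X")
        assert len(fragment.bko.ptas) == 1

    def test_empty_file_gives_empty_fragment(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_obo_subset(path, namespace="X").bko.ptas) == 0

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\n")
        with pytest.raises(ParseError, match="bad.tsv:1"):
            read_obo_subset(path, namespace="X")

    def test_acyclic_import_validates_as_bko(self, tmp_path):
        path = tmp_path / "mondo.obo"
        path.write_text(OBO_TEXT)
        fragment = read_obo_subset(path, namespace="MONDO")
        assert validate_bko(fragment.bko).valid


class TestBridgeIngestion:
    def test_each_xref_becomes_two_directed_rules(self, tmp_path):
        path = tmp_path / "bridge.tsv"
        path.write_text(
            "MONDO:LesionofSciaticNerve\tDO:LesionofSciaticNerve\n"
            "MONDO:SciaticNeuropathy\tDO:SciaticNeuropathy\n"
            "MONDO:Mononeuropathy\tDO:Mononeuropathy\n"
            "MONDO:MononeuritisSimplex\tDO:Mononeuritis\n"
        )
        fragment = read_bridge(path)
        assert len(fragment.bko.ptas) == 8

    def test_single_direction_mode(self, tmp_path):
        path = tmp_path / "bridge.tsv"
        path.write_text("MONDO:X\tDO:Y\n")
        assert len(read_bridge(path, bidirectional=False).bko.ptas) == 1
        assert len(read_bridge(path, bidirectional=True).bko.ptas) == 2

    def test_self_reference_is_rejected(self, tmp_path):
        path = tmp_path / "bridge.tsv"
        path.write_text("MONDO:X\tMONDO:X\n")
        with pytest.raises(ParseError, match="self-reference"):
            read_bridge(path)

    def test_unknown_namespace_is_a_link_error(self, tmp_path):
        path = tmp_path / "bridge.tsv"
        path.write_text("MONDO:X\tHP:Y\n")
        with pytest.raises(LinkError, match="HP"):
            read_bridge(path, known_namespaces=["MONDO", "DO"])

    def test_ingested_fixture_matches_the_packaged_one(self, tmp_path):
        """Reading the worked example's tables reproduces the packaged
        fixture's bridge rules."""
        fragments, _, _ = sciatic_fixture()
        path = tmp_path / "bridge.tsv"
        path.write_text(
            "MONDO:LesionofSciaticNerve\tDO:LesionofSciaticNerve\n"
            "MONDO:SciaticNeuropathy\tDO:SciaticNeuropathy\n"
            "MONDO:Mononeuropathy\tDO:Mononeuropathy\n"
            "MONDO:MononeuritisSimplex\tDO:Mononeuritis\n"
        )
        ingested = read_bridge(path)
        want = {
            (next(iter(t.antecedent)).concept, t.consequent.concept)
            for t in fragments[2].bko.ptas
        }
        got = {
            (next(iter(t.antecedent)).concept, t.consequent.concept)
            for t in ingested.bko.ptas
        }
        assert got == want


class TestGraphExport:
    def test_single_rule_graph_shape(self, tmp_path):
        rule = cpr([RVAssignment("B", 5), RVAssignment("C", 12)],
                   RVAssignment("A", 2), "0.91")
        graph = to_digraph([rule])
        s_nodes = [n for n, d in graph.nodes(data=True) if d["kind"] == "S"]
        i_nodes = [n for n, d in graph.nodes(data=True) if d["kind"] == "I"]
        assert len(s_nodes) == 1 and len(i_nodes) == 3
        assert graph.number_of_edges() == 3
        assert graph.nodes[s_nodes[0]]["label"] == "0.91"

    def test_empty_model_gives_empty_graph(self):
        graph = to_digraph([])
        assert graph.number_of_nodes() == 0

    def test_fused_model_counts_match_the_rule_list(self, sciatic):
        graph = to_digraph(sciatic.full)
        s_nodes = [n for n, d in graph.nodes(data=True) if d["kind"] == "S"]
        assert len(s_nodes) == len(sciatic.full.paas)
        i_nodes = [n for n, d in graph.nodes(data=True) if d["kind"] == "I"]
        distinct_assertions = {
            assertion
            for r in sciatic.full.paas
            for assertion in list(r.antecedent) + [r.consequent]
        }
        assert len(i_nodes) == len(distinct_assertions)

    def test_dot_and_graphml_files(self, sciatic, tmp_path):
        dot = tmp_path / "model.dot"
        gml = tmp_path / "model.graphml"
        write_graph(sciatic.full, dot, "dot")
        write_graph(sciatic.full, gml, "graphml")
        text = dot.read_text()
        assert text.startswith("digraph") and "fillcolor=black" in text
        reread = nx.read_graphml(gml)
        assert reread.number_of_nodes() == to_digraph(sciatic.full).number_of_nodes()
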