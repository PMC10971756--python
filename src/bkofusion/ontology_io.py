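"""Readers and writers: OBO subsets, xref bridges, the YAML exchange
format, and I-node/S-node graph export.

The exchange format is a YAML (JSON-compatible) document holding the
lexicon, declared axioms, PAAs and PTAs, and fragment metadata.
Probabilities are stored as decimal/rational *strings* so weights survive
round trips bit-exactly; variable individuals are written with a leading
``?``; complements as ``not:``.

OBO parsing is deliberately minimal — id, name, namespace, is_a — with
obonet behind it; a full OBO 1.4 parser could be swapped in behind the
same interface.  Cross-reference tables become bidirectional equivalence
rules (one per direction), matching how bridge ontologies such as OxO
exports are used during fusion.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Tuple, Union

import networkx as nx
import yaml

from .bkb import BKB, CPR, RVAssignment
from .bko import (
    BKO,
    PAA,
    PTA,
    VariableAssertion,
    paa as make_paa,
    pta as make_pta,
)
from .bko_fusion import BKOFragment, bko_fragment
from .concepts import (
    Assertion,
    Atomic,
    AxiomStore,
    Complement,
    ConceptExpr,
    DomainLexicon,
    Individual,
    Intersection,
    RoleFiller,
    UnionExpr,
    VariableIndividual,
    complement,
)


class ParseError(ValueError):
    """Malformed input file; message carries position where known."""


class LinkError(ValueError):
    """A cross-reference points at an unregistered namespace."""


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: CURIE identifier, display name, namespace."""

    identifier: str
    common_name: str
    namespace: str

    @property
    def atomic(self) -> Atomic:
        return Atomic(self.common_name.replace(" ", ""), self.namespace,
                      self.identifier)


# ---------------------------------------------------------------------------
# Concept / assertion (de)serialization
# ---------------------------------------------------------------------------

def _term_to_obj(term) -> Union[str, Dict]:
    if isinstance(term, VariableIndividual):
        return f"?{term.name}"
    if term.namespace:
        return {"name": term.name, "namespace": term.namespace}
    return term.name


def _term_from_obj(obj) -> Union[Individual, VariableIndividual]:
    if isinstance(obj, str):
        if obj.startswith("?"):
            return VariableIndividual(obj[1:])
        return Individual(obj)
    return Individual(obj["name"], obj.get("namespace"))


def concept_to_obj(c: ConceptExpr) -> Dict:
    if isinstance(c, Complement):
        return {"not": concept_to_obj(c.inner)}
    if isinstance(c, Intersection):
        return {"all_of": [concept_to_obj(p) for p in sorted(c.parts)]}
    if isinstance(c, UnionExpr):
        return {"any_of": [concept_to_obj(p) for p in sorted(c.parts)]}
    if isinstance(c, RoleFiller):
        return {"role": c.role, "owner": _term_to_obj(c.owner),
                "filler": _term_to_obj(c.filler)}
    out: Dict = {"name": c.name}
    if c.namespace:
        out["namespace"] = c.namespace
    if c.identifier:
        out["identifier"] = c.identifier
    return out


def concept_from_obj(obj: Dict) -> ConceptExpr:
    if "not" in obj:
        return complement(concept_from_obj(obj["not"]))
    if "all_of" in obj:
        return Intersection(frozenset(concept_from_obj(p) for p in obj["all_of"]))
    if "any_of" in obj:
        return UnionExpr(frozenset(concept_from_obj(p) for p in obj["any_of"]))
    if "role" in obj:
        return RoleFiller(obj["role"], _term_from_obj(obj["owner"]),
                          _term_from_obj(obj["filler"]))
    return Atomic(obj["name"], obj.get("namespace"), obj.get("identifier"))


def _clause_to_obj(clause) -> Dict:
    if isinstance(clause, Assertion):
        return {"individual": _term_to_obj(clause.individual),
                "concept": concept_to_obj(clause.concept)}
    return {"var": f"?{clause.subject.name}",
            "concept": concept_to_obj(clause.concept)}


def _clause_from_obj(obj: Dict):
    concept = concept_from_obj(obj["concept"])
    if "var" in obj:
        name = obj["var"]
        return VariableAssertion(VariableIndividual(name.lstrip("?")), concept)
    term = _term_from_obj(obj["individual"])
    return Assertion(term, concept)


def _p_to_str(p: Optional[Fraction]) -> Optional[str]:
    if p is None:
        return None
    if p.denominator == 1:
        return str(p.numerator)
    # exact decimal when the denominator allows it, else a fraction string
    num, den = p.numerator, p.denominator
    d = den
    while d % 2 == 0:
        d //= 2
    while d % 5 == 0:
        d //= 5
    if d == 1:
        digits = max(len(str(den)) + 1, 1)
        text = f"{num / den:.{digits}f}".rstrip("0")
        if Fraction(text) == p:
            return text
    return f"{num}/{den}"


# ---------------------------------------------------------------------------
# Exchange documents
# ---------------------------------------------------------------------------

def bko_to_document(b: BKO, source: Optional[str] = None,
                    weight: Optional[Fraction] = None) -> Dict:
    doc: Dict = {}
    if source is not None:
        doc["fragment"] = {"source": source,
                           "weight": None if weight is None else _p_to_str(weight)}
    doc["individuals"] = [_term_to_obj(i) for i in sorted(b.lexicon.individuals)]
    doc["classes"] = [
        concept_to_obj(c) for c in sorted(b.lexicon.classes)
        if isinstance(c, Atomic) and c.name not in ("⊤", "⊥")
    ]
    doc["axioms"] = {
        "disjoint": [
            [concept_to_obj(c) for c in sorted(pair)]
            for pair in sorted(b.axioms.disjoint_pairs, key=lambda p: str(sorted(p)))
        ],
        "subsumption": [
            [concept_to_obj(sub), concept_to_obj(sup)]
            for sub, sup in sorted(b.axioms.subsumptions, key=str)
        ],
        "partitions": [
            [concept_to_obj(c) for c in sorted(part)]
            for part in b.axioms.partitions
        ],
    }
    doc["paas"] = [
        {
            "p": _p_to_str(r.p),
            "consequent": _clause_to_obj(r.consequent),
            "antecedent": [_clause_to_obj(a) for a in sorted(r.antecedent)],
            **({"source": r.source} if r.source else {}),
        }
        for r in b.paas
    ]
    doc["ptas"] = [
        {
            "id": t.pta_id,
            "p": _p_to_str(t.p),
            "consequent": _clause_to_obj(t.consequent),
            "antecedent": [_clause_to_obj(a) for a in sorted(t.antecedent, key=str)],
            **({"source": t.source} if t.source else {}),
        }
        for t in b.ptas
    ]
    return doc


def document_to_bko(doc: Dict) -> Tuple[BKO, Optional[str], Optional[Fraction]]:
    lexicon = DomainLexicon()
    for obj in doc.get("individuals", ()):
        term = _term_from_obj(obj)
        if isinstance(term, Individual):
            lexicon.register_individual(term)
    for obj in doc.get("classes", ()):
        lexicon.register_class(concept_from_obj(obj))
    axioms = AxiomStore()
    ax = doc.get("axioms", {}) or {}
    for c1, c2 in ax.get("disjoint", ()):
        axioms.declare_disjoint(concept_from_obj(c1), concept_from_obj(c2))
    for sub, sup in ax.get("subsumption", ()):
        axioms.declare_subsumption(concept_from_obj(sub), concept_from_obj(sup))
    for part in ax.get("partitions", ()):
        axioms.declare_partition(concept_from_obj(c) for c in part)
    paas = [
        make_paa(
            (_clause_from_obj(a) for a in obj.get("antecedent", ())),
            _clause_from_obj(obj["consequent"]),
            obj.get("p"),
            source=obj.get("source"),
        )
        for obj in doc.get("paas", ())
    ]
    ptas = [
        make_pta(
            (_clause_from_obj(a) for a in obj.get("antecedent", ())),
            _clause_from_obj(obj["consequent"]),
            obj.get("p"),
            pta_id=obj.get("id", ""),
            source=obj.get("source"),
        )
        for obj in doc.get("ptas", ())
    ]
    frag = doc.get("fragment") or {}
    weight = frag.get("weight")
    return (
        BKO(paas, ptas, lexicon, axioms),
        frag.get("source"),
        None if weight is None else Fraction(weight) if "/" in str(weight)
        else Fraction(str(weight)),
    )


def write_exchange(b: BKO, path: Union[str, os.PathLike],
                   source: Optional[str] = None,
                   weight: Optional[Fraction] = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(bko_to_document(b, source, weight), fh,
                       sort_keys=False, allow_unicode=True)


def read_exchange(path: Union[str, os.PathLike]
                  ) -> Tuple[BKO, Optional[str], Optional[Fraction]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return BKO(), None, None
    return document_to_bko(doc)


# ---------------------------------------------------------------------------
# Token-state BKBs (plain CPR sets) as JSON
# ---------------------------------------------------------------------------

def write_bkb_json(bkb: Union[BKB, Iterable[CPR]],
                   path: Union[str, os.PathLike]) -> None:
    """Plain CPR sets use a small JSON form: states are strings/ints,
    probabilities decimal strings."""
    import json

    rules = list(bkb)
    doc = {
        "rules": [
            {
                "p": _p_to_str(r.p),
                "consequent": {"rv": r.consequent.rv, "state": r.consequent.state},
                "antecedent": [{"rv": a.rv, "state": a.state}
                               for a in sorted(r.antecedent)],
                **({"source": r.source} if r.source else {}),
            }
            for r in sorted(rules)
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def read_bkb_json(path: Union[str, os.PathLike]) -> BKB:
    import json

    from .bkb import as_probability

    with open(path) as fh:
        doc = json.load(fh)
    rules = [
        CPR(
            frozenset(RVAssignment(a["rv"], a["state"])
                      for a in obj.get("antecedent", ())),
            RVAssignment(obj["consequent"]["rv"], obj["consequent"]["state"]),
            as_probability(obj.get("p")),
            obj.get("source"),
        )
        for obj in doc.get("rules", ())
    ]
    return BKB(rules)


# ---------------------------------------------------------------------------
# OBO subsets and xref bridges
# ---------------------------------------------------------------------------

_X = VariableIndividual("x")


def _subsumption_pta(child: Atomic, parent: Atomic, pta_id: str,
                     source: Optional[str]) -> PTA:
    return make_pta((VariableAssertion(_X, child),),
                    VariableAssertion(_X, parent), 1, pta_id=pta_id, source=source)


def read_obo_subset(path: Union[str, os.PathLike],
                    namespace: str,
                    relation_filter: str = "is_a",
                    weight: Fraction = Fraction(1)) -> BKOFragment:
    """A (subset of an) ontology as a BKO fragment of certainty rules.

    Accepts an OBO file (parsed with obonet) or a two-column
    child<TAB>parent table.  Each retained edge C→D becomes the rule
    P(x̂∈D | x̂∈C) = 1; terms register as atomics in ``namespace``; edges
    with other relations are skipped (their count is retained on the
    fragment's lexicon for logging by callers).
    """
    path = os.fspath(path)
    with open(path) as fh:
        text = fh.read()
    lexicon = DomainLexicon()
    ptas: List[PTA] = []
    skipped = 0
    if "[Term]" in text or text.startswith("format-version"):
        import obonet

        graph = obonet.read_obo(io.StringIO(text))
        names = {n: (data.get("name") or n) for n, data in graph.nodes(data=True)}
        atoms = {
            n: Atomic(names[n].replace(" ", ""), namespace, n) for n in graph.nodes
        }
        for atom in atoms.values():
            lexicon.register_class(atom)
        for idx, (child, parent, key) in enumerate(sorted(graph.edges(keys=True))):
            if key != relation_filter:
                skipped += 1
                continue
            ptas.append(_subsumption_pta(atoms[child], atoms[parent],
                                         f"{namespace}:{idx}", namespace))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3 and parts[1] != relation_filter:
                skipped += 1
                continue
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns")
            child, parent = parts[0], parts[-1]
            c = Atomic(child.replace(" ", ""), namespace)
            p = Atomic(parent.replace(" ", ""), namespace)
            lexicon.register_class(c)
            lexicon.register_class(p)
            ptas.append(_subsumption_pta(c, p, f"{namespace}:{lineno}", namespace))
    bko = BKO((), ptas, lexicon, AxiomStore())
    return bko_fragment(bko, namespace, weight)


def read_bridge(path: Union[str, os.PathLike],
                source: str = "BRIDGE",
                bidirectional: bool = True,
                known_namespaces: Optional[Iterable[str]] = None,
                weight: Fraction = Fraction(1)) -> BKOFragment:
    """A cross-reference table as a bridge fragment.

    Rows are ``namespace:Term<TAB>namespace:Term``.  Each xref becomes
    two certainty rules (one per direction), or one in single-direction
    mode.  Self-references are rejected, as is any namespace outside
    ``known_namespaces`` when that set is given.
    """
    known = set(known_namespaces) if known_namespaces is not None else None
    lexicon = DomainLexicon()
    ptas: List[PTA] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            atoms = []
            for cell in parts:
                if ":" not in cell:
                    raise ParseError(
                        f"{path}:{lineno}: terms must be namespace-qualified"
                    )
                ns, name = cell.split(":", 1)
                if known is not None and ns not in known:
                    raise LinkError(f"{path}:{lineno}: unknown namespace {ns!r}")
                atoms.append(Atomic(name.replace(" ", ""), ns))
            a, b = atoms
            if a == b:
                raise ParseError(f"{path}:{lineno}: self-reference {a}")
            lexicon.register_class(a)
            lexicon.register_class(b)
            ptas.append(_subsumption_pta(b, a, f"{source}:{lineno}a", source))
            if bidirectional:
                ptas.append(_subsumption_pta(a, b, f"{source}:{lineno}b", source))
    bko = BKO((), ptas, lexicon, AxiomStore())
    return bko_fragment(bko, source, weight)


# ---------------------------------------------------------------------------
# Graph export (I-nodes and S-nodes)
# ---------------------------------------------------------------------------

def to_digraph(obj: Union[BKB, BKO, Iterable]) -> nx.DiGraph:
    """The bipartite support-graph view: white I-nodes are rv
    instantiations (or assertions), black S-nodes are rules labelled with
    their weight; edges run antecedent → S-node → consequent."""
    if isinstance(obj, BKO):
        rules = list(obj.paas)
    elif isinstance(obj, BKB):
        rules = list(obj.rules)
    else:
        rules = list(obj)
    graph = nx.DiGraph()

    def inode(state) -> str:
        return str(state.state if isinstance(state, RVAssignment) else state)

    for rule in sorted(rules, key=str):
        if isinstance(rule, (CPR, PAA)):
            ant, con = sorted(rule.antecedent), rule.consequent
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot graph {type(rule).__name__}")
        s_id = f"s:{rule.rule_id}" if isinstance(rule, CPR) else f"s:{rule}"
        label = "?" if rule.p is None else _p_to_str(rule.p)
        sourced = getattr(rule, "source", None)
        graph.add_node(s_id, kind="S", label=str(label),
                       source=str(sourced or ""))
        for a in ant:
            node = inode(a) if isinstance(a, RVAssignment) else str(a)
            graph.add_node(node, kind="I", label=node, source="")
            graph.add_edge(node, s_id)
        con_node = inode(con) if isinstance(con, RVAssignment) else str(con)
        graph.add_node(con_node, kind="I", label=con_node, source="")
        graph.add_edge(s_id, con_node)
    return graph


def write_graph(obj: Union[BKB, BKO], path: Union[str, os.PathLike],
                fmt: str = "dot") -> None:
    """Emit the support graph as DOT or GraphML.

    S-nodes are filled black and carry the weight label; nodes derived
    from source fragments carry a ``source`` attribute (rendered as a
    colored edge style in DOT) approximating the usual blue-edge
    convention for bridge knowledge.
    """
    graph = to_digraph(obj)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    if fmt != "dot":
        raise ValueError(f"unsupported graph format: {fmt}")
    lines = ["digraph bkb {", "  rankdir=LR;"]
    ids = {node: f"n{i}" for i, node in enumerate(sorted(graph.nodes))}
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        if data["kind"] == "S":
            attrs = (f'shape=circle, style=filled, fillcolor=black, '
                     f'fontcolor=white, label="{data["label"]}"')
        else:
            attrs = f'shape=ellipse, label="{data["label"]}"'
        if data.get("source"):
            attrs += f', color=blue, source="{data["source"]}"'
        lines.append(f"  {ids[node]} [{attrs}];")
    for u, v in sorted(graph.edges):
        lines.append(f"  {ids[u]} -> {ids[v]};")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
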