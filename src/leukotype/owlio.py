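"""OWL serialization of the knowledge base and ontology-file statistics.

The primary dialect is OWL functional-style syntax: line-oriented,
diff-friendly, and written in a fully deterministic order so two exports of
the same knowledge base are byte-identical.  A restricted reader parses the
fragment this writer emits (declarations, annotation assertions, subclass
and equivalence axioms over intersections/unions of existential
restrictions), which is enough for round-trip checks and statistics.
RDF/XML is accepted on input for statistics only.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .kb import (
    KnowledgeBase,
    RelationVocabulary,
    UnsupportedRelationError,
)
from .model import (
    CellClassDefinition,
    ExpressionStatus,
    Location,
    Marker,
    MarkerLiteral,
    Phenotype,
)

__all__ = [
    "OwlRenderPlan",
    "OntologyStats",
    "OwlParseError",
    "render_class_axioms",
    "export_ontology",
    "parse_functional",
    "kb_from_ontology",
    "load_ontology_stats",
]

_RDFS = "http://www.w3.org/2000/01/rdf-schema#"
_OWL = "http://www.w3.org/2002/07/owl#"
_RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_XSD = "http://www.w3.org/2001/XMLSchema#"
_OBO = "http://purl.obolibrary.org/obo/"

LABEL_IRI = _RDFS + "label"
COMMENT_IRI = _RDFS + "comment"
DEFINITION_IRI = _OBO + "IAO_0000115"

_DEFAULT_PREFIX = "https://w3id.org/leukotype/LKT_"

_DEFAULT_RELATION_IRIS: Dict[str, str] = {
    "has_plasma_membrane_part": _OBO + "RO_0002104",
    "lacks_plasma_membrane_part": _OBO + "cl#lacks_plasma_membrane_part",
    "has_high_plasma_membrane_amount": _OBO + "cl#has_high_plasma_membrane_amount",
    "has_low_plasma_membrane_amount": _OBO + "cl#has_low_plasma_membrane_amount",
    "lacks_part": _OBO + "cl#lacks_part",
    # the two cytoplasmic relations are new, hence minted natively
    "has_cytoplasm_part": _DEFAULT_PREFIX + "has_cytoplasm_part",
    "lacks_cytoplasm_part": _DEFAULT_PREFIX + "lacks_cytoplasm_part",
}


class OwlParseError(ValueError):
    pass


@dataclass
class OwlRenderPlan:
    """How to mint IRIs and annotate entities on export.

    Class IRIs are zero-padded numeric ids in knowledge-base order; marker
    IRIs continue the numbering, sorted by marker label, so an unchanged KB
    always re-exports identically.
    """

    iri_prefix: str = _DEFAULT_PREFIX
    ontology_iri: str = "https://w3id.org/leukotype/leukotype.owl"
    id_width: int = 7
    relation_iris: Dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_RELATION_IRIS)
    )
    class_iris: Dict[str, str] = field(default_factory=dict)
    marker_iris: Dict[str, str] = field(default_factory=dict)

    def mint_for(self, kb: KnowledgeBase) -> "OwlRenderPlan":
        """Assign stable numeric IRIs for the KB's classes and used markers."""
        self.class_iris = {}
        counter = 0
        for cid in kb.classes:
            counter += 1
            self.class_iris[cid] = f"{self.iri_prefix}{counter:0{self.id_width}d}"
        used: Dict[str, Marker] = {}
        for definition in kb.classes.values():
            for literal in definition.differentia.literals():
                used[literal.marker.id] = literal.marker
        self.marker_iris = {}
        for marker in sorted(used.values(), key=lambda m: m.label.casefold()):
            counter += 1
            self.marker_iris[marker.id] = f"{self.iri_prefix}{counter:0{self.id_width}d}"
        return self


@dataclass(frozen=True)
class OntologyStats:
    """Named-class and axiom counts for one ontology file."""

    total_class_count: int
    native_class_count: int
    imported_class_count: int
    relation_count: int
    axiom_counts: Tuple[Tuple[str, int], ...]
    import_iris: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.total_class_count != self.native_class_count + self.imported_class_count:
            raise ValueError("total must equal native + imported")

    @property
    def axiom_count_map(self) -> Dict[str, int]:
        return dict(self.axiom_counts)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _annotation(prop_iri: str, subject_iri: str, value: str) -> str:
    return f'AnnotationAssertion(<{prop_iri}> <{subject_iri}> "{_escape(value)}")'


def _restriction(literal: MarkerLiteral, plan: OwlRenderPlan, vocab: RelationVocabulary) -> str:
    relation = vocab.relation_for(literal.location, literal.status)
    try:
        relation_iri = plan.relation_iris[relation]
    except KeyError:
        raise UnsupportedRelationError(f"no IRI mapped for relation {relation!r}") from None
    marker_iri = plan.marker_iris[literal.marker.id]
    return f"ObjectSomeValuesFrom(<{relation_iri}> <{marker_iri}>)"


def _clause_expr(clause: Sequence[MarkerLiteral], plan: OwlRenderPlan, vocab: RelationVocabulary) -> str:
    parts = [_restriction(lit, plan, vocab) for lit in clause]
    if len(parts) == 1:
        return parts[0]
    return "ObjectUnionOf(" + " ".join(parts) + ")"


def _serialize_phenotype(phenotype: Phenotype) -> str:
    return " && ".join(
        " || ".join(
            f"{lit.marker.label}|{lit.location.value}|{lit.status.value}"
            for lit in clause
        )
        for clause in phenotype.clauses
    )


def render_class_axioms(
    definition: CellClassDefinition,
    plan: OwlRenderPlan,
    kb: KnowledgeBase,
) -> List[str]:
    """Functional-syntax axiom strings (annotations + logic) for one class."""
    from .kb import render_textual_definition

    iri = plan.class_iris[definition.id]
    axioms = [_annotation(LABEL_IRI, iri, definition.label)]
    axioms.append(
        _annotation(DEFINITION_IRI, iri, render_textual_definition(definition.id, kb))
    )
    if definition.lineage_text:
        axioms.append(_annotation(COMMENT_IRI, iri, f"lineage_text: {definition.lineage_text}"))
    if definition.typical_profile is not None:
        axioms.append(
            _annotation(
                COMMENT_IRI,
                iri,
                f"typical_profile: {_serialize_phenotype(definition.typical_profile)}",
            )
        )
    if definition.genus is None:
        return axioms
    genus_iri = plan.class_iris[definition.genus]
    if definition.differentia.is_trivial:
        axioms.append(f"SubClassOf(<{iri}> <{genus_iri}>)")
        return axioms
    clause_exprs = [
        _clause_expr(clause, plan, kb.relations)
        for clause in definition.differentia.clauses
    ]
    expr = "ObjectIntersectionOf(" + " ".join([f"<{genus_iri}>"] + clause_exprs) + ")"
    if definition.defining:
        axioms.append(f"EquivalentClasses(<{iri}> {expr})")
    else:
        axioms.append(f"SubClassOf(<{iri}> {expr})")
    return axioms


def _used_relations(kb: KnowledgeBase) -> List[str]:
    names = set()
    for definition in kb.classes.values():
        for literal in definition.differentia.literals():
            names.add(kb.relations.relation_for(literal.location, literal.status))
    return sorted(names)


def ontology_document(kb: KnowledgeBase, plan: Optional[OwlRenderPlan] = None) -> str:
    """Serialize the KB to one deterministic functional-syntax document."""
    if plan is None:
        plan = OwlRenderPlan()
    if not plan.class_iris:
        plan.mint_for(kb)
    lines = [
        f"Prefix(owl:=<{_OWL}>)",
        f"Prefix(rdf:=<{_RDF}>)",
        f"Prefix(rdfs:=<{_RDFS}>)",
        f"Prefix(xsd:=<{_XSD}>)",
        f"Ontology(<{plan.ontology_iri}>",
    ]
    relations = _used_relations(kb)
    relation_iris = {name: plan.relation_iris[name] for name in relations}
    for name in sorted(relations, key=lambda n: relation_iris[n]):
        lines.append(f"Declaration(ObjectProperty(<{relation_iris[name]}>))")
    for cid in kb.classes:
        lines.append(f"Declaration(Class(<{plan.class_iris[cid]}>))")
    for name in sorted(relations, key=lambda n: relation_iris[n]):
        lines.append(_annotation(LABEL_IRI, relation_iris[name], name))
    for marker_id, iri in plan.marker_iris.items():
        lines.append(_annotation(LABEL_IRI, iri, kb.markers[marker_id].label))
    for definition in kb.classes.values():
        lines.extend(render_class_axioms(definition, plan, kb))
    lines.append(")")
    return "\n".join(lines) + "\n"


def export_ontology(
    kb: KnowledgeBase,
    plan: Optional[OwlRenderPlan] = None,
    path: Union[str, Path, None] = None,
) -> OntologyStats:
    """Write the KB as OWL functional syntax and return stats of the output."""
    if plan is None:
        plan = OwlRenderPlan()
    document = ontology_document(kb, plan)
    if path is not None:
        Path(path).write_text(document, encoding="utf-8")
    return _stats_from_functional(document, native_prefix=plan.iri_prefix)


# ---------------------------------------------------------------------------
# Parsing (restricted functional syntax)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r'<[^>]*>|"(?:[^"\\]|\\.)*"|\(|\)|[^\s()"<>]+')


def _tokenize(text: str) -> List[str]:
    return _TOKEN_RE.findall(text)


class _Node:
    __slots__ = ("head", "children")

    def __init__(self, head: str, children: List[object]):
        self.head = head
        self.children = children


def _parse_forms(tokens: List[str], pos: int, stop_at_close: bool) -> Tuple[List[object], int]:
    forms: List[object] = []
    n = len(tokens)
    while pos < n:
        token = tokens[pos]
        if token == ")":
            if stop_at_close:
                return forms, pos + 1
            raise OwlParseError("unbalanced ')'")
        if pos + 1 < n and tokens[pos + 1] == "(":
            children, pos = _parse_forms(tokens, pos + 2, True)
            forms.append(_Node(token, children))
            continue
        forms.append(token)
        pos += 1
    if stop_at_close:
        raise OwlParseError("unexpected end of input")
    return forms, pos


def parse_functional(text: str) -> List[_Node]:
    """Parse functional-syntax text into axiom nodes (ontology body)."""
    forms, _ = _parse_forms(_tokenize(text), 0, False)
    axioms: List[_Node] = []
    for form in forms:
        if isinstance(form, _Node) and form.head == "Prefix":
            continue
        if isinstance(form, _Node) and form.head == "Ontology":
            axioms.extend(c for c in form.children if isinstance(c, _Node))
        elif isinstance(form, _Node):
            axioms.append(form)
    return axioms


def _iri(token: object) -> str:
    if isinstance(token, str) and token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    raise OwlParseError(f"expected an IRI, got {token!r}")


def _string(token: object) -> str:
    if isinstance(token, str) and token.startswith('"'):
        return token[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    raise OwlParseError(f"expected a string literal, got {token!r}")


def _parse_comment_phenotype(text: str, markers_by_label: Dict[str, Marker]) -> Phenotype:
    clauses = []
    for clause_text in text.split(" && "):
        literals = []
        for lit_text in clause_text.split(" || "):
            label, loc, status = lit_text.rsplit("|", 2)
            marker = markers_by_label.setdefault(label, Marker(id=label, label=label))
            literals.append(
                MarkerLiteral(
                    marker=marker,
                    location=Location(loc),
                    status=ExpressionStatus(status),
                )
            )
        clauses.append(literals)
    return Phenotype.from_clauses(clauses)


def kb_from_ontology(
    source: Union[str, Path],
    plan: Optional[OwlRenderPlan] = None,
) -> KnowledgeBase:
    """Reconstruct a KnowledgeBase from an exported functional-syntax file.

    Class ids become the IRI local names; marker identity is recovered from
    label annotations, so re-exporting the result with an equivalent plan
    reproduces the input byte for byte.
    """
    if plan is None:
        plan = OwlRenderPlan()
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text(encoding="utf-8")
    axioms = parse_functional(text)

    relation_by_iri = {iri: name for name, iri in plan.relation_iris.items()}
    pair_by_relation: Dict[str, Tuple[Location, ExpressionStatus]] = {
        name: pair for pair, name in RelationVocabulary().mapping
    }

    class_order: List[str] = []
    labels: Dict[str, str] = {}
    definitions_text: Dict[str, str] = {}
    comments: Dict[str, List[str]] = {}
    logical: Dict[str, _Node] = {}
    prefix = plan.iri_prefix

    def local(iri: str) -> str:
        return iri[len(prefix):] if iri.startswith(prefix) else iri

    for node in axioms:
        if node.head == "Declaration":
            inner = node.children[0]
            if isinstance(inner, _Node) and inner.head == "Class":
                class_order.append(_iri(inner.children[0]))
        elif node.head == "AnnotationAssertion":
            prop = _iri(node.children[0])
            subject = _iri(node.children[1])
            value = _string(node.children[2])
            if prop == LABEL_IRI:
                labels[subject] = value
            elif prop == DEFINITION_IRI:
                definitions_text[subject] = value
            elif prop == COMMENT_IRI:
                comments.setdefault(subject, []).append(value)
        elif node.head in ("SubClassOf", "EquivalentClasses"):
            logical[_iri(node.children[0])] = node

    class_ids = {iri: local(iri) for iri in class_order}
    markers_by_label: Dict[str, Marker] = {}

    def literal_from_restriction(node: _Node) -> MarkerLiteral:
        relation_iri = _iri(node.children[0])
        marker_iri = _iri(node.children[1])
        name = relation_by_iri.get(relation_iri) or labels.get(relation_iri)
        if name is None or name not in pair_by_relation:
            raise OwlParseError(f"unknown relation IRI {relation_iri!r}")
        location, status = pair_by_relation[name]
        label = labels.get(marker_iri, local(marker_iri))
        marker = markers_by_label.setdefault(label, Marker(id=label, label=label))
        return MarkerLiteral(marker=marker, location=location, status=status)

    kb = KnowledgeBase()
    kb.metadata = {"name": "ontology-import", "version": "0", "provenance": ""}

    for iri in class_order:
        cid = class_ids[iri]
        genus: Optional[str] = None
        differentia = Phenotype.trivial()
        defining = False
        node = logical.get(iri)
        if node is not None:
            target = node.children[1]
            defining = node.head == "EquivalentClasses"
            if isinstance(target, _Node) and target.head == "ObjectIntersectionOf":
                clauses: List[List[MarkerLiteral]] = []
                for operand in target.children:
                    if not isinstance(operand, _Node):
                        genus = class_ids.get(_iri(operand), local(_iri(operand)))
                    elif operand.head == "ObjectUnionOf":
                        clauses.append([literal_from_restriction(r) for r in operand.children])
                    elif operand.head == "ObjectSomeValuesFrom":
                        clauses.append([literal_from_restriction(operand)])
                    else:
                        raise OwlParseError(f"unexpected operand {operand.head!r}")
                differentia = Phenotype.from_clauses(clauses)
            else:
                genus = class_ids.get(_iri(target), local(_iri(target)))
                defining = False
        typical = None
        lineage = None
        for comment in comments.get(iri, []):
            if comment.startswith("lineage_text: "):
                lineage = comment[len("lineage_text: "):]
            elif comment.startswith("typical_profile: "):
                typical = _parse_comment_phenotype(
                    comment[len("typical_profile: "):], markers_by_label
                )
        kb.classes[cid] = CellClassDefinition(
            id=cid,
            label=labels.get(iri, cid),
            genus=genus,
            differentia=differentia,
            defining=defining,
            typical_profile=typical,
            lineage_text=lineage,
            textual_definition=definitions_text.get(iri),
        )
        if genus is None:
            kb.roots.append(cid)

    for marker in sorted(markers_by_label.values(), key=lambda m: m.label.casefold()):
        kb.markers[marker.id] = marker
    return kb


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _stats_from_functional(text: str, native_prefix: str) -> OntologyStats:
    axiom_counts: Dict[str, int] = {}
    classes = set()
    relations = set()
    imports: List[str] = []
    for node in parse_functional(text):
        axiom_counts[node.head] = axiom_counts.get(node.head, 0) + 1
        if node.head == "Declaration":
            inner = node.children[0]
            if isinstance(inner, _Node):
                if inner.head == "Class":
                    classes.add(_iri(inner.children[0]))
                elif inner.head == "ObjectProperty":
                    relations.add(_iri(inner.children[0]))
        elif node.head == "Import":
            imports.append(_iri(node.children[0]))
    native = sum(1 for iri in classes if iri.startswith(native_prefix))
    return OntologyStats(
        total_class_count=len(classes),
        native_class_count=native,
        imported_class_count=len(classes) - native,
        relation_count=len(relations),
        axiom_counts=tuple(sorted(axiom_counts.items())),
        import_iris=tuple(imports),
    )


def _stats_from_rdfxml(text: str, native_prefix: str) -> OntologyStats:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise OwlParseError(f"not parseable as RDF/XML: {exc}") from exc
    about = "{%s}about" % _RDF
    resource = "{%s}resource" % _RDF
    classes = set()
    relations = set()
    imports: List[str] = []
    axiom_counts: Dict[str, int] = {}
    for element in root.iter():
        tag = element.tag
        if tag == "{%s}Class" % _OWL and element.get(about):
            classes.add(element.get(about))
        elif tag == "{%s}ObjectProperty" % _OWL and element.get(about):
            relations.add(element.get(about))
        elif tag == "{%s}imports" % _OWL and element.get(resource):
            imports.append(element.get(resource))
        short = tag.rsplit("}", 1)[-1]
        axiom_counts[short] = axiom_counts.get(short, 0) + 1
    native = sum(1 for iri in classes if iri.startswith(native_prefix))
    return OntologyStats(
        total_class_count=len(classes),
        native_class_count=native,
        imported_class_count=len(classes) - native,
        relation_count=len(relations),
        axiom_counts=tuple(sorted(axiom_counts.items())),
        import_iris=tuple(imports),
    )


def load_ontology_stats(
    path: Union[str, Path],
    native_prefix: str,
    on_imports: str = "local",
) -> OntologyStats:
    """Count named classes and relations in an ontology file.

    Native vs imported classes are split by IRI prefix.  Import closures are
    never resolved over the network: with ``on_imports="local"`` (default)
    counts cover the local file only and import IRIs are reported in the
    stats; with ``on_imports="fail"`` any import directive raises.
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith(("Prefix(", "Ontology(")):
        stats = _stats_from_functional(text, native_prefix)
    else:
        stats = _stats_from_rdfxml(text, native_prefix)
    if on_imports == "fail" and stats.import_iris:
        raise OwlParseError(
            f"unresolved imports: {', '.join(stats.import_iris)}"
        )
    return stats
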