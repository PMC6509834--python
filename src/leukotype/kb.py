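"""Knowledge base of cell-class definitions.

Loads/saves the structured-text (YAML) KB format, ships a built-in encoding
of the EGIL acute-leukemia classification scheme, validates content, and
renders deterministic textual definitions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .model import (
    CellClassDefinition,
    ExpressionStatus,
    GenusCycleError,
    Location,
    Marker,
    MarkerLiteral,
    Phenotype,
    UnknownClassError,
    expand_definition,
    normalize_marker_label,
    _norm_key,
)

__all__ = [
    "RelationVocabulary",
    "UnsupportedRelationError",
    "KnowledgeBase",
    "Finding",
    "KBSchemaError",
    "KBValidationError",
    "builtin_egil_kb",
    "load_kb",
    "loads_kb",
    "save_kb",
    "dumps_kb",
    "validate_kb",
    "render_textual_definition",
]

BUILTIN_KB_RESOURCE = "egil_table1.yaml"


class UnsupportedRelationError(ValueError):
    """No relation exists for the given (location, status) pair."""


_DEFAULT_RELATIONS: Dict[Tuple[Location, ExpressionStatus], str] = {
    (Location.SURFACE, ExpressionStatus.PRESENT): "has_plasma_membrane_part",
    (Location.SURFACE, ExpressionStatus.ABSENT): "lacks_plasma_membrane_part",
    (Location.SURFACE, ExpressionStatus.HIGH): "has_high_plasma_membrane_amount",
    (Location.SURFACE, ExpressionStatus.LOW): "has_low_plasma_membrane_amount",
    (Location.CYTOPLASMIC, ExpressionStatus.PRESENT): "has_cytoplasm_part",
    (Location.CYTOPLASMIC, ExpressionStatus.ABSENT): "lacks_cytoplasm_part",
}


@dataclass(frozen=True)
class RelationVocabulary:
    """Maps (location, status) pairs to relation names.

    The vocabulary also carries the generic absence relation ``lacks_part``;
    (cytoplasmic, high) and (cytoplasmic, low) have no relation and raise
    :class:`UnsupportedRelationError`.
    """

    mapping: Tuple[Tuple[Tuple[Location, ExpressionStatus], str], ...] = tuple(
        _DEFAULT_RELATIONS.items()
    )
    generic_absence: str = "lacks_part"

    def relation_for(self, location: Location, status: ExpressionStatus) -> str:
        for (loc, st), name in self.mapping:
            if loc is location and st is status:
                return name
        raise UnsupportedRelationError(
            f"no relation for ({location.value}, {status.value})"
        )

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(name for _, name in self.mapping) + (self.generic_absence,)


class KBSchemaError(ValueError):
    """The KB document violates the schema (with record context)."""


class KBValidationError(ValueError):
    def __init__(self, findings: Sequence["Finding"]):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in findings)
        super().__init__(f"knowledge base failed validation: {lines}")


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    code: str
    severity: str
    subject: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.code} ({self.subject}): {self.message}"


@dataclass
class KnowledgeBase:
    """Cell-class definitions plus the marker dictionary and relations."""

    classes: Dict[str, CellClassDefinition] = field(default_factory=dict)
    markers: Dict[str, Marker] = field(default_factory=dict)
    relations: RelationVocabulary = field(default_factory=RelationVocabulary)
    roots: List[str] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._marker_index: Optional[Dict[str, Marker]] = None
        self._caches: Dict[str, object] = {}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.markers == other.markers
            and self.relations == other.relations
            and self.roots == other.roots
            and self.metadata == other.metadata
        )

    # -- caches ------------------------------------------------------------
    def invalidate_caches(self) -> None:
        self._marker_index = None
        self._caches.clear()

    def cache(self, key: str, compute):
        """Memoize derived structures (expansions, closures) on the KB."""
        if key not in self._caches:
            self._caches[key] = compute()
        return self._caches[key]

    def marker_index(self) -> Dict[str, Marker]:
        if self._marker_index is None:
            index: Dict[str, Marker] = {}
            for marker in self.markers.values():
                for name in (marker.label, *marker.synonyms):
                    key = _norm_key(name)
                    existing = index.get(key)
                    if existing is not None and existing is not marker:
                        raise KBSchemaError(
                            f"marker name {name!r} maps to both "
                            f"{existing.label!r} and {marker.label!r}"
                        )
                    index[key] = marker
            self._marker_index = index
        return self._marker_index

    # -- convenience -------------------------------------------------------
    def resolve_marker(self, raw: str) -> Marker:
        return normalize_marker_label(raw, self)

    def expand(self, class_id: str) -> Phenotype:
        expansions = self.cache("expansions", dict)
        if class_id not in expansions:
            expansions[class_id] = expand_definition(class_id, self)
        return expansions[class_id]

    def genus_chain(self, class_id: str) -> List[str]:
        """Class id followed by its genus chain up to a root."""
        if class_id not in self.classes:
            raise UnknownClassError(class_id)
        chain: List[str] = []
        current: Optional[str] = class_id
        while current is not None:
            if current in chain:
                raise GenusCycleError(" -> ".join(chain + [current]))
            chain.append(current)
            definition = self.classes.get(current)
            if definition is None:
                raise UnknownClassError(current)
            current = definition.genus
        return chain

    def asserted_ancestors(self, class_id: str) -> frozenset:
        return frozenset(self.genus_chain(class_id)[1:])

    def defining_ids(self) -> List[str]:
        return [cid for cid, d in self.classes.items() if d.defining]

    def add_class(self, definition: CellClassDefinition) -> None:
        """Extension point: register an additional class definition."""
        if definition.id in self.classes:
            raise KBSchemaError(f"duplicate class id {definition.id!r}")
        if definition.genus is not None and definition.genus not in self.classes:
            raise KBSchemaError(
                f"class {definition.id!r}: dangling genus {definition.genus!r}"
            )
        self.classes[definition.id] = definition
        self.invalidate_caches()


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

_LOCATION_TOKENS = {loc.value: loc for loc in Location}
_STATUS_TOKENS = {st.value: st for st in ExpressionStatus}


def _parse_marker_record(record: Mapping, index: int) -> Marker:
    if not isinstance(record, Mapping) or "id" not in record or "label" not in record:
        raise KBSchemaError(f"markers[{index}]: expected a mapping with id and label")
    synonyms = tuple(str(s) for s in record.get("synonyms") or ())
    return Marker(
        id=str(record["id"]),
        label=str(record["label"]),
        synonyms=synonyms,
        external_ref=record.get("external_ref"),
        display=record.get("display"),
    )


def _parse_clauses(
    raw: object, kb: KnowledgeBase, vocab: RelationVocabulary, context: str
) -> Phenotype:
    if raw is None:
        return Phenotype.trivial()
    if not isinstance(raw, list):
        raise KBSchemaError(f"{context}: clauses must be a list of clauses")
    clauses: List[List[MarkerLiteral]] = []
    for ci, clause in enumerate(raw):
        if not isinstance(clause, list) or not clause:
            raise KBSchemaError(f"{context}: clause {ci} must be a non-empty list")
        literals: List[MarkerLiteral] = []
        for li, triple in enumerate(clause):
            if not isinstance(triple, list) or len(triple) != 3:
                raise KBSchemaError(
                    f"{context}: clause {ci} literal {li} must be "
                    "[marker, location, status]"
                )
            raw_marker, raw_loc, raw_status = triple
            marker = normalize_marker_label(str(raw_marker), kb)
            location = _LOCATION_TOKENS.get(str(raw_loc).strip().casefold())
            if location is None:
                raise KBSchemaError(f"{context}: unknown location {raw_loc!r}")
            status = _STATUS_TOKENS.get(str(raw_status).strip().casefold())
            if status is None:
                raise KBSchemaError(f"{context}: unknown status {raw_status!r}")
            try:
                vocab.relation_for(location, status)
            except UnsupportedRelationError as exc:
                raise KBSchemaError(f"{context}: {exc}") from None
            literals.append(MarkerLiteral(marker=marker, location=location, status=status))
        clauses.append(literals)
    return Phenotype.from_clauses(clauses)


def loads_kb(text: str, strict: bool = True) -> KnowledgeBase:
    """Parse a KB document from its YAML text. See :func:`load_kb`."""
    document = yaml.safe_load(text)
    if not isinstance(document, Mapping):
        raise KBSchemaError("KB document must be a mapping")

    kb = KnowledgeBase()
    kb.metadata = {
        "name": document.get("name", "unnamed"),
        "version": str(document.get("version", "0")),
        "provenance": document.get("provenance", ""),
    }
    if document.get("stage_precedence"):
        kb.metadata["stage_precedence"] = [
            [str(c) for c in chain] for chain in document["stage_precedence"]
        ]
    kb.roots = [str(r) for r in document.get("roots") or []]

    for index, record in enumerate(document.get("markers") or []):
        marker = _parse_marker_record(record, index)
        if marker.id in kb.markers:
            raise KBSchemaError(f"markers[{index}]: duplicate marker id {marker.id!r}")
        kb.markers[marker.id] = marker
    kb.marker_index()  # force label/synonym uniqueness check

    records = document.get("classes") or []
    for index, record in enumerate(records):
        if not isinstance(record, Mapping) or "id" not in record:
            raise KBSchemaError(f"classes[{index}]: expected a mapping with an id")
        cid = str(record["id"])
        context = f"classes[{index}] ({cid})"
        if cid in kb.classes:
            raise KBSchemaError(f"{context}: duplicate class id")
        genus = record.get("genus")
        genus = None if genus is None else str(genus)
        differentia = _parse_clauses(record.get("clauses"), kb, kb.relations, context)
        typical = record.get("typical_profile")
        typical_profile = (
            None
            if typical is None
            else _parse_clauses(typical, kb, kb.relations, f"{context} typical_profile")
        )
        defining = bool(record.get("defining", True))
        if defining and differentia.is_trivial:
            raise KBSchemaError(f"{context}: defining class needs a non-empty differentia")
        kb.classes[cid] = CellClassDefinition(
            id=cid,
            label=str(record.get("label", cid)),
            genus=genus,
            differentia=differentia,
            defining=defining,
            typical_profile=typical_profile,
            lineage_text=record.get("lineage_text"),
            textual_definition=record.get("textual_definition"),
        )

    # referential checks with record context
    for index, (cid, definition) in enumerate(kb.classes.items()):
        if definition.genus is not None and definition.genus not in kb.classes:
            raise KBSchemaError(
                f"classes[{index}] ({cid}): dangling genus {definition.genus!r}"
            )
        if definition.genus is None and cid not in kb.roots:
            raise KBSchemaError(
                f"classes[{index}] ({cid}): has no genus but is not a declared root"
            )
    for cid in kb.classes:
        kb.genus_chain(cid)  # raises GenusCycleError on cycles

    findings = validate_kb(kb)
    errors = [f for f in findings if f.severity == "error"]
    if strict and errors:
        raise KBValidationError(errors)
    return kb


def load_kb(path: Union[str, Path, io.TextIOBase], strict: bool = True) -> KnowledgeBase:
    """Load and validate a KB file (structured YAML text).

    With ``strict`` (the default) any error-severity validation finding
    raises :class:`KBValidationError`; schema problems raise
    :class:`KBSchemaError` with record context.
    """
    if hasattr(path, "read"):
        return loads_kb(path.read(), strict=strict)
    return loads_kb(Path(path).read_text(encoding="utf-8"), strict=strict)


def _phenotype_to_lists(phenotype: Phenotype) -> List[List[List[str]]]:
    return [
        [[lit.marker.label, lit.location.value, lit.status.value] for lit in clause]
        for clause in phenotype.clauses
    ]


def dumps_kb(kb: KnowledgeBase) -> str:
    """Serialize a KB back to its YAML document form (deterministic)."""
    document: Dict[str, object] = {
        "name": kb.metadata.get("name", "unnamed"),
        "version": kb.metadata.get("version", "0"),
        "provenance": kb.metadata.get("provenance", ""),
        "roots": list(kb.roots),
    }
    if kb.metadata.get("stage_precedence"):
        document["stage_precedence"] = kb.metadata["stage_precedence"]
    markers = []
    for marker in kb.markers.values():
        record: Dict[str, object] = {"id": marker.id, "label": marker.label}
        if marker.synonyms:
            record["synonyms"] = list(marker.synonyms)
        if marker.display:
            record["display"] = marker.display
        if marker.external_ref:
            record["external_ref"] = marker.external_ref
        markers.append(record)
    document["markers"] = markers
    classes = []
    for definition in kb.classes.values():
        record = {
            "id": definition.id,
            "label": definition.label,
            "genus": definition.genus,
            "defining": definition.defining,
        }
        if not definition.differentia.is_trivial:
            record["clauses"] = _phenotype_to_lists(definition.differentia)
        if definition.typical_profile is not None:
            record["typical_profile"] = _phenotype_to_lists(definition.typical_profile)
        if definition.lineage_text:
            record["lineage_text"] = definition.lineage_text
        if definition.textual_definition:
            record["textual_definition"] = definition.textual_definition
        classes.append(record)
    document["classes"] = classes
    return yaml.safe_dump(document, sort_keys=False, allow_unicode=True, width=100)


def save_kb(kb: KnowledgeBase, path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_kb(kb), encoding="utf-8")


@lru_cache(maxsize=1)
def _builtin_text() -> str:
    return (
        resources.files("leukotype.data")
        .joinpath(BUILTIN_KB_RESOURCE)
        .read_text(encoding="utf-8")
    )


def builtin_egil_kb() -> KnowledgeBase:
    """The built-in EGIL acute-leukemia knowledge base (fresh instance)."""
    return loads_kb(_builtin_text())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_kb(kb: KnowledgeBase) -> List[Finding]:
    """Run structural and logical consistency checks; findings are data.

    Checks: genus cycles, dangling references, unmappable literals,
    defining classes with empty differentia, unsatisfiable expanded
    definitions, pairs of distinct classes with logically equivalent
    expanded definitions, and markers never used anywhere.
    """
    from . import reasoner  # local import to avoid a cycle

    findings: List[Finding] = []

    chains_ok: Dict[str, bool] = {}
    for cid, definition in kb.classes.items():
        if definition.genus is not None and definition.genus not in kb.classes:
            findings.append(
                Finding("dangling-genus", "error", cid, f"genus {definition.genus!r} not defined")
            )
            chains_ok[cid] = False
            continue
        try:
            kb.genus_chain(cid)
            chains_ok[cid] = True
        except GenusCycleError as exc:
            findings.append(Finding("genus-cycle", "error", cid, str(exc)))
            chains_ok[cid] = False

    used_markers = set()
    for cid, definition in kb.classes.items():
        phenotypes = [definition.differentia]
        if definition.typical_profile is not None:
            phenotypes.append(definition.typical_profile)
        for phenotype in phenotypes:
            for literal in phenotype.literals():
                used_markers.add(literal.marker.id)
                if kb.markers.get(literal.marker.id) != literal.marker:
                    findings.append(
                        Finding(
                            "dangling-marker",
                            "error",
                            cid,
                            f"marker {literal.marker.label!r} not in the dictionary",
                        )
                    )
                try:
                    kb.relations.relation_for(literal.location, literal.status)
                except UnsupportedRelationError as exc:
                    findings.append(Finding("unsupported-relation", "error", cid, str(exc)))
        if definition.defining and definition.differentia.is_trivial:
            findings.append(
                Finding(
                    "empty-defining-differentia",
                    "error",
                    cid,
                    "defining class has an empty differentia",
                )
            )

    for marker_id in kb.markers:
        if marker_id not in used_markers:
            findings.append(
                Finding("unused-marker", "warning", marker_id, "marker never referenced")
            )

    # logical checks need intact genus chains
    checkable = [cid for cid, ok in chains_ok.items() if ok]
    expansions = {cid: kb.expand(cid) for cid in checkable}
    unsat = set()
    for cid in checkable:
        if not reasoner.is_satisfiable(expansions[cid]):
            unsat.add(cid)
            findings.append(
                Finding(
                    "unsatisfiable-class",
                    "error",
                    cid,
                    "expanded definition is contradictory",
                )
            )
    defining = [
        cid for cid in checkable if kb.classes[cid].defining and cid not in unsat
    ]
    for i, a in enumerate(defining):
        for b in defining[i + 1 :]:
            if reasoner.entails(expansions[a], expansions[b]) and reasoner.entails(
                expansions[b], expansions[a]
            ):
                findings.append(
                    Finding(
                        "equivalent-classes",
                        "warning",
                        a,
                        f"logically equivalent to {b!r}",
                    )
                )
    return findings


# ---------------------------------------------------------------------------
# Textual definitions
# ---------------------------------------------------------------------------

_STATUS_WORDS = {
    ExpressionStatus.PRESENT: "positive",
    ExpressionStatus.ABSENT: "negative",
    ExpressionStatus.HIGH: "high",
    ExpressionStatus.LOW: "low",
}


def _article(noun: str) -> str:
    return "An" if noun[:1].casefold() in "aeiou" else "A"


def _literal_phrase(literal: MarkerLiteral) -> str:
    name = literal.marker.display_name
    word = _STATUS_WORDS[literal.status]
    if literal.location is Location.CYTOPLASMIC:
        return f"cytoplasmic {name} {word}"
    return f"{name}-{word}"


def render_textual_definition(class_id: str, kb: KnowledgeBase) -> str:
    """Deterministic human-readable definition for one class.

    Classes with differentia read "A/An {genus} that is {marker phrases}.";
    upper-level classes without differentia use their lineage sentence.
    A stored ``textual_definition`` (e.g. read back from an ontology file)
    takes precedence and re-renders unchanged.
    """
    definition = kb.classes.get(class_id)
    if definition is None:
        raise UnknownClassError(class_id)
    if definition.textual_definition:
        return definition.textual_definition
    if definition.genus is None:
        return f"{_article(definition.label)} {definition.label}."
    genus_label = kb.classes[definition.genus].label
    base = f"{_article(genus_label)} {genus_label}"
    if definition.differentia.is_trivial:
        if definition.lineage_text:
            return f"{base} {definition.lineage_text}."
        return f"{base}."
    clause_phrases = [
        " or ".join(_literal_phrase(lit) for lit in clause)
        for clause in definition.differentia.clauses
    ]
    return f"{base} that is {' and '.join(clause_phrases)}."
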