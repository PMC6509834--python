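"""Core vocabulary for marker-based cell phenotypes.

The data model is deliberately small: a :class:`Marker` names a measurable
protein, a :class:`MarkerLiteral` asserts its expression status at one
cellular location, and a :class:`Phenotype` is a conjunction of disjunctive
clauses over such literals (the normal form used by immunophenotyping
schemes that mix "and" with "and/or").
"""

from __future__ import annotations

import difflib
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .kb import KnowledgeBase

__all__ = [
    "Location",
    "ExpressionStatus",
    "Marker",
    "MarkerLiteral",
    "Clause",
    "Phenotype",
    "CellClassDefinition",
    "UnknownMarkerError",
    "UnknownClassError",
    "GenusCycleError",
    "EmptyClauseError",
    "normalize_marker_label",
    "parse_marker_token",
    "make_phenotype",
    "expand_definition",
    "WORLD_STATUSES",
    "literal_world_statuses",
]


class Location(str, enum.Enum):
    """Cellular compartment at which a marker is assayed."""

    SURFACE = "surface"
    CYTOPLASMIC = "cytoplasmic"


class ExpressionStatus(str, enum.Enum):
    """Expression call for a marker at a location.

    ``HIGH`` and ``LOW`` each entail ``PRESENT``; ``ABSENT`` is incompatible
    with all three.
    """

    PRESENT = "present"
    ABSENT = "absent"
    HIGH = "high"
    LOW = "low"


#: Exact world-level statuses: "present" here means present at an
#: unspecified amount (i.e. neither called high nor low).
WORLD_STATUSES: Tuple[str, ...] = ("absent", "present", "high", "low")

_LITERAL_WORLDS = {
    ExpressionStatus.PRESENT: frozenset({"present", "high", "low"}),
    ExpressionStatus.ABSENT: frozenset({"absent"}),
    ExpressionStatus.HIGH: frozenset({"high"}),
    ExpressionStatus.LOW: frozenset({"low"}),
}


def literal_world_statuses(status: ExpressionStatus) -> frozenset:
    """World statuses that satisfy a literal with the given status."""
    return _LITERAL_WORLDS[status]


class UnknownMarkerError(KeyError):
    """Raised when a marker label cannot be resolved against a dictionary."""

    def __init__(self, raw: str, candidates: Sequence[str] = ()):
        self.raw = raw
        self.candidates = list(candidates)
        hint = f" (did you mean: {', '.join(self.candidates)}?)" if self.candidates else ""
        super().__init__(f"unknown marker {raw!r}{hint}")

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


class UnknownClassError(KeyError):
    def __init__(self, class_id: str):
        self.class_id = class_id
        super().__init__(f"unknown class {class_id!r}")

    def __str__(self) -> str:
        return self.args[0]


class GenusCycleError(ValueError):
    """A class is (transitively) its own genus."""


class EmptyClauseError(ValueError):
    """A phenotype clause must contain at least one literal."""


@dataclass(frozen=True)
class Marker:
    """A measurable marker (usually a surface or cytoplasmic protein)."""

    id: str
    label: str
    synonyms: Tuple[str, ...] = ()
    external_ref: Optional[str] = None
    #: Optional prose name used when rendering textual definitions
    #: (e.g. "Ig mu" for the cyIgM heavy chain); defaults to ``label``.
    display: Optional[str] = None

    @property
    def display_name(self) -> str:
        return self.display or self.label


@dataclass(frozen=True)
class MarkerLiteral:
    """One assertion about one marker at one location."""

    marker: Marker
    location: Location
    status: ExpressionStatus

    @property
    def sort_index(self) -> Tuple[str, str, str]:
        return (self.marker.label.casefold(), self.location.value, self.status.value)

    def __lt__(self, other: "MarkerLiteral") -> bool:
        if not isinstance(other, MarkerLiteral):
            return NotImplemented
        return self.sort_index < other.sort_index

    @property
    def var(self) -> Tuple[str, str]:
        """The (marker id, location) variable this literal constrains."""
        return (self.marker.id, self.location.value)

    def __str__(self) -> str:
        sign = {"present": "+", "absent": "-", "high": "++", "low": "+dim"}[self.status.value]
        prefix = "cy" if self.location is Location.CYTOPLASMIC else ""
        return f"{prefix}{self.marker.label}{sign}"


Clause = Tuple[MarkerLiteral, ...]


def _canonical_clause(literals: Iterable[MarkerLiteral]) -> Clause:
    unique = sorted(set(literals))
    if not unique:
        raise EmptyClauseError("clause must contain at least one literal")
    return tuple(unique)


@dataclass(frozen=True)
class Phenotype:
    """A conjunction of clauses; each clause is a disjunction of literals.

    The empty clause list is the trivially true phenotype.  Construction via
    :meth:`from_clauses` canonicalizes ordering and removes duplicates so
    that equal phenotypes compare equal.
    """

    clauses: Tuple[Clause, ...] = ()

    @classmethod
    def from_clauses(cls, clauses: Iterable[Iterable[MarkerLiteral]]) -> "Phenotype":
        canon = sorted(
            {_canonical_clause(c) for c in clauses},
            key=lambda clause: tuple(lit.sort_index for lit in clause),
        )
        return cls(tuple(canon))

    @classmethod
    def trivial(cls) -> "Phenotype":
        return cls(())

    @property
    def is_trivial(self) -> bool:
        return not self.clauses

    def literals(self) -> Iterable[MarkerLiteral]:
        for clause in self.clauses:
            yield from clause

    def variables(self) -> frozenset:
        """The set of (marker id, location value) pairs constrained here."""
        return frozenset(lit.var for lit in self.literals())

    def conjoin(self, other: "Phenotype") -> "Phenotype":
        return Phenotype.from_clauses(self.clauses + other.clauses)

    def __str__(self) -> str:
        if self.is_trivial:
            return "⊤"
        return " & ".join(
            "(" + " | ".join(str(lit) for lit in clause) + ")" for clause in self.clauses
        )


@dataclass
class CellClassDefinition:
    """A genus-differentia definition of one cell class.

    ``defining`` marks whether the differentia is necessary *and* sufficient
    (an equivalence axiom) or the class only carries a subclass axiom.
    ``typical_profile`` is an annotation-only phenotype ("often ...") that
    never participates in reasoning.
    """

    id: str
    label: str
    genus: Optional[str]
    differentia: Phenotype = field(default_factory=Phenotype.trivial)
    defining: bool = True
    typical_profile: Optional[Phenotype] = None
    lineage_text: Optional[str] = None
    textual_definition: Optional[str] = None


_WS_RE = re.compile(r"\s+")


def _norm_key(raw: str) -> str:
    return _WS_RE.sub(" ", raw.strip()).casefold()


def normalize_marker_label(raw: str, kb: "KnowledgeBase") -> Marker:
    """Resolve a raw marker spelling to the unique dictionary marker.

    Matching is case-insensitive, collapses whitespace, and falls back to a
    space-free comparison so OCR-style spellings like ``"CD 117"`` resolve.
    Raises :class:`UnknownMarkerError` naming nearest candidates otherwise.
    """
    if not raw or not raw.strip():
        raise UnknownMarkerError(raw)
    index = kb.marker_index()
    key = _norm_key(raw)
    marker = index.get(key)
    if marker is None:
        marker = index.get(key.replace(" ", ""))
    if marker is None:
        candidates = difflib.get_close_matches(key, index.keys(), n=3, cutoff=0.6)
        labels = sorted({index[c].label for c in candidates})
        raise UnknownMarkerError(raw, labels)
    return marker


def parse_marker_token(raw: str, kb: "KnowledgeBase") -> Tuple[Marker, Optional[Location]]:
    """Resolve a marker token that may carry a ``cy``/``s`` location prefix.

    ``"cyCD3"`` resolves to (CD3, cytoplasmic) and ``"sCD3"`` to
    (CD3, surface); tokens that resolve directly (e.g. ``"sIg"``, which is a
    marker in its own right) take precedence and return location ``None``.
    """
    try:
        return normalize_marker_label(raw, kb), None
    except UnknownMarkerError:
        pass
    stripped = raw.strip()
    for prefix, loc in (("cy", Location.CYTOPLASMIC), ("c", Location.CYTOPLASMIC), ("s", Location.SURFACE)):
        if stripped.casefold().startswith(prefix) and len(stripped) > len(prefix):
            try:
                return normalize_marker_label(stripped[len(prefix):], kb), loc
            except UnknownMarkerError:
                continue
    # re-raise with the original token for the error message
    return normalize_marker_label(raw, kb), None


_LOCATIONS = {loc.value: loc for loc in Location}
_STATUSES = {st.value: st for st in ExpressionStatus}


def _coerce_literal(
    spec: Tuple[object, object, object], kb: "KnowledgeBase"
) -> MarkerLiteral:
    name, location, status = spec
    marker = name if isinstance(name, Marker) else normalize_marker_label(str(name), kb)
    if not isinstance(location, Location):
        try:
            location = _LOCATIONS[str(location).strip().casefold()]
        except KeyError:
            raise ValueError(f"unknown location {location!r}") from None
    if not isinstance(status, ExpressionStatus):
        try:
            status = _STATUSES[str(status).strip().casefold()]
        except KeyError:
            raise ValueError(f"unknown status {status!r}") from None
    return MarkerLiteral(marker=marker, location=location, status=status)


def make_phenotype(
    clauses: Iterable[Iterable[Tuple[object, object, object]]], kb: "KnowledgeBase"
) -> Phenotype:
    """Build a canonical :class:`Phenotype` from (marker, location, status) triples.

    Marker names are resolved through the knowledge base dictionary;
    duplicate literals and duplicate clauses are removed.  An empty clause is
    an error; an empty clause *list* yields the trivially true phenotype.
    """
    built = []
    for clause in clauses:
        literals = [_coerce_literal(tuple(spec), kb) for spec in clause]
        if not literals:
            raise EmptyClauseError("clause must contain at least one literal")
        built.append(literals)
    return Phenotype.from_clauses(built)


def expand_definition(class_id: str, kb: "KnowledgeBase") -> Phenotype:
    """Conjoin a class's differentia with all differentia up its genus chain."""
    if class_id not in kb.classes:
        raise UnknownClassError(class_id)
    phenotype = Phenotype.trivial()
    seen = []
    current: Optional[str] = class_id
    while current is not None:
        if current in seen:
            chain = " -> ".join(seen + [current])
            raise GenusCycleError(f"genus cycle: {chain}")
        seen.append(current)
        try:
            definition = kb.classes[current]
        except KeyError:
            raise UnknownClassError(current) from None
        phenotype = phenotype.conjoin(definition.differentia)
        current = definition.genus
    return phenotype
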