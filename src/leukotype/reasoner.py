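"""Sound and complete reasoning over marker phenotypes.

Phenotypes are conjunctions of disjunctive clauses whose literals constrain
one (marker, location) variable to a set of world statuses drawn from
{absent, present, high, low} ("present" meaning present at an unspecified
amount).  Entailment and satisfiability are decided by a small
constraint-propagation/backtracking solver over these 4-valued variables;
completeness is checked against exhaustive world enumeration in the test
suite rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .kb import KnowledgeBase
from .model import (
    ExpressionStatus,
    MarkerLiteral,
    Phenotype,
    UnknownClassError,
    UnknownMarkerError,
    WORLD_STATUSES,
    literal_world_statuses,
)

__all__ = [
    "MarkerWorld",
    "UniverseMismatchError",
    "HierarchyResult",
    "ClassificationResult",
    "literal_implies",
    "satisfies",
    "entails",
    "is_satisfiable",
    "subsumes",
    "classify_hierarchy",
    "classify_instance",
]

Var = Tuple[str, str]  # (marker id, location value)
_FULL: FrozenSet[str] = frozenset(WORLD_STATUSES)


class UniverseMismatchError(ValueError):
    """A world does not cover every variable of the phenotype."""


@dataclass(frozen=True)
class MarkerWorld:
    """A total assignment of exact statuses over a finite variable universe."""

    assignment: Tuple[Tuple[Var, str], ...]

    @classmethod
    def of(cls, mapping: Mapping[Var, str]) -> "MarkerWorld":
        for status in mapping.values():
            if status not in WORLD_STATUSES:
                raise ValueError(f"unknown world status {status!r}")
        return cls(tuple(sorted(mapping.items())))

    @property
    def as_dict(self) -> Dict[Var, str]:
        return dict(self.assignment)


def literal_implies(a: MarkerLiteral, b: MarkerLiteral) -> bool:
    """True iff every world satisfying literal ``a`` satisfies literal ``b``."""
    if a.var != b.var:
        return False
    return literal_world_statuses(a.status) <= literal_world_statuses(b.status)


def satisfies(world: MarkerWorld, phenotype: Phenotype) -> bool:
    """Exact model check of ``phenotype`` against a total world."""
    assignment = world.as_dict
    missing = phenotype.variables() - assignment.keys()
    if missing:
        raise UniverseMismatchError(f"world does not cover variables {sorted(missing)}")
    return all(
        any(assignment[lit.var] in literal_world_statuses(lit.status) for lit in clause)
        for clause in phenotype.clauses
    )


# ---------------------------------------------------------------------------
# Constraint solver
# ---------------------------------------------------------------------------

_SolverClause = Tuple[Tuple[Var, FrozenSet[str]], ...]


def _phenotype_clauses(phenotype: Phenotype) -> List[_SolverClause]:
    return [
        tuple((lit.var, literal_world_statuses(lit.status)) for lit in clause)
        for clause in phenotype.clauses
    ]


def _solve(clauses: Sequence[_SolverClause], domains: Dict[Var, FrozenSet[str]]) -> bool:
    """Satisfiability of clauses under per-variable domain restrictions.

    Unit propagation first (a clause whose only live literal forces its
    variable), then branching over the literals of a shortest clause; each
    branch commits one literal, so the search covers every way of
    satisfying that clause.
    """
    while True:
        changed = False
        pending: List[_SolverClause] = []
        for clause in clauses:
            live: List[Tuple[Var, FrozenSet[str]]] = []
            satisfied = False
            for var, allowed in clause:
                dom = domains.get(var, _FULL)
                if not (dom & allowed):
                    continue  # literal cannot be satisfied
                if dom <= allowed:
                    satisfied = True  # literal holds in every remaining world
                    break
                live.append((var, allowed))
            if satisfied:
                continue
            if not live:
                return False
            if len(live) == 1:
                var, allowed = live[0]
                domains[var] = domains.get(var, _FULL) & allowed
                changed = True
                continue
            pending.append(tuple(live))
        clauses = pending
        if not changed:
            break
    if not clauses:
        return True
    branch = min(clauses, key=len)
    rest = [c for c in clauses if c is not branch]
    for var, allowed in branch:
        new_domains = dict(domains)
        new_domains[var] = new_domains.get(var, _FULL) & allowed
        if _solve(rest, new_domains):
            return True
    return False


def is_satisfiable(phenotype: Phenotype) -> bool:
    """True iff some world satisfies the phenotype."""
    return _solve(_phenotype_clauses(phenotype), {})


def entails(p: Phenotype, q: Phenotype) -> bool:
    """True iff every world satisfying ``p`` also satisfies ``q``.

    Decided clause by clause: ``p`` entails a clause ``c`` iff ``p`` is
    unsatisfiable under the negation of ``c`` (each negated literal
    restricting its variable to the complementary statuses).
    """
    p_clauses = _phenotype_clauses(p)
    for clause in q.clauses:
        domains: Dict[Var, FrozenSet[str]] = {}
        tautological = False
        for lit in clause:
            complement = _FULL - literal_world_statuses(lit.status)
            restricted = domains.get(lit.var, _FULL) & complement
            if not restricted:
                tautological = True  # negation already contradictory
                break
            domains[lit.var] = restricted
        if tautological:
            continue
        if _solve(p_clauses, domains):
            return False  # countermodel found
    return True


# ---------------------------------------------------------------------------
# Class-level reasoning
# ---------------------------------------------------------------------------

def subsumes(parent_id: str, child_id: str, kb: KnowledgeBase) -> bool:
    """True iff ``parent_id`` subsumes ``child_id``.

    Reflexive; holds along the asserted genus chain for every class, and
    additionally by entailment of expanded definitions between defining
    classes.  An unsatisfiable defining child is vacuously subsumed.
    """
    for cid in (parent_id, child_id):
        if cid not in kb.classes:
            raise UnknownClassError(cid)
    if parent_id == child_id:
        return True
    if parent_id in kb.asserted_ancestors(child_id):
        return True
    parent = kb.classes[parent_id]
    child = kb.classes[child_id]
    if parent.defining and child.defining:
        return entails(kb.expand(child_id), kb.expand(parent_id))
    return False


def _subsumption_graph(kb: KnowledgeBase) -> nx.DiGraph:
    """Child -> parent digraph of asserted and logically derived subsumptions."""

    def compute() -> nx.DiGraph:
        graph = nx.DiGraph()
        graph.add_nodes_from(kb.classes)
        for cid, definition in kb.classes.items():
            if definition.genus is not None:
                graph.add_edge(cid, definition.genus, asserted=True)
        defining = [
            cid
            for cid in kb.defining_ids()
            if is_satisfiable(kb.expand(cid))
        ]
        for child in defining:
            for parent in defining:
                if child != parent and entails(kb.expand(child), kb.expand(parent)):
                    if graph.has_edge(child, parent):
                        graph[child][parent]["derived"] = True
                    else:
                        graph.add_edge(child, parent, asserted=False, derived=True)
        return graph

    return kb.cache("subsumption_graph", compute)


def _subsumption_closure(kb: KnowledgeBase) -> Dict[str, FrozenSet[str]]:
    """Map class id -> all class ids subsuming it (including itself)."""

    def compute() -> Dict[str, FrozenSet[str]]:
        graph = _subsumption_graph(kb)
        return {
            cid: frozenset(nx.descendants(graph, cid)) | {cid} for cid in graph.nodes
        }

    return kb.cache("subsumption_closure", compute)


@dataclass(frozen=True)
class HierarchyResult:
    """Inferred class hierarchy: direct edges after transitive reduction,
    groups of mutually subsuming classes, and asserted genus edges that are
    not re-derivable logically."""

    direct_edges: Tuple[Tuple[str, str], ...]
    equivalence_groups: Tuple[FrozenSet[str], ...]
    asserted_only: Tuple[Tuple[str, str], ...]

    def parents_of(self, class_id: str) -> Tuple[str, ...]:
        return tuple(p for c, p in self.direct_edges if c == class_id)


def classify_hierarchy(kb: KnowledgeBase) -> HierarchyResult:
    """Re-derive the class hierarchy from asserted and logical subsumption."""
    graph = _subsumption_graph(kb)

    groups = [frozenset(scc) for scc in nx.strongly_connected_components(graph)]
    representative = {cid: min(group) for group in groups for cid in group}
    condensed = nx.DiGraph()
    condensed.add_nodes_from(set(representative.values()))
    for child, parent in graph.edges:
        rc, rp = representative[child], representative[parent]
        if rc != rp:
            condensed.add_edge(rc, rp)
    reduced = nx.transitive_reduction(condensed)

    asserted_only = []
    for child, parent, data in graph.edges(data=True):
        if not data.get("asserted"):
            continue
        if not (kb.classes[child].defining and kb.classes[parent].defining):
            continue
        if not data.get("derived"):
            asserted_only.append((child, parent))

    return HierarchyResult(
        direct_edges=tuple(sorted(reduced.edges)),
        equivalence_groups=tuple(
            sorted((g for g in groups if len(g) > 1), key=sorted)
        ),
        asserted_only=tuple(sorted(asserted_only)),
    )


# ---------------------------------------------------------------------------
# Instance classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    definite: FrozenSet[str]
    compatible: FrozenSet[str]
    most_specific_definite: Tuple[str, ...]
    policy: str


_MEASURED_WORLDS = {
    ExpressionStatus.PRESENT: frozenset({"present", "high", "low"}),
    ExpressionStatus.ABSENT: frozenset({"absent"}),
    ExpressionStatus.HIGH: frozenset({"high"}),
    ExpressionStatus.LOW: frozenset({"low"}),
}


def _known_statuses(
    measurements: Mapping[Tuple[str, object], ExpressionStatus],
    kb: KnowledgeBase,
    on_unknown_marker: str,
) -> Dict[Var, FrozenSet[str]]:
    known: Dict[Var, FrozenSet[str]] = {}
    for (raw_marker, location), status in measurements.items():
        try:
            marker = kb.resolve_marker(str(raw_marker))
        except UnknownMarkerError:
            if on_unknown_marker == "error":
                raise
            warnings.warn(f"skipping unknown marker {raw_marker!r}", stacklevel=3)
            continue
        loc_value = location.value if hasattr(location, "value") else str(location)
        known[(marker.id, loc_value)] = _MEASURED_WORLDS[ExpressionStatus(status)]
    return known


def classify_instance(
    sample,
    kb: KnowledgeBase,
    policy: str = "open",
    on_unknown_marker: str = "skip",
    stage_precedence: bool = False,
) -> ClassificationResult:
    """Sort one patient sample into matching classes.

    ``policy`` is ``"open"`` (unmeasured markers stay unknown) or
    ``"closed"`` (unmeasured markers are treated as absent over the universe
    of marker-locations used by the KB).  A class is *definite* when it is a
    satisfiable defining class whose every expanded clause is witnessed by a
    measured status, or subsumes such a class; it is *compatible* unless some
    expanded clause is contradicted outright.  With ``stage_precedence``,
    later maturation stages win ties among most-specific classes along the
    KB's declared stage chains.
    """
    if policy not in ("open", "closed"):
        raise ValueError(f"unknown policy {policy!r}")
    known = _known_statuses(sample.measurements, kb, on_unknown_marker)
    absent_worlds = _MEASURED_WORLDS[ExpressionStatus.ABSENT]

    satisfied_ids: Set[str] = set()
    compatible: Set[str] = set()
    for cid in kb.classes:
        expansion = kb.expand(cid)
        falsified = False
        all_satisfied = True
        for clause in expansion.clauses:
            # satisfaction needs a measured witness; under closed-world an
            # unmeasured marker defaults to absent for falsification only
            clause_sat = False
            clause_fals = True
            for lit in clause:
                measured = known.get(lit.var)
                allowed = literal_world_statuses(lit.status)
                if measured is not None and measured <= allowed:
                    clause_sat = True
                    clause_fals = False
                    break
                possible = measured
                if possible is None:
                    possible = absent_worlds if policy == "closed" else None
                if possible is None or (possible & allowed):
                    clause_fals = False
            if clause_fals:
                falsified = True
                break
            if not clause_sat:
                all_satisfied = False
        if falsified:
            continue
        compatible.add(cid)
        if all_satisfied and kb.classes[cid].defining and is_satisfiable(expansion):
            satisfied_ids.add(cid)

    closure = _subsumption_closure(kb)
    definite: Set[str] = set()
    for cid in satisfied_ids:
        definite |= closure[cid]

    most_specific = [
        cid
        for cid in definite
        if not any(
            other != cid and cid in closure[other] and other not in closure[cid]
            for other in definite
        )
    ]
    if stage_precedence:
        most_specific = _apply_stage_precedence(most_specific, kb)

    return ClassificationResult(
        sample_id=getattr(sample, "sample_id", ""),
        definite=frozenset(definite),
        compatible=frozenset(compatible),
        most_specific_definite=tuple(sorted(most_specific)),
        policy=policy,
    )


def _apply_stage_precedence(most_specific: Iterable[str], kb: KnowledgeBase) -> List[str]:
    """Within each declared maturation chain, keep only the latest stage."""
    chains = kb.metadata.get("stage_precedence") or []
    kept = list(most_specific)
    for chain in chains:
        ranked = [cid for cid in chain if cid in kept]
        if len(ranked) > 1:
            winner = max(ranked, key=chain.index)
            kept = [cid for cid in kept if cid not in ranked or cid == winner]
    return kept
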