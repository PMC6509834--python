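"""Independent brute-force oracles used to check the reasoner.

These deliberately share no code with ``leukotype.reasoner``: phenotype
satisfaction is re-derived from the literal/world tables and decided by
exhaustive enumeration of every world over the relevant variables.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from leukotype.model import Phenotype, WORLD_STATUSES

# world statuses satisfying each literal status, restated independently
_SAT = {
    "present": {"present", "high", "low"},
    "absent": {"absent"},
    "high": {"high"},
    "low": {"low"},
}


def _world_satisfies(world: Dict, phenotype: Phenotype) -> bool:
    return all(
        any(world[lit.var] in _SAT[lit.status.value] for lit in clause)
        for clause in phenotype.clauses
    )


def _worlds(variables: Sequence) -> Iterable[Dict]:
    for combo in itertools.product(WORLD_STATUSES, repeat=len(variables)):
        yield dict(zip(variables, combo))


def oracle_is_satisfiable(phenotype: Phenotype) -> bool:
    variables = sorted(phenotype.variables())
    return any(_world_satisfies(w, phenotype) for w in _worlds(variables))


def oracle_entails(p: Phenotype, q: Phenotype) -> bool:
    variables = sorted(p.variables() | q.variables())
    return all(
        _world_satisfies(w, q)
        for w in _worlds(variables)
        if _world_satisfies(w, p)
    )


def oracle_transitive_reduction(
    nodes: Sequence[str], relation: Set[Tuple[str, str]]
) -> Set[Tuple[str, str]]:
    """Transitive reduction of a strict partial order given as pair set."""
    strict = {(a, b) for a, b in relation if a != b}
    return {
        (a, b)
        for a, b in strict
        if not any((a, c) in strict and (c, b) in strict for c in nodes)
    }
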