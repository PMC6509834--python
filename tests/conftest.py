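from __future__ import annotations

import random

import pytest

from leukotype.kb import builtin_egil_kb
from leukotype.model import (
    ExpressionStatus,
    Location,
    Marker,
    MarkerLiteral,
    Phenotype,
)


@pytest.fixture(scope="session")
def kb():
    return builtin_egil_kb()


#: a small fixed marker pool for randomized reasoner tests
POOL_MARKERS = [Marker(id=f"M{i}", label=f"M{i}") for i in range(3)]
POOL_VARS = [(m, loc) for m in POOL_MARKERS for loc in Location]  # 6 marker-locations


def random_phenotype(rng: random.Random, max_clauses: int = 3, max_literals: int = 3) -> Phenotype:
    clauses = []
    for _ in range(rng.randint(0, max_clauses)):
        size = rng.randint(1, max_literals)
        picks = rng.sample(POOL_VARS, size)
        clauses.append(
            [
                MarkerLiteral(marker, loc, rng.choice(list(ExpressionStatus)))
                for marker, loc in picks
            ]
        )
    return Phenotype.from_clauses(clauses)
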