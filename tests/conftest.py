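"""Shared fixtures: small graphs, random instances, synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from jdcnet import ExpressionMatrix, PPINetwork, SyntheticSpec, generate


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork(edges=[("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star() -> PPINetwork:
    return PPINetwork(edges=[("HUB", f"L{i}") for i in range(4)])


@pytest.fixture(scope="session")
def default_bundle():
    return generate(SyntheticSpec())


def random_graph(n: int, p: float, rng: np.random.Generator) -> PPINetwork:
    """Erdős–Rényi G(n, p) over string node IDs, drawn pair by pair."""
    ids = [f"N{i:02d}" for i in range(n)]
    edges = [
        (ids[a], ids[b])
        for a in range(n)
        for b in range(a + 1, n)
        if rng.random() < p
    ]
    return PPINetwork(edges=edges, nodes=ids)


def random_boolean_rows(gene_ids, n_samples: int, rng: np.random.Generator):
    """A BooleanExpression-like random {0,1} matrix over the given genes."""
    from jdcnet import BooleanExpression

    values = (rng.random((len(gene_ids), n_samples)) < 0.5).astype(np.uint8)
    return BooleanExpression(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(f"s{t}" for t in range(n_samples)),
        values=values,
    )


def expr_from_rows(rows: dict[str, list[float]]) -> ExpressionMatrix:
    genes = tuple(rows)
    n = len(next(iter(rows.values())))
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=tuple(f"s{t}" for t in range(n)),
        values=np.array([rows[g] for g in genes], dtype=float),
    )
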