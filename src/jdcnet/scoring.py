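"""Protein essentiality scores: JDC and the DC/NC/PeC/WDC baselines.

JDC scores a protein by how strongly it sits inside a co-expressed dense
cluster: for each neighbour j of protein i, the edge weight is the product
of the edge clustering coefficient (a topological cluster-membership proxy)
and the Jaccard similarity of the two genes' Boolean activity vectors, and

    JDC(i) = Σ_{j ∈ D_i} Jaccard(i, j) · ECC(i, j).

Because both factors lie in [0, 1], JDC(i) ≤ NC(i) ≤ DC(i) always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import BooleanExpression, ExpressionMatrix, binarize
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BASELINE_METHODS",
    "METHODS",
    "EdgeWeights",
    "ScoreTable",
    "ecc",
    "jaccard",
    "edge_weights",
    "jdc_scores",
    "baseline_scores",
    "read_score_table",
    "write_score_table",
]

BASELINE_METHODS = ("DC", "NC", "PeC", "WDC")
METHODS = ("JDC",) + BASELINE_METHODS


def ecc(net: PPINetwork, i: str, j: str) -> float:
    """Edge clustering coefficient of edge {i, j}.

    The ratio of triangles through the edge to the maximum possible,
    min(k_i − 1, k_j − 1).  When an endpoint has degree 1 no triangle is
    possible and the coefficient is defined as 0.
    """
    if not net.has_edge(i, j):
        raise ValueError(f"ecc requires an edge, but {{{i!r}, {j!r}}} is not one")
    denom = min(net.degree(i) - 1, net.degree(j) - 1)
    if denom == 0:
        return 0.0
    return net.common_neighbor_count(i, j) / denom


def jaccard(si: np.ndarray, sj: np.ndarray) -> float:
    """Jaccard similarity |S_i ∩ S_j| / |S_i ∪ S_j| of two Boolean vectors.

    Two all-zero (never-active) vectors share no co-expression evidence:
    the empty-union case returns 0.
    """
    si = np.asarray(si, dtype=bool)
    sj = np.asarray(sj, dtype=bool)
    if si.shape != sj.shape or si.ndim != 1:
        raise ValueError(f"Boolean vectors must be 1-D of equal length, got {si.shape} vs {sj.shape}")
    union = int(np.count_nonzero(si | sj))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(si & sj)) / union


@dataclass(frozen=True)
class EdgeWeights:
    """Per-edge ECC, Jaccard and their product J_c, all in [0, 1]."""

    ecc: dict[frozenset[str], float]
    jaccard: dict[frozenset[str], float]
    jc: dict[frozenset[str], float]


def edge_weights(net: PPINetwork, boolexpr: BooleanExpression) -> EdgeWeights:
    """ECC, Jaccard and J_c = Jaccard·ECC for every edge of the network.

    A protein with no expression row is treated as an all-zero activity
    vector, forcing Jaccard (hence J_c) to 0 on all its edges; the number
    of such proteins is logged.
    """
    zero = np.zeros(len(boolexpr.sample_ids), dtype=np.uint8)
    index = {g: k for k, g in enumerate(boolexpr.gene_ids)}

    def vec(node: str) -> np.ndarray:
        k = index.get(node)
        return boolexpr.values[k] if k is not None else zero

    missing = sum(1 for n in net.nodes if n not in index)
    if missing:
        logger.info("edge_weights: %d network protein(s) lack expression rows (Jaccard 0)", missing)

    e_map: dict[frozenset[str], float] = {}
    j_map: dict[frozenset[str], float] = {}
    jc_map: dict[frozenset[str], float] = {}
    for edge in net.edges:
        i, j = tuple(edge)
        e = ecc(net, i, j)
        ja = jaccard(vec(i), vec(j))
        e_map[edge] = e
        j_map[edge] = ja
        jc_map[edge] = ja * e
    return EdgeWeights(ecc=e_map, jaccard=j_map, jc=jc_map)


@dataclass(frozen=True)
class ScoreTable:
    """Protein → score map for one method, with a deterministic ranking.

    Ranking order: descending score, ties broken by ascending protein ID.
    Every network node is scored; the ranking is a permutation of the
    scored proteins.
    """

    method_name: str
    scores: dict[str, float] = field(repr=False)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda p: (-self.scores[p], p))

    def __len__(self) -> int:
        return len(self.scores)

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.scores):
            raise ValueError(f"k={k} out of range 1..{len(self.scores)}")
        return self.ranking[:k]


def jdc_scores(net: PPINetwork, boolexpr: BooleanExpression) -> ScoreTable:
    """JDC(i) = Σ_{j ∈ D_i} Jaccard(i,j)·ECC(i,j); isolated nodes score 0."""
    w = edge_weights(net, boolexpr)
    scores = {n: 0.0 for n in net.nodes}
    for edge, jc in w.jc.items():
        i, j = tuple(edge)
        scores[i] += jc
        scores[j] += jc
    return ScoreTable(method_name="JDC", scores=scores)


def _pcc_clamped(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation clamped to [0, 1]; undefined (zero-variance) → 0."""
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r) or r < 0.0:
        return 0.0
    return min(r, 1.0)


def baseline_scores(
    net: PPINetwork,
    expr: ExpressionMatrix | None,
    method: str,
    wdc_lambda: float = 0.5,
) -> ScoreTable:
    """One of the comparison centralities: DC, NC, PeC or WDC.

    DC(i)  = degree k_i
    NC(i)  = Σ_j ECC(i,j)
    PeC(i) = Σ_j ECC(i,j)·PCC(i,j)
    WDC(i) = Σ_j [λ·ECC(i,j) + (1−λ)·PCC(i,j)],  default λ = 0.5

    PCC is the Pearson correlation of the raw expression rows, clamped to
    [0, 1] (negative or undefined → 0); a protein with no expression row
    contributes PCC = 0 on all its edges.  ``expr`` may be None for DC/NC.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {BASELINE_METHODS}")
    if method in ("PeC", "WDC") and expr is None:
        raise ValueError(f"{method} requires an expression matrix")
    if not 0.0 <= wdc_lambda <= 1.0:
        raise ValueError(f"wdc_lambda must be in [0, 1], got {wdc_lambda}")

    scores = {n: 0.0 for n in net.nodes}
    if method == "DC":
        for n in scores:
            scores[n] = float(net.degree(n))
        return ScoreTable(method_name="DC", scores=scores)

    index = {g: k for k, g in enumerate(expr.gene_ids)} if expr is not None else {}
    for edge in net.edges:
        i, j = tuple(edge)
        e = ecc(net, i, j)
        if method == "NC":
            contrib = e
        else:
            ki, kj = index.get(i), index.get(j)
            pcc = (
                _pcc_clamped(expr.values[ki], expr.values[kj])
                if ki is not None and kj is not None
                else 0.0
            )
            contrib = e * pcc if method == "PeC" else wdc_lambda * e + (1.0 - wdc_lambda) * pcc
        scores[i] += contrib
        scores[j] += contrib
    return ScoreTable(method_name=method, scores=scores)


def score_method(
    net: PPINetwork,
    expr: ExpressionMatrix | None,
    method: str,
    wdc_lambda: float = 0.5,
) -> ScoreTable:
    """Dispatch to ``jdc_scores`` or ``baseline_scores`` by method name."""
    if method == "JDC":
        if expr is None:
            raise ValueError("JDC requires an expression matrix")
        return jdc_scores(net, binarize(expr))
    return baseline_scores(net, expr, method, wdc_lambda=wdc_lambda)


def write_score_table(table: ScoreTable, path: str | Path) -> Path:
    """TSV ``protein_id\\tscore\\trank`` sorted by rank; method in a header comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# method: {table.method_name}\n")
        fh.write("protein_id\tscore\trank\n")
        for rank, pid in enumerate(table.ranking, start=1):
            fh.write(f"{pid}\t{repr(float(table.scores[pid]))}\t{rank}\n")
    return path


def read_score_table(path: str | Path) -> ScoreTable:
    """Read a score TSV written by :func:`write_score_table`."""
    path = Path(path)
    method = "unknown"
    scores: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# method:"):
                method = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            pid, score, _rank = line.split("\t")
            scores[pid] = float(score)
    return ScoreTable(method_name=method, scores=scores)
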