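"""Gene-expression matrices and their Boolean ("active"/"inactive") form.

A gene is called *active* in a sample when its expression strictly exceeds a
per-gene dynamic threshold

    G(i) = U(i) + 2·σ(i)·V(i),    V(i) = 1 / (1 + σ²(i)),

where U(i) and σ²(i) are the mean and *population* variance of the gene's
profile.  The volatility factor V(i) damps the threshold towards the mean
for noisy genes: 2·σ·V = 2σ/(1+σ²) ≤ 1, so G always lies within one
standard deviation of the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneThresholds",
    "BooleanExpression",
    "read_expression",
    "write_expression",
    "gene_thresholds",
    "binarize",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued gene × sample matrix.

    ``values[i, t]`` is the (normalised, unitless) expression of gene
    ``gene_ids[i]`` in sample ``sample_ids[t]``.  No missing values; gene
    IDs unique.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError(f"expression values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(self.gene_ids)} genes "
                f"× {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 1:
            raise ValueError("at least one sample required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene IDs must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene: {gene_id!r}") from None
        return self.values[idx]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class GeneThresholds:
    """Per-gene mean, variance, volatility and activity threshold.

    Invariants: sigma = sqrt(sigma2); V = 1/(1+sigma2); G = U + 2·sigma·V,
    so G ≥ U with equality iff sigma = 0.
    """

    gene_ids: tuple[str, ...]
    mean: np.ndarray = field(repr=False)       # U(i)
    variance: np.ndarray = field(repr=False)   # sigma²(i), divisor n
    std: np.ndarray = field(repr=False)        # sigma(i)
    volatility: np.ndarray = field(repr=False) # V(i) ∈ (0, 1]
    threshold: np.ndarray = field(repr=False)  # G(i)

    def for_gene(self, gene_id: str) -> dict[str, float]:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene: {gene_id!r}") from None
        return {
            "mean": float(self.mean[i]),
            "variance": float(self.variance[i]),
            "std": float(self.std[i]),
            "volatility": float(self.volatility[i]),
            "threshold": float(self.threshold[i]),
        }


@dataclass(frozen=True)
class BooleanExpression:
    """{0,1} gene × sample matrix; row i is the Boolean activity vector S_i."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.uint8)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("Boolean matrix shape inconsistent with ID lists")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("Boolean matrix entries must be 0 or 1")

    def vector(self, gene_id: str) -> np.ndarray:
        """Boolean activity vector S_i for one gene."""
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene: {gene_id!r}") from None
        return self.values[idx]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a TSV expression matrix (header = sample IDs, first column = gene IDs).

    Duplicate gene IDs are collapsed by the arithmetic mean of their rows
    (logged).  Non-numeric or missing cells raise ``ValueError`` with the
    offending coordinates; an empty matrix raises ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    raw = df.to_numpy()
    try:
        # numpy's string parser is correctly rounded, so writer output
        # round-trips bit-exactly (pandas' to_numeric is not)
        values = raw.astype(float)
    except (ValueError, TypeError):
        values = None
    if values is None or not np.isfinite(values).all():
        for r in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                try:
                    ok = np.isfinite(float(raw[r, c]))
                except (ValueError, TypeError):
                    ok = False
                if not ok:
                    raise ValueError(
                        f"{path}: non-numeric or missing cell at gene "
                        f"{df.index[r]!r}, sample {df.columns[c]!r}"
                    )
    numeric = pd.DataFrame(values, index=df.index, columns=df.columns)
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("read_expression(%s): averaged %d duplicate gene row(s)", path, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        gene_ids=tuple(str(g) for g in numeric.index),
        sample_ids=tuple(str(s) for s in numeric.columns),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Write TSV with full-precision (repr-round-trip) floats."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def gene_thresholds(expr: ExpressionMatrix) -> GeneThresholds:
    """Per-gene dynamic threshold G(i) = U(i) + 2·σ(i)·V(i).

    The variance uses divisor n (population variance), not n−1.
    """
    u = expr.values.mean(axis=1)
    sigma2 = expr.values.var(axis=1, ddof=0)
    sigma = np.sqrt(sigma2)
    v = 1.0 / (1.0 + sigma2)
    g = u + 2.0 * sigma * v
    return GeneThresholds(
        gene_ids=expr.gene_ids, mean=u, variance=sigma2, std=sigma, volatility=v, threshold=g
    )


def binarize(expr: ExpressionMatrix) -> BooleanExpression:
    """Threshold each gene at G(i): strictly greater ⇒ active (1), else 0.

    Ties at the threshold are inactive; a constant gene (σ = 0 ⇒ G = U)
    is therefore all-zero.
    """
    th = gene_thresholds(expr)
    active = expr.values > th.threshold[:, None]
    return BooleanExpression(
        gene_ids=expr.gene_ids,
        sample_ids=expr.sample_ids,
        values=active.astype(np.uint8),
    )
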