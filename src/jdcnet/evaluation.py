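"""Ranking-based evaluation against a reference essential-protein list.

All evaluation runs over a single universe: the proteins ranked by a score
table.  Essential IDs absent from that universe are dropped up front (and
counted in the log).  The battery mirrors standard practice for essentiality
prediction: confusion metrics at a fixed cutoff, ROC/AUC over the full
ranking and over its top fraction, jackknife (cumulative-recovery) curves,
top-percentage counts and pairwise top-N overlap between methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc

from .scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledRanking",
    "ConfusionCounts",
    "read_essential_list",
    "confusion_at_cutoff",
    "classification_metrics",
    "roc_auc",
    "roc_auc_top_fraction",
    "jackknife_curve",
    "top_percent_counts",
    "overlap_analysis",
    "OverlapRecord",
]

DEFAULT_TOP_PERCENTS = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0)


def read_essential_list(path: str | Path) -> set[str]:
    """One protein ID per line; ``#`` comments and blank lines allowed."""
    path = Path(path)
    ids: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
    return ids


@dataclass(frozen=True)
class LabeledRanking:
    """A method's ranking joined with the reference essential set.

    ``essential`` is restricted to ranked proteins at construction; the
    number of dropped IDs is logged.
    """

    ranking: tuple[str, ...]
    essential: frozenset[str]
    scores: dict[str, float] = field(repr=False)

    @classmethod
    def from_score_table(cls, table: ScoreTable, essential: set[str]) -> "LabeledRanking":
        ranked = tuple(table.ranking)
        universe = set(ranked)
        kept = frozenset(essential & universe)
        dropped = len(essential) - len(kept)
        if dropped:
            logger.info(
                "LabeledRanking(%s): dropped %d essential ID(s) absent from the ranking",
                table.method_name, dropped,
            )
        return cls(ranking=ranked, essential=kept, scores=dict(table.scores))

    @property
    def n(self) -> int:
        return len(self.ranking)

    @property
    def n_essential(self) -> int:
        return len(self.essential)

    def labels(self) -> np.ndarray:
        """Indicator vector (1 = essential) in ranking order."""
        return np.fromiter((p in self.essential for p in self.ranking), dtype=int, count=self.n)

    def score_array(self) -> np.ndarray:
        return np.fromiter((self.scores[p] for p in self.ranking), dtype=float, count=self.n)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_at_cutoff(r: LabeledRanking, k: int) -> ConfusionCounts:
    """Predict the top-k ranked proteins essential; count the 2×2 table."""
    if not 1 <= k <= r.n:
        raise ValueError(f"cutoff k={k} out of range 1..{r.n}")
    top = set(r.ranking[:k])
    tp = len(top & r.essential)
    fp = k - tp
    fn = r.n_essential - tp
    tn = r.n - k - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """SN, SP, FPR, PPV, NPV, F-measure, ACC and MCC from a 2×2 table.

    Requires both classes present.  Any 0/0 ratio (e.g. PPV with no
    positive predictions) is reported as 0 with a logged warning; an MCC
    with a zero denominator likewise.
    """
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise ValueError("classification_metrics requires both classes present")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("classification_metrics: %s is 0/0, reporting 0", name)
            return 0.0
        return num / den

    sn = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    fpr = c.FP / (c.TN + c.FP)
    ppv = ratio(c.TP, c.TP + c.FP, "PPV")
    npv = ratio(c.TN, c.TN + c.FN, "NPV")
    f = ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F-measure")
    acc = (c.TP + c.TN) / c.total
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * float(c.TP + c.FN) * float(c.TN + c.FP) * float(c.TN + c.FN)
    )
    mcc = ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC")
    return {
        "SN": sn, "SP": sp, "FPR": fpr, "PPV": ppv, "NPV": npv,
        "F-measure": f, "ACC": acc, "MCC": mcc,
    }


def roc_auc(r: LabeledRanking) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC over all score thresholds.

    Tied scores enter together (one threshold per distinct score), producing
    diagonal segments; the resulting AUC equals the tie-corrected
    Mann–Whitney statistic P(score_ess > score_non) + ½·P(equal).
    """
    labels = r.labels()
    if labels.min() == labels.max():
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, r.score_array(), drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def roc_auc_top_fraction(
    r: LabeledRanking, fraction: float
) -> tuple[list[tuple[float, float]], float]:
    """ROC/AUC restricted to the top ⌈fraction·P⌉ ranked proteins."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    m = math.ceil(fraction * r.n)
    top = r.ranking[:m]
    sub = LabeledRanking(
        ranking=tuple(top),
        essential=frozenset(p for p in top if p in r.essential),
        scores={p: r.scores[p] for p in top},
    )
    return roc_auc(sub)


def jackknife_curve(r: LabeledRanking) -> list[int]:
    """Cumulative count of essentials among the top m ranked proteins, m = 1..P."""
    if r.n == 0:
        raise ValueError("jackknife_curve requires a nonempty ranking")
    return np.cumsum(r.labels()).tolist()


def top_percent_counts(
    r: LabeledRanking, percents: tuple[float, ...] = DEFAULT_TOP_PERCENTS
) -> dict[float, int]:
    """Essential count in the top ⌈p·P/100⌉ ranked proteins for each percentage p."""
    for p in percents:
        if not 0.0 < p <= 100.0:
            raise ValueError(f"percentage must be in (0, 100], got {p}")
    labels = r.labels()
    cum = np.cumsum(labels)
    out: dict[float, int] = {}
    for p in percents:
        m = math.ceil(p * r.n / 100.0)
        out[p] = int(cum[m - 1])
    return out


@dataclass(frozen=True)
class OverlapRecord:
    """Top-N overlap between two methods, with essentiality of the differences.

    ``a_only``/``b_only`` are the symmetric-difference sides (A−B and B−A);
    percentages are of essential proteins within each side, reported as 0
    alongside ``empty_difference=True`` when the sides are empty.
    """

    method_a: str
    method_b: str
    top_n: int
    intersection: int
    a_only: int
    b_only: int
    a_only_essential: int
    b_only_essential: int
    a_only_essential_pct: float
    b_only_essential_pct: float
    empty_difference: bool


def overlap_analysis(
    a: ScoreTable, b: ScoreTable, essential: set[str], top_n: int
) -> OverlapRecord:
    """Compare the top-N protein sets of two methods.

    Reports |A∩B| and, for each side of the symmetric difference, the
    essential count and percentage.
    """
    if set(a.scores) != set(b.scores):
        raise ValueError("overlap_analysis requires score tables over the same protein universe")
    if not 1 <= top_n <= len(a.scores):
        raise ValueError(f"top_n={top_n} out of range 1..{len(a.scores)}")
    set_a = set(a.top(top_n))
    set_b = set(b.top(top_n))
    a_only = set_a - set_b
    b_only = set_b - set_a
    a_ess = len(a_only & essential)
    b_ess = len(b_only & essential)
    empty = not a_only and not b_only
    return OverlapRecord(
        method_a=a.method_name,
        method_b=b.method_name,
        top_n=top_n,
        intersection=len(set_a & set_b),
        a_only=len(a_only),
        b_only=len(b_only),
        a_only_essential=a_ess,
        b_only_essential=b_ess,
        a_only_essential_pct=100.0 * a_ess / len(a_only) if a_only else 0.0,
        b_only_essential_pct=100.0 * b_ess / len(b_only) if b_only else 0.0,
        empty_difference=empty,
    )
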