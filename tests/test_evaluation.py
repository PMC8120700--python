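"""Confusion metrics, ROC/AUC, jackknife, top-percentage and overlap."""

from __future__ import annotations

import math

import numpy as np
import pytest

from jdcnet import (
    ConfusionCounts,
    LabeledRanking,
    classification_metrics,
    confusion_at_cutoff,
    jackknife_curve,
    overlap_analysis,
    read_essential_list,
    roc_auc,
    roc_auc_top_fraction,
    top_percent_counts,
)
from jdcnet.scoring import ScoreTable


def make_ranking(scores: dict[str, float], essential: set[str]) -> LabeledRanking:
    return LabeledRanking.from_score_table(ScoreTable("test", scores), essential)


def random_ranking(n: int, rng: np.random.Generator, tie_prob: float = 0.3):
    """Random scores (with deliberate ties) and random labels."""
    scores = {}
    for i in range(n):
        if tie_prob and rng.random() < tie_prob:
            scores[f"P{i:03d}"] = float(rng.integers(0, 5))  # coarse -> many ties
        else:
            scores[f"P{i:03d}"] = float(rng.random())
    essential = {p for p in scores if rng.random() < 0.4}
    if not essential:
        essential = {next(iter(scores))}
    if len(essential) == n:
        essential.discard(sorted(scores)[-1])
    return make_ranking(scores, essential)


def mann_whitney_auc(r: LabeledRanking) -> float:
    """Independent oracle: tie-corrected pairwise statistic over all
    (essential, non-essential) pairs."""
    ess = [r.scores[p] for p in r.ranking if p in r.essential]
    non = [r.scores[p] for p in r.ranking if p not in r.essential]
    total = 0.0
    for e in ess:
        for x in non:
            total += 1.0 if e > x else (0.5 if e == x else 0.0)
    return total / (len(ess) * len(non))


class TestConfusionAtCutoff:
    def test_alternating_example(self):
        r = make_ranking({"e1": 4.0, "n1": 3.0, "e2": 2.0, "n2": 1.0}, {"e1", "e2"})
        c = confusion_at_cutoff(r, 2)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 1)

    def test_cutoff_at_all_proteins(self):
        r = make_ranking({"a": 3.0, "b": 2.0, "c": 1.0}, {"b"})
        c = confusion_at_cutoff(r, 3)
        assert c.FN == 0 and c.FP == 2 and c.TP == 1 and c.TN == 0

    def test_counts_partition_the_universe(self):
        rng = np.random.default_rng(44)
        r = random_ranking(50, rng)
        for k in (1, 10, 25, 50):
            c = confusion_at_cutoff(r, k)
            assert c.TP + c.FN == r.n_essential
            assert c.TN + c.FP == r.n - r.n_essential
            assert c.total == r.n

    def test_out_of_range_cutoff(self):
        r = make_ranking({"a": 1.0, "b": 0.0}, {"a"})
        with pytest.raises(ValueError):
            confusion_at_cutoff(r, 0)
        with pytest.raises(ValueError):
            confusion_at_cutoff(r, 3)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert m["SN"] == m["SP"] == m["PPV"] == m["ACC"] == m["MCC"] == 1.0
        assert m["FPR"] == 0.0

    def test_hand_evaluated_example(self):
        # TP=10 FP=5 TN=80 FN=5: SN=10/15, SP=80/85, PPV=10/15, F=20/30,
        # ACC=90/100, MCC=(800-25)/sqrt(15*15*85*85)=775/1275
        m = classification_metrics(ConfusionCounts(TP=10, FP=5, TN=80, FN=5))
        assert m["SN"] == pytest.approx(2 / 3, abs=1e-12)
        assert m["SP"] == pytest.approx(80 / 85, abs=1e-12)
        assert m["FPR"] == pytest.approx(5 / 85, abs=1e-12)
        assert m["PPV"] == pytest.approx(2 / 3, abs=1e-12)
        assert m["NPV"] == pytest.approx(80 / 85, abs=1e-12)
        assert m["F-measure"] == pytest.approx(2 / 3, abs=1e-12)
        assert m["ACC"] == pytest.approx(0.9, abs=1e-12)
        assert m["MCC"] == pytest.approx(775 / 1275, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(TP=5, FP=0, TN=0, FN=5))

    def test_zero_over_zero_reported_as_zero(self):
        # no positive predictions: PPV and F-measure are 0/0 -> 0
        m = classification_metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=5))
        assert m["PPV"] == 0.0
        assert m["F-measure"] == 0.0
        assert m["MCC"] == 0.0

    def test_random_confusion_matrices_identities(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 1000:
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 60, size=4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = classification_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
            assert m["FPR"] == pytest.approx(1.0 - m["SP"], abs=1e-12)
            assert -1.0 <= m["MCC"] <= 1.0
            assert 0.0 <= m["ACC"] <= 1.0
            if m["SN"] > 0 and m["PPV"] > 0:
                harmonic = 2 * m["SN"] * m["PPV"] / (m["SN"] + m["PPV"])
                assert m["F-measure"] == pytest.approx(harmonic, abs=1e-12)
            checked += 1

    def test_cutoff_at_essential_count_forces_sn_eq_ppv(self):
        # k = |essential| implies TP+FP = TP+FN, hence SN = PPV and SP = NPV
        rng = np.random.default_rng(7)
        for _ in range(20):
            r = random_ranking(60, rng)
            c = confusion_at_cutoff(r, r.n_essential)
            m = classification_metrics(c)
            assert m["SN"] == pytest.approx(m["PPV"], abs=1e-12)
            assert m["SP"] == pytest.approx(m["NPV"], abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        r = make_ranking({"e": 2.0, "f": 1.5, "n": 1.0, "m": 0.5}, {"e", "f"})
        _, auc = roc_auc(r)
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        r = make_ranking({p: 1.0 for p in "abcdef"}, {"a", "b"})
        points, auc = roc_auc(r)
        assert auc == pytest.approx(0.5, abs=1e-12)
        assert (1.0, 1.0) in points  # single diagonal segment endpoint

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(make_ranking({"a": 1.0, "b": 0.0}, {"a", "b"}))

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            r = random_ranking(200, rng)
            _, auc = roc_auc(r)
            assert auc == pytest.approx(mann_whitney_auc(r), abs=1e-12)

    def test_curve_starts_at_origin_ends_at_one_one(self):
        r = random_ranking(50, np.random.default_rng(12))
        points, _ = roc_auc(r)
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)


class TestRocAucTopFraction:
    def test_full_fraction_identical_to_roc_auc(self):
        r = random_ranking(80, np.random.default_rng(3))
        assert roc_auc_top_fraction(r, 1.0) == roc_auc(r)

    def test_single_class_top_raises(self):
        r = make_ranking({"e1": 3.0, "e2": 2.0, "n": 1.0}, {"e1", "e2"})
        with pytest.raises(ValueError):
            roc_auc_top_fraction(r, 0.5)  # top 2 are both essential

    def test_matches_oracle_on_truncated_list(self):
        rng = np.random.default_rng(88)
        r = random_ranking(100, rng)
        m = math.ceil(0.2 * r.n)
        top = r.ranking[:m]
        sub = LabeledRanking(
            ranking=tuple(top),
            essential=frozenset(p for p in top if p in r.essential),
            scores={p: r.scores[p] for p in top},
        )
        _, expected = roc_auc(sub)
        _, got = roc_auc_top_fraction(r, 0.2)
        assert got == pytest.approx(expected, abs=1e-15)


class TestJackknifeAndTopPercent:
    def test_small_example(self):
        r = make_ranking({"e1": 3.0, "n": 2.0, "e2": 1.0}, {"e1", "e2"})
        assert jackknife_curve(r) == [1, 1, 2]

    def test_all_essential_ranking(self):
        r = LabeledRanking(
            ranking=tuple("abcde"),
            essential=frozenset("abcde"),
            scores={p: 1.0 for p in "abcde"},
        )
        assert jackknife_curve(r) == [1, 2, 3, 4, 5]

    def test_nondecreasing_unit_steps_and_terminal_value(self):
        rng = np.random.default_rng(60)
        for _ in range(20):
            r = random_ranking(40, rng)
            curve = jackknife_curve(r)
            steps = np.diff([0] + curve)
            assert set(steps.tolist()) <= {0, 1}
            assert curve[-1] == r.n_essential

    def test_matches_prefix_sum_oracle(self):
        r = random_ranking(60, np.random.default_rng(42))
        indicator = [1 if p in r.essential else 0 for p in r.ranking]
        assert jackknife_curve(r) == list(np.cumsum(indicator))

    def test_top_percent_equals_jackknife_at_ceiling_index(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            r = random_ranking(73, rng)
            curve = jackknife_curve(r)
            counts = top_percent_counts(r, (1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 100.0))
            for p, c in counts.items():
                assert c == curve[math.ceil(p * r.n / 100.0) - 1]
            assert counts[100.0] == r.n_essential

    def test_invalid_percent_rejected(self):
        r = random_ranking(10, np.random.default_rng(1))
        with pytest.raises(ValueError):
            top_percent_counts(r, (0.0,))


class TestOverlapAnalysis:
    def test_identical_tables_full_intersection(self):
        t = ScoreTable("JDC", {f"P{i}": float(i) for i in range(10)})
        rec = overlap_analysis(t, t, {"P9"}, 5)
        assert rec.intersection == 5
        assert rec.a_only == rec.b_only == 0
        assert rec.empty_difference
        assert rec.a_only_essential_pct == 0.0

    def test_disjoint_top_sets(self):
        a = ScoreTable("A", {f"P{i}": float(i) for i in range(10)})
        b = ScoreTable("B", {f"P{i}": float(-i) for i in range(10)})
        rec = overlap_analysis(a, b, set(), 3)
        assert rec.intersection == 0
        assert rec.a_only == rec.b_only == 3

    def test_counts_match_set_arithmetic(self):
        rng = np.random.default_rng(14)
        universe = [f"P{i:03d}" for i in range(50)]
        a = ScoreTable("A", {p: float(rng.random()) for p in universe})
        b = ScoreTable("B", {p: float(rng.random()) for p in universe})
        essential = {p for p in universe if rng.random() < 0.3}
        rec = overlap_analysis(a, b, essential, 15)
        sa, sb = set(a.top(15)), set(b.top(15))
        assert rec.intersection == len(sa & sb)
        assert rec.a_only == len(sa - sb)
        assert rec.b_only_essential == len((sb - sa) & essential)
        if sa - sb:
            assert rec.a_only_essential_pct == pytest.approx(
                100.0 * len((sa - sb) & essential) / len(sa - sb)
            )

    def test_mismatched_universe_rejected(self):
        a = ScoreTable("A", {"x": 1.0})
        b = ScoreTable("B", {"y": 1.0})
        with pytest.raises(ValueError):
            overlap_analysis(a, b, set(), 1)


class TestEssentialList:
    def test_comments_and_blanks_skipped(self, tmp_path):
        p = tmp_path / "ess.txt"
        p.write_text("# reference list\nP1\n\nP2\n# done\n")
        assert read_essential_list(p) == {"P1", "P2"}

    def test_ids_absent_from_ranking_are_dropped(self):
        r = make_ranking({"a": 2.0, "b": 1.0}, {"a", "ghost"})
        assert r.essential == {"a"}
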