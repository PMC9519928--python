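import numpy as np
import pytest
from sklearn.metrics import (average_precision_score, f1_score,
                             matthews_corrcoef, precision_score,
                             recall_score, roc_auc_score)

from mpm.evaluation import (SplitSpec, auc, average_precision, compute_report,
                            make_splits, sample_test_negatives,
                            threshold_metrics, top_n_hits)


def brute_force_auc(scores, labels):
    """Exhaustive pair counting over all positive x negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def sweep_ap(scores, labels):
    """Naive threshold sweep with tied scores grouped."""
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        selected = [l for s, l in zip(scores, labels) if s >= t]
        tp = sum(selected)
        recall = tp / n_pos
        precision = tp / len(selected)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


@pytest.fixture
def pairs():
    return [(f"m{i}", f"d{j}") for i in range(8) for j in range(6)
            if (i + j) % 2 == 0]


class TestSplits:
    def test_cv5_folds_partition_positives(self, pairs):
        specs = make_splits(pairs, "cv5", seed=1)
        tests = [set(s.test_pos) for s in specs]
        assert len(specs) == 5
        union = set().union(*tests)
        assert union == set(pairs)
        for i, a in enumerate(tests):
            for b in tests[i + 1:]:
                assert not a & b
        for s in specs:
            assert not set(s.train_pairs) & set(s.test_pos)

    def test_transductive_entities_seen_in_training(self, pairs):
        spec = make_splits(pairs, "transductive", seed=2)
        train_m = {m for m, _ in spec.train_pairs}
        train_d = {d for _, d in spec.train_pairs}
        assert spec.test_pos
        for m, d in spec.test_pos:
            assert m in train_m and d in train_d
        assert set(spec.train_pairs) | set(spec.test_pos) == set(pairs)

    def test_inductive_disease_exclusion(self, pairs):
        spec = make_splits(pairs, "inductive_disease", seed=3)
        held = set(spec.held_out_diseases)
        assert held
        assert all(d in held for _, d in spec.test_pos)
        assert all(d not in held for _, d in spec.train_pairs)

    def test_same_seed_identical_folds(self, pairs):
        a = make_splits(pairs, "cv5", seed=9)
        b = make_splits(pairs, "cv5", seed=9)
        assert [s.test_pos for s in a] == [s.test_pos for s in b]

    def test_missing_holdout_disease_errors(self, pairs):
        with pytest.raises(ValueError, match="absent"):
            make_splits(pairs, "inductive_disease", seed=0,
                        holdout_diseases=["ghost"])

    def test_leakage_guard_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec(mode="transductive", train_pairs=[("m", "d")],
                      test_pos=[("m", "d")])

    def test_inductive_guard_rejects_seen_disease(self):
        with pytest.raises(ValueError, match="held-out"):
            SplitSpec(mode="inductive_disease",
                      train_pairs=[("m1", "d1")], test_pos=[("m2", "d1")])


class TestTestNegatives:
    def test_ratio_exclusion_and_reproducibility(self, pairs):
        spec = make_splits(pairs, "transductive", seed=4)
        for nr in (1, 2):
            neg = sample_test_negatives(spec, nr=nr, seed=5)
            assert len(neg) == nr * len(spec.test_pos)
            assert not set(neg) & (set(spec.train_pairs) | set(spec.test_pos))
            assert neg == sample_test_negatives(spec, nr=nr, seed=5)

    def test_insufficient_candidates_error(self):
        spec = SplitSpec(mode="transductive", train_pairs=[],
                         test_pos=[("m1", "d1"), ("m1", "d2"),
                                   ("m2", "d1"), ("m2", "d2")])
        with pytest.raises(ValueError, match="candidates"):
            sample_test_negatives(spec, nr=1, seed=0)


class TestAuc:
    def test_perfect_and_all_tied(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.integers(0, 10, size=40) / 10.0  # ties present
            labels = rng.integers(0, 2, size=40)
            labels[:2] = [0, 1]
            assert abs(auc(scores, labels) - brute_force_auc(scores, labels)) < 1e-12

    def test_agrees_with_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(30) / 30.0
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(3 * scores), labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("r,n", [(1, 5), (3, 8), (7, 7)])
    def test_single_positive_closed_form(self, r, n):
        scores = np.linspace(1.0, 0.1, n)
        labels = np.zeros(n, dtype=int)
        labels[r - 1] = 1
        assert average_precision(scores, labels) == pytest.approx(1.0 / r, abs=1e-12)

    def test_matches_naive_sweep_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = (rng.integers(0, 6, size=30) / 5.0).tolist()
            labels = rng.integers(0, 2, size=30).tolist()
            labels[0] = 1
            assert abs(average_precision(scores, labels)
                       - sweep_ap(scores, labels)) < 1e-12

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[0] = 1
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)

    def test_above_prevalence_for_informative_scores(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            labels = rng.integers(0, 2, size=50)
            labels[:2] = [0, 1]
            scores = 0.5 * labels + rng.normal(0, 0.25, size=50)
            ap = average_precision(scores, labels)
            assert ap >= labels.mean() - 1e-9 or auc(scores, labels) < 0.5

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.5], [0])


class TestThresholdMetrics:
    def test_all_positive_predictor_degenerate_row(self):
        scores = [0.9] * 10
        labels = [1] * 5 + [0] * 5
        sn, sp, acc, pre, f1, mcc = threshold_metrics(scores, labels)
        assert (sn, sp, acc) == (1.0, 0.0, 0.5)
        assert mcc == 0.0

    def test_perfect_predictor_all_ones(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [1, 1, 0, 0]
        assert threshold_metrics(scores, labels) == (1, 1, 1, 1, 1, 1)

    def test_matches_reference_formulas(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            scores = rng.random(40)
            labels = rng.integers(0, 2, size=40)
            labels[:2] = [0, 1]
            pred = (scores >= 0.5).astype(int)
            sn, sp, acc, pre, f1, mcc = threshold_metrics(scores, labels)
            assert sn == pytest.approx(recall_score(labels, pred, zero_division=0), abs=1e-12)
            assert pre == pytest.approx(precision_score(labels, pred, zero_division=0), abs=1e-12)
            assert f1 == pytest.approx(f1_score(labels, pred, zero_division=0), abs=1e-12)
            assert mcc == pytest.approx(matthews_corrcoef(labels, pred), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            threshold_metrics([0.2, 0.9], [1, 1])


class TestTopN:
    def test_all_positives_ranked_first(self):
        scores = np.concatenate([np.linspace(1, 0.9, 100), np.linspace(0.5, 0, 100)])
        labels = np.array([1] * 100 + [0] * 100)
        assert top_n_hits(scores, labels, n=100) == 100

    def test_no_positives_in_top(self):
        assert top_n_hits([0.9, 0.8, 0.1], [0, 0, 1], n=2) == 0

    def test_counting_oracle_on_constructed_instance(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 20, size=150) / 20.0
        labels = rng.integers(0, 2, size=150)
        ids = [f"p{i:03d}" for i in range(150)]
        order = sorted(range(150), key=lambda i: (-scores[i], ids[i]))
        oracle = sum(labels[i] for i in order[:100])
        assert top_n_hits(scores, labels, n=100, ids=ids) == oracle

    def test_truncates_when_fewer_pairs_than_n(self):
        assert top_n_hits([0.9, 0.1], [1, 1], n=100) == 2


def test_compute_report_shapes_and_ranges():
    rng = np.random.default_rng(8)
    scores = rng.random(60)
    labels = rng.integers(0, 2, size=60)
    labels[:2] = [0, 1]
    report = compute_report(scores, labels, nr=5)
    d = report.to_dict()
    for key in ("AUC", "AP", "SN", "SP", "ACC", "Pre", "F1"):
        assert 0.0 <= d[key] <= 1.0
    assert -1.0 <= d["MCC"] <= 1.0
    assert d["negative_ratio"] == 5
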