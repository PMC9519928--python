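"""Split construction, test-time negative sampling, and the metric suite.

Three evaluation regimes:

* ``cv5`` — 5-fold partition of the known positive pairs;
* ``transductive`` — held-out positives whose miRNA and disease both still
  appear in training (partially observed entities);
* ``inductive_disease`` — all pairs of the held-out disease(s) removed from
  training, so test diseases are completely new to the classifier.

Metrics: AUC as the rank-sum probability P(score_pos > score_neg) + half
ties; AP as the discrete (non-interpolated) precision-recall sum with tied
scores entering as one group; confusion-matrix metrics at a fixed threshold
with the 0/0 -> 0 convention (an all-positive predictor on balanced data
gives SN=1, SP=0, ACC=0.5, MCC=0); Top-N hit counts with deterministic
boundary tie-breaking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

Pair = tuple[str, str]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    mode: str
    train_pairs: list[Pair]
    test_pos: list[Pair]
    test_neg: list[Pair] = field(default_factory=list)
    seed: int = 0
    held_out_diseases: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.train_pairs) & set(self.test_pos)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
        if self.mode == "inductive_disease":
            train_diseases = {d for _, d in self.train_pairs}
            leaked = {d for _, d in self.test_pos} & train_diseases
            if leaked:
                raise ValueError(f"held-out diseases appear in training: {sorted(leaked)}")

    @property
    def manifest_hash(self) -> str:
        payload = json.dumps({
            "mode": self.mode,
            "train": sorted(self.train_pairs),
            "test_pos": sorted(self.test_pos),
            "test_neg": sorted(self.test_neg),
            "seed": self.seed,
        })
        return hashlib.sha256(payload.encode()).hexdigest()


def make_splits(positives, mode: str, seed: int, k: int = 5,
                test_fraction: float = 0.2,
                holdout_diseases: list[str] | None = None,
                n_holdout_diseases: int | None = None):
    """Build SplitSpec(s) for the requested evaluation mode.

    Returns a list of k specs for ``cv5`` and a single spec otherwise.
    """
    positives = sorted(set(positives))
    if not positives:
        raise ValueError("no positive pairs to split")
    rng = np.random.default_rng(seed)

    if mode == "cv5":
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, k)
        specs = []
        for f in folds:
            test = [positives[i] for i in f]
            train = [p for p in positives if p not in set(test)]
            specs.append(SplitSpec(mode=mode, train_pairs=train, test_pos=test, seed=seed))
        return specs

    if mode == "transductive":
        perm = rng.permutation(len(positives))
        n_test = max(1, int(round(test_fraction * len(positives))))
        candidate = {positives[i] for i in perm[:n_test]}
        train = [p for p in positives if p not in candidate]
        train_m = {m for m, _ in train}
        train_d = {d for _, d in train}
        test = sorted(p for p in candidate if p[0] in train_m and p[1] in train_d)
        train += sorted(candidate - set(test))  # unsatisfiable candidates stay in training
        return SplitSpec(mode=mode, train_pairs=sorted(train), test_pos=test, seed=seed)

    if mode == "inductive_disease":
        diseases = sorted({d for _, d in positives})
        if holdout_diseases is None:
            n_hold = n_holdout_diseases or max(1, int(round(0.2 * len(diseases))))
            holdout_diseases = sorted(
                rng.choice(diseases, size=min(n_hold, len(diseases)), replace=False))
        missing = set(holdout_diseases) - set(diseases)
        if missing:
            raise ValueError(f"held-out diseases absent from dataset: {sorted(missing)}")
        hold = set(holdout_diseases)
        train = [p for p in positives if p[1] not in hold]
        test = [p for p in positives if p[1] in hold]
        return SplitSpec(mode=mode, train_pairs=train, test_pos=test, seed=seed,
                         held_out_diseases=sorted(hold))

    raise ValueError(f"unknown split mode: {mode!r}")


def sample_test_negatives(split: SplitSpec, nr: int, seed: int,
                          all_positives=None) -> list[Pair]:
    """Uniform unknown pairs within the test entity universe, ratio nr:1.

    Candidates are pairs among the miRNAs and diseases visible in the test
    positives, excluding every known positive (train and test).
    """
    known = set(split.train_pairs) | set(split.test_pos)
    if all_positives is not None:
        known |= set(all_positives)
    mirnas = sorted({m for m, _ in split.test_pos})
    diseases = sorted({d for _, d in split.test_pos})
    candidates = [(m, d) for m in mirnas for d in diseases if (m, d) not in known]
    need = nr * len(split.test_pos)
    if len(candidates) < need:
        raise ValueError(f"need {need} negative candidates, only {len(candidates)} available")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(candidates), size=need, replace=False)
    return [candidates[i] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Rank-sum AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """Discrete AP: sum of (R_k - R_{k-1}) * P_k over the descending-score
    sweep, tied scores entering together."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AP requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += int((1 - y[i:j]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def threshold_metrics(scores, labels, threshold: float = 0.5
                      ) -> tuple[float, float, float, float, float, float]:
    """(SN, SP, ACC, Pre, F1, MCC) of the confusion matrix at ``threshold``.

    Degenerate denominators yield 0 (so an all-positive predictor reports
    MCC = 0 rather than NaN).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("threshold metrics require both classes")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * sn / (pre + sn) if pre + sn else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return sn, sp, acc, pre, f1, float(mcc)


def top_n_hits(scores, labels, n: int = 100, ids=None) -> int:
    """True positives among the n highest scores; boundary ties resolve by
    stable id (or input-index) order."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    keys = list(map(str, ids)) if ids is not None else [f"{i:09d}" for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], keys[i]))
    n = min(n, len(order))
    return int(sum(labels[i] for i in order[:n]))


@dataclass
class MetricReport:
    AUC: float
    AP: float
    SN: float
    SP: float
    ACC: float
    Pre: float
    F1: float
    MCC: float
    Top100: int | None = None
    negative_ratio: int = 1
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


def compute_report(scores, labels, nr: int = 1, threshold: float = 0.5,
                   top_n: int | None = 100, ids=None) -> MetricReport:
    sn, sp, acc, pre, f1, mcc = threshold_metrics(scores, labels, threshold)
    return MetricReport(
        AUC=auc(scores, labels),
        AP=average_precision(scores, labels),
        SN=sn, SP=sp, ACC=acc, Pre=pre, F1=f1, MCC=mcc,
        Top100=top_n_hits(scores, labels, top_n, ids=ids) if top_n else None,
        negative_ratio=nr, threshold=threshold,
    )
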