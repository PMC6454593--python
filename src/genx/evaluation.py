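"""Multi-class evaluation: macro metrics, CV splitting, bootstrap, mu tuning.

Macro precision and recall are unweighted means over classes; the macro
F1 is the harmonic mean of those two macro values (not the mean of
per-class F1 scores). Classes with an empty denominator score 0 by
default so that averaging over all n classes stays well defined.
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class ConfusionMatrix:
    """Square gold x predicted tally over an ordered class list."""

    classes: list[str]
    counts: np.ndarray

    @classmethod
    def from_labels(
        cls,
        gold: Sequence[str],
        predicted: Sequence[str],
        classes: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        if len(gold) != len(predicted):
            raise ValueError("gold and predicted must have equal length")
        if classes is None:
            classes = sorted(set(gold) | set(predicted))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for g, p in zip(gold, predicted):
            counts[index[g], index[p]] += 1
        return cls(list(classes), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _idx(self, c: str) -> int:
        try:
            return self.classes.index(c)
        except ValueError:
            raise KeyError(f"unknown class {c!r}") from None

    def tp(self, c: str) -> int:
        i = self._idx(c)
        return int(self.counts[i, i])

    def fp(self, c: str) -> int:
        i = self._idx(c)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, c: str) -> int:
        i = self._idx(c)
        return int(self.counts[i, :].sum() - self.counts[i, i])


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def per_class_metrics(
    cm: ConfusionMatrix, c: str, beta: float = 1.0
) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F_beta for one class."""
    tp, fp, fn = cm.tp(c), cm.fp(c), cm.fn(c)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f = _safe_div(
        (1 + beta**2) * precision * recall, beta**2 * precision + recall
    )
    return precision, recall, f


@dataclass
class EvalReport:
    per_class: dict[str, tuple[float, float, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_classes: int
    beta: float = 1.0

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {"precision": p, "recall": r, "f": f}
                for c, (p, r, f) in self.per_class.items()
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_classes": self.n_classes,
            "beta": self.beta,
        }

    def render(self) -> str:
        lines = [f"{'class':40s} {'P':>8s} {'R':>8s} {'F':>8s}"]
        for c, (p, r, f) in sorted(self.per_class.items()):
            lines.append(f"{c:40s} {p:8.3f} {r:8.3f} {f:8.3f}")
        lines.append(
            f"{'macro':40s} {self.macro_precision:8.3f} "
            f"{self.macro_recall:8.3f} {self.macro_f1:8.3f}"
        )
        return "\n".join(lines)


def macro_metrics(cm: ConfusionMatrix, beta: float = 1.0) -> EvalReport:
    """Macro P/R as unweighted class means; macro F1 as their harmonic mean."""
    if not cm.classes or cm.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")
    per_class = {c: per_class_metrics(cm, c, beta) for c in cm.classes}
    macro_p = sum(p for p, _, _ in per_class.values()) / len(cm.classes)
    macro_r = sum(r for _, r, _ in per_class.values()) / len(cm.classes)
    macro_f1 = _safe_div(2 * macro_p * macro_r, macro_p + macro_r)
    return EvalReport(per_class, macro_p, macro_r, macro_f1, len(cm.classes), beta)


@dataclass
class CvConfig:
    k: int = 10
    seed: int = 0
    mu_grid: tuple[float, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def stratified_kfold(
    labels: Sequence[str], k: int, seed: int = 0
) -> list[np.ndarray]:
    """Disjoint, covering folds with sizes differing by at most one.

    Members of each class are shuffled and dealt round-robin; the dealing
    cursor carries over between classes so overall fold sizes stay even
    while each class spreads as evenly as it can.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(int(i))
            cursor += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def bootstrap_tg(tg: Sequence, seed: int = 0) -> list:
    """Resample the positive set with replacement to its own size."""
    if not tg:
        raise ValueError("cannot bootstrap an empty dataset")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(tg), size=len(tg))
    return [copy.deepcopy(tg[int(i)]) for i in picks]


def build_dataset(
    tg: Sequence,
    negatives: Sequence,
    n_neg: int,
    seed: int = 0,
    negative_label: str = "Biological",
) -> list:
    """Positives plus n_neg sampled negatives (labelled 'Biological')."""
    if n_neg > len(negatives):
        raise ValueError(f"requested {n_neg} negatives, only {len(negatives)} available")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(negatives), size=n_neg, replace=False) if n_neg else []
    out = [copy.deepcopy(t) for t in tg]
    for i in picks:
        neg = copy.deepcopy(negatives[int(i)])
        if getattr(neg, "gold_label", None) is None:
            neg.gold_label = negative_label
        out.append(neg)
    return out


@dataclass
class MuTuningResult:
    per_round: list[float]
    chosen: float
    f1_by_mu: list[dict[float, float]] = field(default_factory=list)


def tune_mu(
    gold: Sequence[str],
    predict: Callable[[np.ndarray, float], list[str]],
    cfg: CvConfig,
    classes: Sequence[str] | None = None,
) -> MuTuningResult:
    """Per-fold grid search for mu on the training portions.

    ``predict(indices, mu)`` must return predicted labels for the given
    record indices. Each round's winner is the smallest mu maximizing
    macro F1 on that round's training split; the global choice is the
    modal winner (smallest on ties).
    """
    folds = stratified_kfold(gold, cfg.k, cfg.seed)
    gold = np.asarray(gold, dtype=object)
    winners: list[float] = []
    history: list[dict[float, float]] = []
    for fold in folds:
        train = np.setdiff1d(np.arange(len(gold)), fold)
        scores: dict[float, float] = {}
        for mu in cfg.mu_grid:
            pred = predict(train, mu)
            cm = ConfusionMatrix.from_labels(list(gold[train]), pred, classes)
            scores[mu] = macro_metrics(cm).macro_f1
        best = max(scores.values())
        winners.append(min(mu for mu, f1 in scores.items() if f1 == best))
        history.append(scores)
    tally = Counter(winners)
    top = max(tally.values())
    chosen = min(mu for mu, c in tally.items() if c == top)
    return MuTuningResult(winners, chosen, history)
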