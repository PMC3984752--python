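"""Evaluation: per-class sensitivity/specificity, agreement, cross-validation.

Metrics are one-vs-rest per risk class.  Sensitivity is TP/(TP+FN) over
cases carrying the class; specificity is TN/(TN+FP) over cases not carrying
it; classes with no positives (or no negatives) in the evaluated set yield
``None`` (not applicable) rather than a fabricated rate.  Agreement is the
exact-match fraction between model and physician labels.

``cross_validate`` follows a rounds-of-stratified-k-fold protocol: each
round reshuffles, splits the cohort into class-stratified folds, re-derives
the fuzzy partitions from the training split only (no leakage), mines a rule
base on it, and scores the held-out fold.  Confusion counts are pooled over
all episodes.  ``resubstitution`` mines and scores on the full cohort; the
two modes are labelled distinctly in their reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .classify import Prediction, predict_batch
from .data import Dataset, RiskLabel, RISK_LEVELS
from .ga import GAConfig, mine_all
from .partition import partition_all


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts per risk class."""

    counts: dict[RiskLabel, dict[str, int]]

    def __getitem__(self, cls: RiskLabel) -> dict[str, int]:
        return self.counts[cls]

    def total(self, cls: RiskLabel) -> int:
        c = self.counts[cls]
        return c["TP"] + c["FN"] + c["TN"] + c["FP"]

    def add(self, other: "ConfusionCounts") -> None:
        for cls in RISK_LEVELS:
            for k in ("TP", "FN", "TN", "FP"):
                self.counts[cls][k] += other.counts[cls][k]

    @classmethod
    def empty(cls) -> "ConfusionCounts":
        return cls({c: {"TP": 0, "FN": 0, "TN": 0, "FP": 0} for c in RISK_LEVELS})


def confusion(
    preds: Sequence[Prediction | RiskLabel], truth: Sequence[RiskLabel]
) -> ConfusionCounts:
    """Tally one-vs-rest counts for each class."""
    pred_labels = [p.label if isinstance(p, Prediction) else p for p in preds]
    if len(pred_labels) != len(truth):
        raise ValueError("predictions and truth differ in length")
    if not truth:
        raise ValueError("nothing to evaluate")
    cc = ConfusionCounts.empty()
    for p, t in zip(pred_labels, truth):
        for cls in RISK_LEVELS:
            if t is cls:
                cc[cls]["TP" if p is cls else "FN"] += 1
            else:
                cc[cls]["FP" if p is cls else "TN"] += 1
    return cc


def sensitivity(cc: ConfusionCounts, cls: RiskLabel) -> float | None:
    """TP / (TP + FN); None when the class has no positive cases."""
    c = cc[cls]
    pos = c["TP"] + c["FN"]
    return c["TP"] / pos if pos else None


def specificity(cc: ConfusionCounts, cls: RiskLabel) -> float | None:
    """TN / (TN + FP); None when the class has no negative cases."""
    c = cc[cls]
    neg = c["TN"] + c["FP"]
    return c["TN"] / neg if neg else None


def agreement(
    preds: Sequence[Prediction | RiskLabel], truth: Sequence[RiskLabel]
) -> tuple[int, float]:
    """Exact-match count and fraction between model and physician labels."""
    pred_labels = [p.label if isinstance(p, Prediction) else p for p in preds]
    if len(pred_labels) != len(truth):
        raise ValueError("predictions and truth differ in length")
    if not truth:
        raise ValueError("nothing to evaluate")
    matches = sum(p is t for p, t in zip(pred_labels, truth))
    return matches, matches / len(truth)


@dataclass
class EvalReport:
    """Pooled evaluation results plus per-episode detail."""

    mode: str
    confusion: ConfusionCounts
    sensitivity: dict[RiskLabel, float | None]
    specificity: dict[RiskLabel, float | None]
    agreement_count: int
    agreement_fraction: float
    n_evaluated: int
    episodes: list[dict] = field(default_factory=list)
    not_applicable: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_evaluated": self.n_evaluated,
            "agreement": {
                "count": self.agreement_count,
                "fraction": self.agreement_fraction,
            },
            "confusion": {
                cls.level: dict(self.confusion[cls]) for cls in RISK_LEVELS
            },
            "sensitivity": {
                cls.level: self.sensitivity[cls] for cls in RISK_LEVELS
            },
            "specificity": {
                cls.level: self.specificity[cls] for cls in RISK_LEVELS
            },
            "not_applicable": self.not_applicable,
            "episodes": self.episodes,
        }


def _report(
    mode: str,
    preds: list[RiskLabel],
    truth: list[RiskLabel],
    episodes: list[dict],
) -> EvalReport:
    cc = confusion(preds, truth)
    sens = {cls: sensitivity(cc, cls) for cls in RISK_LEVELS}
    spec = {cls: specificity(cc, cls) for cls in RISK_LEVELS}
    count, frac = agreement(preds, truth)
    return EvalReport(
        mode=mode,
        confusion=cc,
        sensitivity=sens,
        specificity=spec,
        agreement_count=count,
        agreement_fraction=frac,
        n_evaluated=len(truth),
        episodes=episodes,
        not_applicable=sum(v is None for v in sens.values())
        + sum(v is None for v in spec.values()),
    )


def stratified_folds(
    labels: Sequence[RiskLabel], folds: int, rng: np.random.Generator
) -> list[list[int]]:
    """Class-stratified fold assignment by shuffled round-robin deal.

    Classes smaller than the fold count simply land in a subset of folds
    (the deal never fails, unlike split schemes that require every class to
    fill every fold).  Folds are disjoint and cover every index.
    """
    assignment: list[list[int]] = [[] for _ in range(folds)]
    for cls in RISK_LEVELS:
        idx = [i for i, lab in enumerate(labels) if lab is cls]
        idx = [idx[i] for i in rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            assignment[pos % folds].append(i)
    return [sorted(f) for f in assignment]


def cross_validate(
    d: Dataset,
    epsilon: float | Mapping[str, float] | None = None,
    ga_config: GAConfig | None = None,
    folds: int = 10,
    rounds: int = 10,
    seed: int = 0,
    eval_labels: Sequence[RiskLabel] | None = None,
) -> EvalReport:
    """Rounds of stratified k-fold cross-validation of the full pipeline.

    Every episode re-derives partitions and mines rules from its training
    split only, then classifies the held-out fold.  Results are pooled over
    all ``rounds * folds`` episodes.

    ``eval_labels`` optionally supplies a different ground truth for scoring
    the held-out folds (training always uses the dataset's own labels).
    Recovery studies on synthetic cohorts pass the noise-free planted labels
    here, so the report measures recovery of the generating process rather
    than of the injected label noise.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(d) < folds:
        raise ValueError("fewer cases than folds")
    cfg = ga_config or GAConfig()
    labels = d.labels()
    truth_labels = list(eval_labels) if eval_labels is not None else labels
    if len(truth_labels) != len(d):
        raise ValueError("eval_labels length must match the dataset")
    all_preds: list[RiskLabel] = []
    all_truth: list[RiskLabel] = []
    episodes: list[dict] = []
    for rnd in range(rounds):
        fold_rng = np.random.default_rng(
            int(np.random.SeedSequence([seed, rnd]).generate_state(1)[0] % 2**31)
        )
        fold_sets = stratified_folds(labels, folds, fold_rng)
        for k, test_idx in enumerate(fold_sets):
            if not test_idx:
                continue
            train_idx = [i for i in range(len(d)) if i not in set(test_idx)]
            train = d.subset(train_idx)
            test = d.subset(test_idx)
            parts = partition_all(train, epsilon=epsilon)
            ep_seed = int(
                np.random.SeedSequence([seed, rnd, k]).generate_state(1)[0] % 2**31
            )
            rb = mine_all(train, parts, replace(cfg, seed=ep_seed))
            preds = predict_batch(rb, test)
            truth = [truth_labels[i] for i in test_idx]
            pred_labels = [p.label for p in preds]
            all_preds.extend(pred_labels)
            all_truth.extend(truth)
            matches = sum(p is t for p, t in zip(pred_labels, truth))
            episodes.append(
                {
                    "round": rnd,
                    "fold": k,
                    "n_test": len(test_idx),
                    "n_match": matches,
                    "seed": ep_seed,
                }
            )
    return _report("cross-validation", all_preds, all_truth, episodes)


def resubstitution(
    d: Dataset,
    epsilon: float | Mapping[str, float] | None = None,
    ga_config: GAConfig | None = None,
) -> EvalReport:
    """Mine on the full cohort and score the same cohort (optimistic mode)."""
    cfg = ga_config or GAConfig()
    parts = partition_all(d, epsilon=epsilon)
    rb = mine_all(d, parts, cfg)
    preds = predict_batch(rb, d)
    return _report(
        "resubstitution", [p.label for p in preds], d.labels(), episodes=[]
    )
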