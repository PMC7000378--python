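"""Model evaluation, test-set subgroup cross-validation, and the shuffle test.

Metrics follow the clinical convention with the case class positive:
accuracy, sensitivity, specificity, PPV and NPV, kept at full precision and
also printed-style at one decimal (truncation, which is how the study's
result tables round all but one entry; see ``solve_confusion`` for the
matching rule used when reconstructing confusion matrices from printed
values).  The shuffle test permutes group labels, re-splits, refits the
logistic model over the fixed selected-region set, and scores the shuffled
test rows; the empirical p is the fraction of permutation accuracies at or
above the observed accuracy, with an escalation stage when no exceedance is
seen.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlasfeat import FeatureTable
from .model import FittedModel, fit_logistic, stratified_split

__all__ = [
    "EvaluationReport",
    "ShuffleTestResult",
    "evaluate",
    "solve_confusion",
    "subgroup_cv",
    "shuffle_test",
    "empirical_p",
    "truncate1",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


def truncate1(x: float | None) -> float | None:
    """Truncate (floor) a percentage to one decimal, printed-table style."""
    if x is None:
        return None
    return math.floor(x * 10.0 + 1e-9) / 10.0


def _ratio(num: int, den: int) -> float | None:
    """Percentage num/den, or None when the denominator is zero (undefined)."""
    return None if den == 0 else 100.0 * num / den


@dataclass
class EvaluationReport:
    """Confusion counts and the five derived metrics (percent, case = positive)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty test set")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float | None:
        return _ratio(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fn)

    def metrics(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def truncated(self) -> dict[str, float | None]:
        return {m: truncate1(v) for m, v in self.metrics().items()}

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                "metrics": self.metrics(), "metrics_printed": self.truncated()}

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvaluationReport":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("label/prediction length mismatch")
        return cls(tp=int(((yt == 1) & (yp == 1)).sum()),
                   fn=int(((yt == 1) & (yp == 0)).sum()),
                   fp=int(((yt == 0) & (yp == 1)).sum()),
                   tn=int(((yt == 0) & (yp == 0)).sum()))


def evaluate(model: FittedModel, test_features: FeatureTable,
             test_labels: pd.Series) -> EvaluationReport:
    """Score the fitted model on held-out rows (p >= 0.5 classifies as case)."""
    if test_features.n_subjects == 0:
        raise ValueError("empty test set")
    pred = model.predict(test_features)
    y = pd.Series(test_labels).loc[pred.index]
    return EvaluationReport.from_predictions(y.to_numpy(), pred.to_numpy())


def _matches_printed(value: float | None, printed: float) -> bool:
    # a printed one-decimal value may be the truncation or the rounding of the
    # full-precision metric (published tables mix both)
    if value is None:
        return False
    return (truncate1(value) == printed
            or math.floor(value * 10.0 + 0.5) / 10.0 == printed)


def solve_confusion(metrics: dict[str, float],
                    max_n: int = 30) -> list[tuple[int, int, int, int]]:
    """All integer confusion matrices (total <= max_n) matching printed metrics.

    ``metrics`` gives any subset of accuracy/sensitivity/specificity/ppv/npv as
    printed percentages; a quadruple matches when every given metric's
    one-decimal truncation or rounding equals the printed value.  Exhaustive
    enumeration; an empty list is a valid outcome.
    """
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric names: {sorted(unknown)}")
    r = np.arange(max_n + 1)
    tp, fn, fp, tn = (a.ravel() for a in np.meshgrid(r, r, r, r, indexing="ij"))
    total = tp + fn + fp + tn
    keep = (total > 0) & (total <= max_n)
    tp, fn, fp, tn, total = tp[keep], fn[keep], fp[keep], tn[keep], total[keep]

    def pct(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, 100.0 * num / den, np.nan)

    computed = {"accuracy": pct(tp + tn, total),
                "sensitivity": pct(tp, tp + fn),
                "specificity": pct(tn, tn + fp),
                "ppv": pct(tp, tp + fp),
                "npv": pct(tn, tn + fn)}
    ok = np.ones(len(tp), dtype=bool)
    for m, printed in metrics.items():
        v = computed[m]
        trunc = np.floor(v * 10.0 + 1e-9) / 10.0
        rounded = np.floor(v * 10.0 + 0.5) / 10.0
        ok &= ~np.isnan(v) & ((trunc == printed) | (rounded == printed))
    return [tuple(int(x) for x in q)
            for q in zip(tp[ok], fn[ok], fp[ok], tn[ok])]


def subgroup_cv(model: FittedModel, test_features: FeatureTable,
                test_labels: pd.Series, k: int = 10,
                seed: int = 0) -> tuple[float, list[float]]:
    """Evaluate the FIXED model on k non-overlapping test-set subgroups.

    The test set is partitioned (seeded, sizes differing by at most one) and
    the already-fitted model scored on each part; returns (mean accuracy %,
    per-subgroup accuracies %).  The mean is the plain average over subgroups,
    so with unequal sizes it can differ slightly from the pooled accuracy;
    the size-weighted average always equals the pooled test accuracy.
    """
    n = test_features.n_subjects
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} exceeds the test-set size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    pred = model.predict(test_features)
    y = pd.Series(test_labels).loc[pred.index].to_numpy()
    yp = pred.to_numpy()
    accs = [100.0 * float((yp[f] == y[f]).mean()) for f in folds]
    return float(np.mean(accs)), accs


def empirical_p(n_exceed: int, n_runs: int) -> float:
    """Raw permutation p: fraction of runs with accuracy >= observed."""
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    return n_exceed / n_runs


@dataclass
class ShuffleTestResult:
    """Permutation-null accuracy distribution and its empirical p."""

    observed_accuracy: float  # percent
    n_runs: int
    shuffled_accuracies: list[float] = field(repr=False)
    empirical_p: float = 0.0
    empirical_p_add_one: float = 0.0
    mean: float = 0.0
    mode: float = 0.0
    max: float = 0.0
    escalated: bool = False
    significant: bool = False

    def __post_init__(self) -> None:
        if len(self.shuffled_accuracies) != self.n_runs:
            raise ValueError("n_runs must equal the number of shuffled accuracies")
        if not 0.0 <= self.empirical_p <= 1.0:
            raise ValueError("empirical_p must be in [0, 1]")

    @classmethod
    def from_accuracies(cls, observed: float, accs: list[float],
                        escalated: bool) -> "ShuffleTestResult":
        n = len(accs)
        exceed = sum(a >= observed - 1e-9 for a in accs)
        p = empirical_p(exceed, n)
        # mode over the exact attainable discrete accuracies (k / test size),
        # ties broken toward the smaller value
        counts = Counter(round(a, 9) for a in accs)
        top = max(counts.values())
        mode = min(a for a, c in counts.items() if c == top)
        return cls(observed_accuracy=observed, n_runs=n,
                   shuffled_accuracies=list(accs), empirical_p=p,
                   empirical_p_add_one=(exceed + 1) / (n + 1),
                   mean=float(np.mean(accs)), mode=float(mode),
                   max=float(np.max(accs)), escalated=escalated,
                   significant=p < 0.05)

    def to_dict(self) -> dict:
        return {"observed_accuracy": self.observed_accuracy,
                "n_runs": self.n_runs, "empirical_p": self.empirical_p,
                "empirical_p_add_one": self.empirical_p_add_one,
                "mean": self.mean, "mode": self.mode, "max": self.max,
                "escalated": self.escalated, "significant": self.significant}


def _one_shuffle_accuracy(features: FeatureTable, y_shuffled: pd.Series,
                          selected_regions: list[int], ratio: float,
                          split_seed: int, penalty: float | None,
                          reselect: bool, rfe_target: int | None,
                          maxiter: int) -> float:
    from .screen import rfe_select  # local import to avoid a cycle

    split = stratified_split(y_shuffled, ratio=ratio, seed=split_seed)
    train = features.subset(split.train_ids)
    test = features.subset(split.test_ids)
    y_train = y_shuffled.loc[split.train_ids]
    regions = selected_regions
    if reselect:
        target = rfe_target or len(selected_regions)
        regions = rfe_select(train, y_train, target, seed=split_seed,
                             penalty=penalty).selected_region_ids
    mdl = fit_logistic(train, y_train, selected_region_ids=regions,
                       penalty=penalty, maxiter=maxiter)
    rep = evaluate(mdl, test, y_shuffled.loc[split.test_ids])
    return float(rep.accuracy)


def shuffle_test(features: FeatureTable, labels: pd.Series,
                 selected_regions: list[int], observed_accuracy: float,
                 n_runs: int = 1000, escalation_runs: int = 10_000,
                 ratio: float = 0.7, seed: int = 0,
                 penalty: float | None = None, reselect: bool = False,
                 rfe_target: int | None = None,
                 maxiter: int = 60) -> ShuffleTestResult:
    """Label-shuffle permutation null for the observed classification accuracy.

    Each run permutes the group labels, draws a stratified ``ratio`` split of
    the shuffled sample, refits the logistic model on the shuffled training
    rows over the FIXED selected-region set (``reselect=True`` reruns RFE per
    shuffle instead), and scores the shuffled test rows.  If no run reaches
    the observed accuracy after ``n_runs``, ``escalation_runs`` more are
    executed and the empirical p recomputed over every run performed.
    Significance is declared at p < 0.05.
    """
    if n_runs < 100:
        warnings.warn(f"n_runs = {n_runs} < 100 gives an unstable empirical p")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)

    def run_batch(k: int) -> list[float]:
        accs = []
        for _ in range(k):
            y_shuf = pd.Series(rng.permutation(labels.to_numpy()),
                               index=labels.index)
            split_seed = int(rng.integers(0, 2 ** 31 - 1))
            accs.append(_one_shuffle_accuracy(
                features, y_shuf, selected_regions, ratio, split_seed,
                penalty, reselect, rfe_target, maxiter))
        return accs

    accs = run_batch(n_runs)
    escalated = False
    if not any(a >= observed_accuracy - 1e-9 for a in accs) and escalation_runs > 0:
        escalated = True
        accs.extend(run_batch(escalation_runs))
    return ShuffleTestResult.from_accuracies(observed_accuracy, accs, escalated)
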