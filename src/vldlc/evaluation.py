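"""Diagnostic-test evaluation: ROC analysis, cut-points, confusion metrics.

The ROC machinery is written out explicitly (threshold grid of midpoints
between adjacent distinct scores plus infinite sentinels; a call is positive
when ``score >= threshold``; AUC via the Mann-Whitney rank statistic with
ties counted one half) so that every quantity matches hand pair-counting
exactly.  The operating cut-point follows the Youden-type rule: the
threshold with the greatest sensitivity + specificity, ties broken toward
the higher threshold (higher specificity) — sensible for a condition with
~0.5% prevalence, where false positives dominate the error cost.

Confusion summaries include the Matthews correlation coefficient (MCC, with
the zero-margin convention MCC = 0) and its normalized form
``(MCC + 1) / 2``, which rescales to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .phenotyping import PhenotypeCall

__all__ = [
    "RocResult",
    "ConfusionMetrics",
    "GroupComparison",
    "roc_curve",
    "optimal_cutpoint",
    "match_operating_point",
    "confusion_metrics",
    "compare_groups",
]

LabelLike = Union[bool, int, str]


def _as_bool_labels(labels: Iterable[LabelLike]) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in ("positive", "negative"):
                raise ValueError(f"label must be positive/negative, got {lab!r}")
            out.append(lab == "positive")
        else:
            out.append(bool(lab))
    return np.asarray(out, dtype=bool)


@dataclass(frozen=True)
class RocResult:
    """A full ROC curve with its selected operating point.

    ``thresholds`` ascend and include -inf/+inf sentinels; ``sens`` is
    non-increasing and ``spec`` non-decreasing along them.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    optimal_cutpoint: float
    optimal_sens: float
    optimal_spec: float
    n_pos: int
    n_neg: int

    @property
    def degenerate(self) -> bool:
        """True when no finite threshold exists (all scores tied)."""
        return not np.any(np.isfinite(self.thresholds))


def _operating_points(
    pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # positive call when score >= threshold; plain count/size arithmetic so
    # that tied sens+spec sums compare exactly across code paths
    sens = (pos.size - np.searchsorted(pos_sorted, thresholds, side="left")) / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    return sens, spec


def _select_optimum(
    thresholds: np.ndarray, sens: np.ndarray, spec: np.ndarray
) -> int:
    total = sens + spec
    best = np.max(total)
    # ties broken toward the highest threshold (highest specificity)
    return int(np.flatnonzero(total == best)[-1])


def roc_curve(
    scores: Sequence[float], labels: Sequence[LabelLike]
) -> RocResult:
    """Build the ROC curve of a score against binary truth.

    Thresholds are the midpoints between adjacent distinct scores, plus
    -inf (everything positive) and +inf (nothing positive) sentinels.  AUC
    is the probability that a random positive outscores a random negative,
    ties counted one half (the Mann-Whitney statistic).
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    y = _as_bool_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    sens, spec = _operating_points(pos, neg, thresholds)

    ranks = stats.rankdata(s)  # average ranks: ties counted 1/2
    auc = float((ranks[y].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))

    j = _select_optimum(thresholds, sens, spec)
    if mids.size == 0:
        warnings.warn(
            "all scores identical: degenerate ROC curve, returning a sentinel "
            "cut-point", stacklevel=2,
        )
    return RocResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        optimal_cutpoint=float(thresholds[j]),
        optimal_sens=float(sens[j]),
        optimal_spec=float(spec[j]),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def optimal_cutpoint(roc: RocResult) -> float:
    """The threshold maximising sensitivity + specificity.

    Equivalent to an exhaustive scan over the threshold grid; ties resolve
    to the higher threshold.  On a degenerate curve (all scores tied) the
    +inf sentinel is returned with a warning.
    """
    if roc.degenerate:
        warnings.warn("degenerate ROC curve: returning sentinel threshold", stacklevel=2)
    j = _select_optimum(roc.thresholds, roc.sens, roc.spec)
    return float(roc.thresholds[j])


def match_operating_point(roc: RocResult, target: str, value: float) -> float:
    """The threshold attaining a required sensitivity or specificity.

    For a sensitivity target: the largest threshold with sens >= value
    (i.e. the most specific operating point that still reaches the target).
    For a specificity target: the smallest threshold with spec >= value.
    Raises with the curve's achievable extreme when the target is out of
    reach.
    """
    if target == "sensitivity":
        ok = np.flatnonzero(roc.sens >= value)
        if ok.size == 0:
            raise ValueError(
                f"sensitivity {value} unachievable; curve maximum is {roc.sens.max()}"
            )
        return float(roc.thresholds[ok[-1]])
    if target == "specificity":
        ok = np.flatnonzero(roc.spec >= value)
        if ok.size == 0:
            raise ValueError(
                f"specificity {value} unachievable; curve maximum is {roc.spec.max()}"
            )
        return float(roc.thresholds[ok[0]])
    raise ValueError(f"target must be 'sensitivity' or 'specificity', got {target!r}")


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion counts and their standard summaries.

    ``concordance`` is overall agreement (TP+TN)/N, ``mcc`` the Matthews
    correlation coefficient (0 when any margin is empty), ``nmcc`` its
    [0, 1] normalization ``(mcc+1)/2`` and ``balanced`` the mean of
    sensitivity and specificity.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_not_evaluable: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def concordance(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def mcc(self) -> float:
        margins = (
            (self.tp + self.fp) * (self.tp + self.fn)
            * (self.tn + self.fp) * (self.tn + self.fn)
        )
        if margins == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / np.sqrt(float(margins))

    @property
    def nmcc(self) -> float:
        return (self.mcc + 1.0) / 2.0

    @property
    def balanced(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def confusion_metrics(
    calls: Sequence[Union[PhenotypeCall, str, bool, int]],
    truth: Sequence[LabelLike],
    not_evaluable: str = "exclude",
) -> ConfusionMetrics:
    """Cross-tabulate phenotype calls against reference truth.

    ``not_evaluable`` policy: ``exclude`` (default) removes unevaluable
    calls from the counts and reports them separately; ``negative`` (strict
    mode) counts them as negative calls.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    if not_evaluable not in ("exclude", "negative"):
        raise ValueError("not_evaluable must be 'exclude' or 'negative'")
    y = _as_bool_labels(truth)
    tp = fp = tn = fn = n_ne = 0
    for call, is_pos in zip(calls, y):
        if isinstance(call, PhenotypeCall):
            status = call.status
        elif isinstance(call, str):
            status = call
        else:
            status = "positive" if call else "negative"
        if status == "not_evaluable":
            n_ne += 1
            if not_evaluable == "exclude":
                continue
            status = "negative"
        called_pos = status == "positive"
        if called_pos and is_pos:
            tp += 1
        elif called_pos:
            fp += 1
        elif is_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, n_not_evaluable=n_ne)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary: means, interquartile ranges, Welch t-test p."""

    mean_a: float
    mean_b: float
    iqr_a: Tuple[float, float]
    iqr_b: Tuple[float, float]
    p_value: float
    n_a: int
    n_b: int


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Compare an analyte between two groups.

    Means, 25th/75th percentiles (linear-interpolation quantile rule) and a
    two-sided unequal-variance (Welch) t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t = stats.ttest_ind(a, b, equal_var=False)
    p = float(t.pvalue)
    if np.isnan(p):  # both groups constant and equal: no evidence of difference
        p = 1.0
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        iqr_a=tuple(np.quantile(a, [0.25, 0.75])),
        iqr_b=tuple(np.quantile(b, [0.25, 0.75])),
        p_value=p,
        n_a=a.size,
        n_b=b.size,
    )
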