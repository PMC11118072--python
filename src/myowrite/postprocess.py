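"""Majority-vote smoothing of decision streams and the evaluation metrics.

A classifier emitting one class vote per analysis window (every 75 ms by
default) produces a noisy decision stream; majority voting replaces each
vote with the modal label of a centred window of M+1 votes (M/2 before and
after), trading a latency of M/2 vote periods for stability. Evaluation
covers the confusion matrix and accuracy, precision, recall, F1 and the
Matthews correlation coefficient, computed one-vs-rest per class and
macro-averaged, plus the paired Wilcoxon signed-rank comparison between
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


@dataclass
class DecisionStream:
    """Time-ordered class votes at the feature update rate.

    ``provenance`` (optional) carries one row per vote with at least a
    ``recording_id`` column; smoothing never crosses recording boundaries.
    """

    votes: np.ndarray
    update_period: float = 0.075
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes)
        if self.provenance is not None and len(self.provenance) != len(self.votes):
            raise ValueError("provenance length must match votes")

    def __len__(self) -> int:
        return len(self.votes)

    def groups(self) -> list[np.ndarray]:
        """Index arrays of per-recording runs, in stream order."""
        if self.provenance is None:
            return [np.arange(len(self.votes))]
        rec = self.provenance["recording_id"].to_numpy()
        boundaries = np.flatnonzero(rec[1:] != rec[:-1]) + 1
        return np.split(np.arange(len(rec)), boundaries)


def majority_vote(stream: DecisionStream, M: int = 4) -> DecisionStream:
    """Smooth a decision stream with a centred (M+1)-vote majority window.

    At stream edges the window is truncated to the available votes (no
    fabricated padding). Ties keep the centre vote when it is among the
    tied labels, otherwise the tied label occurring most recently in the
    window: both choices avoid spurious label switching.
    """
    if M % 2 != 0 or M < 2:
        raise MetricError(f"M must be an even count >= 2, got {M}")
    half = M // 2
    out = np.array(stream.votes, copy=True)
    for idx in stream.groups():
        votes = stream.votes[idx]
        n = len(votes)
        for t in range(n):
            window = votes[max(0, t - half) : min(n, t + half + 1)]
            out[idx[t]] = _modal(window, centre=votes[t])
    return DecisionStream(
        votes=out, update_period=stream.update_period, provenance=stream.provenance
    )


def _modal(window: np.ndarray, centre):
    labels, counts = np.unique(window, return_counts=True)
    tied = labels[counts == counts.max()]
    if len(tied) == 1:
        return tied[0]
    if centre in tied:
        return centre
    tied_set = set(tied.tolist())
    for v in window[::-1]:  # most recent occurrence among tied labels
        if v in tied_set:
            return v
    raise AssertionError("unreachable: tied labels come from the window")


class MvTiming(NamedTuple):
    latency: float
    output_rate: float
    input_rate: float


def mv_timing(M: int, step: float = 0.075) -> MvTiming:
    """Latency and rate arithmetic of majority voting.

    With votes every ``step`` seconds (input rate 1/step), waiting for M/2
    future votes delays each smoothed decision by (M/2)*step seconds and
    caps the effective output rate at its reciprocal: M=4 and a 75 ms step
    give 13.33 Hz in, 150 ms latency, 6.66 Hz out.
    """
    if M % 2 != 0:
        raise MetricError(f"M must be even, got {M}")
    if step <= 0:
        raise MetricError("step must be positive")
    latency = (M / 2) * step
    return MvTiming(latency=latency, output_rate=1.0 / latency, input_rate=1.0 / step)


# --- confusion matrix and metrics -----------------------------------------

@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    labels: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = np.unique(np.concatenate([y_true, y_pred]))
        labels = np.asarray(labels)
        index = {lab: i for i, lab in enumerate(labels.tolist())}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(labels=labels, counts=counts)

    @property
    def n_scored(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> pd.DataFrame:
        """Per-class TP/FP/FN/TN counts."""
        tp = np.diag(self.counts).astype(float)
        fn = self.counts.sum(axis=1) - tp
        fp = self.counts.sum(axis=0) - tp
        tn = self.n_scored - tp - fn - fp
        return pd.DataFrame(
            {"TP": tp, "FP": fp, "FN": fn, "TN": tn}, index=self.labels
        )


@dataclass
class MetricsReport:
    """Headline accuracy plus per-class and macro one-vs-rest metrics."""

    confusion: ConfusionMatrix
    accuracy: float
    per_class: pd.DataFrame  # accuracy, precision, recall, f1, mcc per class
    n_scored: int
    macro: dict[str, float] = field(default_factory=dict)

    @property
    def f1_macro(self) -> float:
        return self.macro["f1"]

    @property
    def mcc_macro(self) -> float:
        return self.macro["mcc"]


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    bad = den == 0
    if bad.any():
        logger.warning("%s: zero denominator for %d classes, reported as 0", what, bad.sum())
    out[~bad] = num[~bad] / den[~bad]
    return out


def score(y_true, predicted, labels=None) -> MetricsReport:
    """Score predictions against truth with the one-vs-rest metric suite.

    ``predicted`` may be a DecisionStream or a plain label array. The
    headline ``accuracy`` is the overall fraction of correct votes;
    precision, recall, F1 (harmonic mean 2PR/(P+R)) and MCC are computed
    per class from one-vs-rest counts and macro-averaged.
    """
    y_pred = predicted.votes if isinstance(predicted, DecisionStream) else predicted
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise MetricError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if len(y_true) == 0:
        raise MetricError("need at least one scored window")

    cm = ConfusionMatrix.from_predictions(y_true, y_pred, labels=labels)
    ovr = cm.one_vs_rest()
    tp, fp, fn, tn = (ovr[c].to_numpy() for c in ("TP", "FP", "FN", "TN"))

    acc_c = (tp + tn) / cm.n_scored
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")

    per_class = pd.DataFrame(
        {
            "accuracy": acc_c,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "mcc": mcc,
        },
        index=cm.labels,
    )
    macro = {k: float(per_class[k].mean()) for k in per_class.columns}
    return MetricsReport(
        confusion=cm,
        accuracy=float(np.trace(cm.counts) / cm.n_scored),
        per_class=per_class,
        n_scored=cm.n_scored,
        macro=macro,
    )


class PairedComparison(NamedTuple):
    statistic: float
    p_value: float
    significant: bool


def paired_compare(a, b, alpha: float = 0.05) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-subject values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise MetricError("paired_compare needs two equal-length vectors, n >= 2")
    if np.allclose(a, b):
        logger.warning("all paired differences are zero; p = 1 by convention")
        return PairedComparison(statistic=0.0, p_value=1.0, significant=False)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return PairedComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )
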