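"""Sample-wise detector evaluation.

Output samples are split into MI periods (events) and rest periods
(non-events); at each candidate threshold the sample counts N_TP, N_FN, N_TN,
N_FP give

    R_TP = N_TP / (N_TP + N_FN)        (true positive rate, sensitivity)
    R_FP = N_FP / (N_TN + N_FP)        (false positive rate)

and the ROC curve over all thresholds is integrated trapezoidally for the
AUC (1 = complete separation, 0.5 = chance). The operating point closest to
the line R_TP = 1 - R_FP balances sensitivity against false alarms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ErrorCurve
from .io import TrialSet, ValidationError


@dataclass
class ROCResult:
    """Exact sample-wise ROC: one row per candidate threshold (ascending),
    predictions are ``output > threshold``."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    counts: pd.DataFrame  # columns N_TP, N_FN, N_TN, N_FP, indexed like thresholds

    def __post_init__(self):
        if np.any(np.diff(self.tpr) > 0) or np.any(np.diff(self.fpr) > 0):
            raise ValidationError("TPR/FPR must be non-increasing in the threshold")
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValidationError("AUC must lie in [0, 1]")


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    tpr: float
    fpr: float


def confusion_counts(output: np.ndarray, event_mask: np.ndarray,
                     threshold: float) -> tuple[int, int, int, int]:
    """Sample counts (N_TP, N_FN, N_TN, N_FP) for detections ``output > threshold``."""
    output = np.asarray(output, dtype=float)
    event_mask = np.asarray(event_mask, dtype=bool)
    if output.shape != event_mask.shape:
        raise ValidationError("output and event mask must have equal length")
    det = output > threshold
    n_tp = int(np.sum(det & event_mask))
    n_fn = int(np.sum(~det & event_mask))
    n_tn = int(np.sum(~det & ~event_mask))
    n_fp = int(np.sum(det & ~event_mask))
    return n_tp, n_fn, n_tn, n_fp


def sample_roc(output: np.ndarray, event_mask: np.ndarray) -> ROCResult:
    """Exact ROC over every unique output value (plus a -inf sentinel).

    Ties in the outputs produce diagonal ROC segments, so the trapezoidal AUC
    equals the midrank-corrected Mann-Whitney statistic.
    """
    output = np.asarray(output, dtype=float)
    event_mask = np.asarray(event_mask, dtype=bool)
    if output.shape != event_mask.shape:
        raise ValidationError("output and event mask must have equal length")
    n_pos = int(event_mask.sum())
    n_neg = int((~event_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both event and non-event samples are required")

    thresholds = np.concatenate([[-np.inf], np.unique(output)])
    # counts of events/non-events strictly above each threshold, via cumsums
    order = np.argsort(output, kind="stable")
    sorted_out = output[order]
    sorted_ev = event_mask[order]
    # position of first element > thr for each threshold
    above = np.searchsorted(sorted_out, thresholds, side="right")
    ev_cum = np.concatenate([[0], np.cumsum(sorted_ev)])
    n_tp = n_pos - ev_cum[above]
    n_det = len(output) - above
    n_fp = n_det - n_tp
    tpr = n_tp / n_pos
    fpr = n_fp / n_neg
    counts = pd.DataFrame({
        "N_TP": n_tp, "N_FN": n_pos - n_tp, "N_TN": n_neg - n_fp, "N_FP": n_fp,
    })
    # integrate in increasing-FPR order (reverse of the threshold order)
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCResult(thresholds, tpr, fpr, auc, counts)


def best_threshold(roc: ROCResult) -> OperatingPoint:
    """ROC point closest (Euclidean) to the line R_TP = 1 - R_FP; ties take
    the lower-FPR point."""
    if len(roc.thresholds) == 0:
        raise ValidationError("empty ROC curve")
    dist = np.abs(roc.tpr + roc.fpr - 1.0) / np.sqrt(2.0)
    candidates = np.flatnonzero(dist == dist.min())
    best = candidates[np.argmin(roc.fpr[candidates])]
    return OperatingPoint(float(roc.thresholds[best]), float(roc.tpr[best]),
                          float(roc.fpr[best]))


def mi_window_mask(times: np.ndarray, trials: TrialSet) -> np.ndarray:
    """Boolean event mask: True where a time falls in some trial's MI window
    (half-open intervals)."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for start, end in trials.mi_windows():
        mask |= (times >= start) & (times < end)
    return mask


def error_over_time(curves: dict[object, ErrorCurve],
                    mi_window: tuple[float, float] = (5.0, 10.0)) -> pd.DataFrame:
    """Summarize per-day error curves.

    ``curves`` maps a day key to its ErrorCurve (shared time grid). Returns a
    long-format table (day, time_s, error_rate) whose ``attrs['mi_average']``
    holds each day's mean error over the trial-axis MI window [5, 10) s.
    """
    curves = dict(curves)
    if not curves:
        raise ValidationError("no curves supplied")
    items = list(curves.items())
    ref_times = items[0][1].times
    rows = []
    mi_avg = {}
    for day, curve in items:
        if not np.array_equal(curve.times, ref_times):
            raise ValidationError(f"curve {day!r} is on a different time grid")
        in_mi = (curve.times >= mi_window[0]) & (curve.times < mi_window[1])
        mi_avg[day] = float(curve.error_rate[in_mi].mean())
        for t, e in zip(curve.times, curve.error_rate):
            rows.append({"day": day, "time_s": t, "error_rate": e})
    table = pd.DataFrame(rows)
    table.attrs["mi_average"] = mi_avg
    return table
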