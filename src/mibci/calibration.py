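"""Cue-paced LDA calibration.

At every 250 ms of the 13-s trial (53 time points) the four hand features
(mu and beta log band power at C3 and C4) of all trials are collected, a
Fisher linear discriminant is cross-validated with the exact-partition packet
scheme (40 vectors -> 10 packets of 4), and the per-timepoint error curve is
assembled. The model at the minimum-error time point (earliest on ties) is
the one used for online classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import HAND_FEATURES, BandPowerSeries
from .io import RunConfig, TrialSet, ValidationError

logger = logging.getLogger(__name__)

LEFT, RIGHT = "left_hand", "right_hand"

#: relative ridge added to a near-singular pooled covariance
RIDGE_REL = 1e-6


@dataclass
class LDAModel:
    """Fisher LDA over the 4-element hand feature vector.

    Sign convention: ``weights @ x + bias > 0`` predicts left-hand MI.
    """

    weights: np.ndarray
    bias: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.bias)):
            raise ValidationError("LDA parameters must be finite")

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels; the boundary itself (output 0) falls to right_hand."""
        return np.where(self.decision(X) > 0, LEFT, RIGHT)


@dataclass
class ErrorCurve:
    """Cross-validated error rate per trial-axis time point."""

    times: np.ndarray
    error_rate: np.ndarray
    models: list[LDAModel]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.error_rate = np.asarray(self.error_rate, dtype=float)
        if np.any((self.error_rate < 0) | (self.error_rate > 1)):
            raise ValidationError("error rates must lie in [0, 1]")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")


def trial_features(bp_streams: dict[str, BandPowerSeries], trials: TrialSet,
                   timestep_s: float = 0.25, rate: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint feature matrices sampled at trial onset + t.

    Returns ``(times, X)`` where ``times`` spans [0, trial_s] inclusive at
    ``timestep_s`` spacing and ``X`` has shape (n_times, n_trials, 4) in
    HAND_FEATURES order.
    """
    if rate is None:
        raise ValidationError("trial_features needs the sampling rate of the BP streams")
    trial_s = trials.phase_timing.trial_s
    n_steps = int(round(trial_s / timestep_s))
    times = np.arange(n_steps + 1) * timestep_s
    n_samples = len(next(iter(bp_streams.values())).values)
    X = np.empty((len(times), len(trials), len(HAND_FEATURES)))
    for j, onset in enumerate(trials.onsets):
        idx = np.floor((onset + times) * rate).astype(int)
        idx[idx == n_samples] = n_samples - 1  # inclusive right endpoint of the last trial
        if idx.max() >= n_samples or idx.min() < 0:
            raise ValidationError(
                f"trial at {onset} s extends past the recording end")
        for k, name in enumerate(HAND_FEATURES):
            X[:, j, k] = bp_streams[name].values[idx]
    return times, X


def fit_lda(X: np.ndarray, labels) -> LDAModel:
    """Fisher LDA: ``w = Sw^-1 (m_left - m_right)``, boundary midway between
    the projected class means. Near-singular pooled covariance gets a small
    ridge (logged as a warning)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if classes != {LEFT, RIGHT}:
        raise ValidationError(f"need both classes {LEFT!r} and {RIGHT!r}; got {sorted(classes)}")
    Xl, Xr = X[labels == LEFT], X[labels == RIGHT]
    if len(Xl) < 2 or len(Xr) < 2:
        raise ValidationError("need at least 2 vectors per class")
    ml, mr = Xl.mean(axis=0), Xr.mean(axis=0)
    Sw = np.cov(Xl, rowvar=False) * (len(Xl) - 1) + np.cov(Xr, rowvar=False) * (len(Xr) - 1)
    Sw /= len(X) - 2
    d = X.shape[1]
    if np.linalg.cond(Sw) > 1e10:
        lam = RIDGE_REL * np.trace(Sw) / d
        if lam <= 0:
            lam = RIDGE_REL
        logger.warning("pooled covariance near-singular; adding ridge %.3g", lam)
        Sw = Sw + lam * np.eye(d)
    w = np.linalg.solve(Sw, ml - mr)
    b = -0.5 * w @ (ml + mr)
    return LDAModel(w, float(b))


def crossval_error(X: np.ndarray, labels, folds: int = 10,
                   seed: int | None = 0) -> tuple[float, LDAModel]:
    """Exact-partition packet cross-validation.

    The vectors are shuffled (seeded), divided into ``folds`` equal packets,
    and each packet is classified by an LDA trained on the others. Returns the
    mean of the fold error rates and the element-wise mean of the fold LDA
    parameters (the fit's sign convention is already uniform, so averaging is
    well defined).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    if n % folds != 0:
        raise ValidationError(f"{n} vectors cannot be split into {folds} equal packets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    packet = n // folds
    errs, Ws, Bs = [], [], []
    for k in range(folds):
        test = order[k * packet:(k + 1) * packet]
        train = np.concatenate([order[:k * packet], order[(k + 1) * packet:]])
        model = fit_lda(X[train], labels[train])
        errs.append(np.mean(model.predict(X[test]) != labels[test]))
        Ws.append(model.weights)
        Bs.append(model.bias)
    avg = LDAModel(np.mean(Ws, axis=0), float(np.mean(Bs)))
    return float(np.mean(errs)), avg


def calibrate(bp_streams: dict[str, BandPowerSeries], trials: TrialSet,
              config: RunConfig | None = None, rate: float | None = None,
              refit: bool = False) -> tuple[ErrorCurve, LDAModel, float]:
    """Full calibration sweep.

    Runs ``crossval_error`` at every time point of the trial grid and selects
    the minimum-error time (earliest on ties). Returns the error curve, the
    selected model, and the selected time. By default the selected model is
    the cross-validation parameter average at that time; ``refit=True``
    instead refits on all vectors there.
    """
    config = config or RunConfig()
    times, X = trial_features(bp_streams, trials, config.lda_timestep_s, rate=rate)
    labels = np.asarray(trials.classes)
    errors, models = [], []
    for i in range(len(times)):
        err, avg = crossval_error(X[i], labels, folds=config.cv_folds, seed=config.seed)
        errors.append(err)
        models.append(avg)
    curve = ErrorCurve(times, np.asarray(errors), models)
    best = int(np.argmin(curve.error_rate))  # argmin takes the earliest tie
    model = fit_lda(X[best], labels) if refit else models[best]
    return curve, model, float(times[best])
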