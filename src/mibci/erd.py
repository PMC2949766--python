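"""Multichannel ERD/ERS analysis (the power method).

Monopolar recordings are re-referenced with a small surface Laplacian (each
electrode minus the mean of its four nearest neighbours), power is estimated
with FFTs of heavily overlapped 1-s segments (step = rate/16 samples, i.e.
93.75% overlap, 1 Hz resolution, 4-45 Hz), averaged over the trials of one
condition, and expressed relative to the within-trial rest baseline
(0-4 s):

    ERD/ERS(f, t) = 100 * (P(f, t) - R(f)) / R(f)   [%]

so band-power decreases are negative (ERD) and increases positive (ERS).
Band curves average the map over a frequency band; pre/post-training curves
are compared per time point with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import EEGRecording, Montage, TrialSet, ValidationError

#: frequency grid bounds (Hz, inclusive) of the time-frequency maps
FREQ_RANGE = (4.0, 45.0)

#: segment advance as a fraction of the sampling rate (rate/16 samples,
#: i.e. 93.75% overlap of the 1-s segments, matching the 16 Hz frame rate)
SEGMENT_STEP_DIV = 16


@dataclass
class TFMap:
    """Trial-averaged power (uV^2) on a freq x time grid for one channel."""

    channel: str
    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    condition: str = ""
    n_trials: int = 1

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValidationError("power must be freq x time")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")


@dataclass
class ERDMap:
    """Relative band-power change (%) versus the rest baseline."""

    channel: str
    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray          # percent; negative = ERD, positive = ERS
    baseline_window: tuple[float, float]
    condition: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise ValidationError("values must be freq x time")


@dataclass
class BandCurve:
    """Band-averaged ERD/ERS (%) over trial time for one channel."""

    channel: str
    band: tuple[float, float]
    times: np.ndarray
    erd_percent: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.erd_percent = np.asarray(self.erd_percent, dtype=float)
        if not np.all(np.isfinite(self.erd_percent)):
            raise ValidationError("band curve values must be finite")


# ---------------------------------------------------------------------------
# spatial filtering
# ---------------------------------------------------------------------------

def laplacian(rec: EEGRecording, montage: Montage,
              channels=None) -> EEGRecording:
    """Surface Laplacian: each channel minus the mean of its neighbours.

    Edge electrodes with fewer than four neighbours use the mean of those
    available (at least two) and are listed in the output's
    ``partial_channels`` metadata; channels with no usable neighbour raise.
    """
    if rec.reference == "bipolar":
        raise ValidationError("the Laplacian needs a monopolar recording")
    if channels is None:
        channels = [c for c in rec.channel_labels if c in montage.neighbor_map]
    rows, partial = [], []
    for ch in channels:
        nbrs = [n for n in montage.neighbor_map.get(ch, ())
                if n in rec.channel_labels]
        if len(nbrs) == 0:
            raise ValidationError(f"channel {ch!r} has no neighbours in the recording")
        if len(nbrs) < 2:
            raise ValidationError(
                f"channel {ch!r} has only {len(nbrs)} usable neighbour(s); need >= 2")
        if len(nbrs) < 4:
            partial.append(ch)
        rows.append(rec.channel(ch) - np.mean([rec.channel(n) for n in nbrs], axis=0))
    out = EEGRecording(rec.sample_rate, tuple(channels), np.vstack(rows),
                       reference="laplacian", start_time=rec.start_time)
    out.partial_channels = tuple(partial)
    return out


# ---------------------------------------------------------------------------
# time-frequency decomposition
# ---------------------------------------------------------------------------

def _segment_power(x: np.ndarray, rate: int, window: str) -> np.ndarray:
    """Power (uV^2 per 1-Hz bin) of overlapped 1-s segments of one trial.

    Returns (n_freqs, n_segments); segment k starts at sample k * rate/16.
    The scaling makes a pure in-bin tone of amplitude A read A^2/2.
    """
    w = int(rate)
    step = int(rate) // SEGMENT_STEP_DIV
    n_seg = (len(x) - w) // step + 1
    if n_seg < 1:
        raise ValidationError("trial shorter than the 1-s analysis segment")
    idx = np.arange(w)[None, :] + step * np.arange(n_seg)[:, None]
    segs = x[idx]
    if window == "hann":
        taper = np.hanning(w)
        segs = segs * taper
        norm = np.sum(taper ** 2) * w / 2.0
    elif window == "rect":
        norm = w * w / 2.0
    else:
        raise ValueError(f"unknown FFT window {window!r} (use 'rect' or 'hann')")
    spec = np.fft.rfft(segs, axis=1)
    return (np.abs(spec) ** 2 / norm).T


def time_freq(rec: EEGRecording, trials: TrialSet, condition: str,
              channel: str, window: str = "rect",
              average: bool = True):
    """Time-frequency map(s) of one channel for the trials of one condition.

    1-s segments advanced by ``rate/16`` samples, per-segment FFT power on the
    1 Hz grid restricted to 4-45 Hz, averaged across the condition's trials at
    each trial-relative time. ``average=False`` returns the per-trial list of
    TFMaps instead (used for trial-paired statistics).
    """
    rate = rec.sample_rate
    if rate != int(rate) or int(rate) % SEGMENT_STEP_DIV != 0:
        raise ValidationError(f"sampling rate {rate} must be an integer multiple of "
                              f"{SEGMENT_STEP_DIV} Hz")
    sel = trials.select(condition)
    if len(sel) == 0:
        raise ValidationError(f"no trials of condition {condition!r}")
    x = rec.channel(channel)
    trial_len = sel.phase_timing.trial_s
    n_tr = int(round(trial_len * rate))
    freqs_all = np.fft.rfftfreq(int(rate), 1.0 / rate)
    keep = (freqs_all >= FREQ_RANGE[0]) & (freqs_all <= FREQ_RANGE[1])
    step = int(rate) // SEGMENT_STEP_DIV
    maps = []
    for onset in sel.onsets:
        i0 = int(np.floor(onset * rate))
        if i0 + n_tr > rec.n_samples:
            raise ValidationError(f"trial at {onset} s extends past the recording end")
        P = _segment_power(x[i0:i0 + n_tr], int(rate), window)[keep]
        n_seg = P.shape[1]
        # segment centre times on the trial axis
        times = (np.arange(n_seg) * step + rate / 2.0) / rate
        maps.append(TFMap(channel, freqs_all[keep], times, P, condition, 1))
    if not average:
        return maps
    power = np.mean([m.power for m in maps], axis=0)
    return TFMap(channel, maps[0].freqs, maps[0].times, power, condition, len(maps))


# ---------------------------------------------------------------------------
# ERD/ERS quantification
# ---------------------------------------------------------------------------

def erd_ers(tfmap: TFMap, baseline: tuple[float, float] = (0.0, 4.0)) -> ERDMap:
    """Relative power change versus the rest baseline, per frequency row.

    R(f) is the mean power over baseline times; values are
    100 * (P(f,t) - R(f)) / R(f), so decreases are negative (ERD).
    """
    lo, hi = baseline
    in_base = (tfmap.times >= lo) & (tfmap.times < hi)
    if not np.any(in_base):
        raise ValidationError(f"baseline {baseline} contains no map time points")
    R = tfmap.power[:, in_base].mean(axis=1)
    zero = np.flatnonzero(R <= 0)
    if len(zero):
        raise ValidationError(
            f"zero baseline power at {tfmap.freqs[zero[0]]:g} Hz")
    values = 100.0 * (tfmap.power - R[:, None]) / R[:, None]
    return ERDMap(tfmap.channel, tfmap.freqs, tfmap.times, values, baseline,
                  tfmap.condition)


def band_curve(erdmap: ERDMap, band: tuple[float, float]) -> BandCurve:
    """Unweighted mean of the ERD map over the band's frequency rows."""
    lo, hi = band
    rows = (erdmap.freqs >= lo) & (erdmap.freqs <= hi)
    if not np.any(rows):
        raise ValidationError(f"band {band} contains no frequency rows")
    return BandCurve(erdmap.channel, (float(lo), float(hi)), erdmap.times,
                     erdmap.values[rows].mean(axis=0), erdmap.condition)


def compare_days(pre: list[BandCurve], post: list[BandCurve],
                 window: tuple[float, float] = (5.0, 10.0),
                 alpha: float = 0.01) -> pd.DataFrame:
    """Per-timepoint Wilcoxon signed-rank comparison of two training days.

    ``pre`` and ``post`` are equal-length sets of per-trial band curves on a
    shared time grid; curve i of one day is paired with curve i of the other.
    Returns a table (time_s, p_value, significant) covering the analysis
    window; at least 6 pairs are required for the test to have usable levels.
    """
    if len(pre) != len(post):
        raise ValidationError("pre and post must pair up (equal curve counts)")
    if len(pre) < 6:
        raise ValidationError("need at least 6 paired curves for the signed-rank test")
    times = pre[0].times
    for c in (*pre, *post):
        if not np.array_equal(c.times, times):
            raise ValidationError("all curves must share the time grid")
    A = np.array([c.erd_percent for c in pre])
    B = np.array([c.erd_percent for c in post])
    in_win = (times >= window[0]) & (times < window[1])
    rows = []
    for j in np.flatnonzero(in_win):
        d = B[:, j] - A[:, j]
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(A[:, j], B[:, j], zero_method="wilcox").pvalue)
        rows.append({"time_s": float(times[j]), "p_value": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows, columns=["time_s", "p_value", "significant"])


def topography_export(curves: dict[str, BandCurve], montage: Montage,
                      window: tuple[float, float] = (5.0, 10.0)) -> pd.DataFrame:
    """Per-channel mean ERD/ERS over the MI window, with scalp coordinates.

    ``curves`` maps channel label -> BandCurve; the table (channel, x, y,
    value) feeds external topographic rendering. All montage grid electrodes
    must be present.
    """
    wanted = [l for l in montage.labels if l in montage.neighbor_map]
    missing = sorted(set(wanted) - set(curves))
    if missing:
        raise ValidationError(f"missing channels: {missing}")
    rows = []
    for ch in wanted:
        c = curves[ch]
        in_win = (c.times >= window[0]) & (c.times < window[1])
        x, y = montage.positions[ch]
        rows.append({"channel": ch, "x": x, "y": y,
                     "value": float(c.erd_percent[in_win].mean())})
    return pd.DataFrame(rows, columns=["channel", "x", "y", "value"])
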