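"""Band-power (BP) feature extraction.

The feature is the classic sensorimotor-rhythm band power: band-pass filter
(Butterworth, design order 4), square, average over a trailing 1-s window,
take the natural logarithm — computed sample by sample so the online decoder
can consume it causally. Filter and window state carry across streamed blocks,
so chunked processing is bit-identical to whole-record processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, Montage, RunConfig, ValidationError

#: power floor (uV^2) applied before the log so silent inputs stay finite
POWER_FLOOR = 1e-12

#: hand-feature channels and the feet-feature channel
HAND_CHANNELS = ("C3", "C4")
FEET_CHANNEL = "Cz"


@dataclass
class BandPowerSeries:
    """Log band power (ln uV^2), one value per input sample."""

    channel: str
    band: tuple[float, float]
    values: np.ndarray
    window_s: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.window_s <= 0:
            raise ValidationError("window_s must be > 0")


def bipolar_derive(rec: EEGRecording, montage: Montage) -> EEGRecording:
    """Anode-minus-cathode derivation for each montage bipolar pair.

    Output channels are labelled by their anodes (Cz, C4, C3 by default).
    """
    rows, labels = [], []
    for anode, cathode in montage.bipolar_pairs:
        for member in (anode, cathode):
            if member not in rec.channel_labels:
                raise ValidationError(
                    f"bipolar pair ({anode}, {cathode}): channel {member!r} missing from recording")
        rows.append(rec.channel(anode) - rec.channel(cathode))
        labels.append(anode)
    return EEGRecording(rec.sample_rate, tuple(labels), np.vstack(rows),
                        reference="bipolar", start_time=rec.start_time)


def butter_sos(band: tuple[float, float], rate: float, order: int = 4) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValidationError(f"band {band} must lie strictly inside (0, {rate / 2}) Hz")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def bandpass(x: np.ndarray, band: tuple[float, float], rate: float,
             mode: str = "causal", order: int = 4) -> np.ndarray:
    """Butterworth band-pass. ``causal`` matches online replay; ``zero_phase``
    (forward-backward) is for offline analysis only."""
    sos = butter_sos(band, rate, order)
    x = np.asarray(x, dtype=float)
    if mode == "causal":
        return sps.sosfilt(sos, x, axis=-1)
    if mode == "zero_phase":
        return sps.sosfiltfilt(sos, x, axis=-1)
    raise ValueError(f"unknown mode {mode!r} (use 'causal' or 'zero_phase')")


@dataclass
class BandPowerExtractor:
    """Streaming band-power estimator for one channel/band.

    Per sample: band-pass (causal), square, average over the trailing
    ``window_s`` seconds (the prefix shorter than the window averages over the
    samples seen so far), then natural log with a small floor. ``process`` may
    be called repeatedly with arbitrary block sizes; state carries over.
    """

    band: tuple[float, float]
    rate: float
    window_s: float = 1.0
    _sos: np.ndarray = field(init=False, repr=False)
    _zi: np.ndarray = field(init=False, repr=False)
    _tail: np.ndarray = field(init=False, repr=False)  # last w-1 squared samples
    _seen: int = field(init=False, default=0)

    def __post_init__(self):
        w = int(round(self.window_s * self.rate))
        if w < 1:
            raise ValidationError("window_s * rate must be >= 1 sample")
        self._w = w
        self._sos = butter_sos(self.band, self.rate)
        self._zi = np.zeros((self._sos.shape[0], 2))
        self._tail = np.zeros(w - 1)  # zero history; prefix averages divide by n seen

    def process(self, block: np.ndarray) -> np.ndarray:
        block = np.asarray(block, dtype=float)
        if block.size == 0:
            return np.empty(0)
        filt, self._zi = sps.sosfilt(self._sos, block, zi=self._zi)
        sq = filt * filt
        w = self._w
        ext = np.concatenate([self._tail, sq])
        # each output sums the exact same w-sample window whatever the chunking,
        # so block-streamed and whole-record results are bit-identical
        sums = np.lib.stride_tricks.sliding_window_view(ext, w).sum(axis=-1)
        n = np.minimum(self._seen + 1 + np.arange(len(sq)), w)
        self._seen += len(sq)
        if w > 1:
            self._tail = ext[-(w - 1):].copy()
        return np.log(np.maximum(sums / n, POWER_FLOOR))


def band_power(x: np.ndarray, band: tuple[float, float], rate: float,
               window_s: float = 1.0) -> BandPowerSeries:
    """Whole-signal band power for one channel (see BandPowerExtractor)."""
    ext = BandPowerExtractor(band, rate, window_s)
    return BandPowerSeries("", band, ext.process(x), window_s)


@dataclass
class FeatureVector:
    """The 4-element hand-classifier feature at one time point."""

    mu_C3: float
    mu_C4: float
    beta_C3: float
    beta_C4: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise ValidationError("feature vector elements must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_C3, self.mu_C4, self.beta_C3, self.beta_C4])


#: order of the hand-feature series, matching FeatureVector fields
HAND_FEATURES = ("mu_C3", "mu_C4", "beta_C3", "beta_C4")


class FeatureStreamer:
    """Streaming producer of the five aligned BP series the decoders consume:
    mu and beta at C3 and C4 (hand LDA features) and beta at Cz (feet
    detector). Input blocks are bipolar channels x samples in the order
    the recording lists Cz, C4, C3."""

    def __init__(self, channel_labels, config: RunConfig, rate: float):
        for ch in (*HAND_CHANNELS, FEET_CHANNEL):
            if ch not in channel_labels:
                raise ValidationError(f"feature extraction needs channel {ch!r}; "
                                      f"recording has {list(channel_labels)}")
        self.labels = tuple(channel_labels)
        self.rate = rate
        mk = lambda band: BandPowerExtractor(band, rate, config.bp_window_s)
        self._extractors = {
            "mu_C3": ("C3", mk(config.mu_band)),
            "mu_C4": ("C4", mk(config.mu_band)),
            "beta_C3": ("C3", mk(config.beta_band)),
            "beta_C4": ("C4", mk(config.beta_band)),
            "beta_Cz": ("Cz", mk(config.beta_band)),
        }

    def process(self, block: np.ndarray) -> dict[str, np.ndarray]:
        block = np.atleast_2d(np.asarray(block, dtype=float))
        out = {}
        for name, (ch, ext) in self._extractors.items():
            out[name] = ext.process(block[self.labels.index(ch)])
        return out


def feature_stream(rec: EEGRecording, config: RunConfig | None = None,
                   montage: Montage | None = None) -> dict[str, BandPowerSeries]:
    """Compute the five BP series for a whole recording.

    ``rec`` may be monopolar (it is bipolar-derived through ``montage``) or
    already bipolar with channels Cz, C4, C3.
    """
    config = config or RunConfig()
    if rec.reference != "bipolar":
        from .io import default_montage
        rec = bipolar_derive(rec, montage or default_montage())
    streamer = FeatureStreamer(rec.channel_labels, config, rec.sample_rate)
    values = streamer.process(rec.data)
    out = {}
    for name, vals in values.items():
        ch, ext = streamer._extractors[name]
        out[name] = BandPowerSeries(ch, ext.band, vals, config.bp_window_s)
    return out
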