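"""Synthetic cue-paced EEG sessions.

The generator emulates the recordings the pipeline was designed for: a
cue-paced protocol (4 s fixation, 1 s guidance, 5 s motor imagery, 3 s
inter-trial interval; 13 s per trial), 1/f background activity, and
band-limited stochastic mu (8-13 Hz) and beta (25-35 Hz) rhythms whose
amplitude is multiplied by a class- and channel-specific factor during the MI
phase. An amplitude factor g scales band power by g^2, so g = sqrt(0.45)
yields an expected ERD of -55% and g = sqrt(1.31) an ERS of +31%. The
modulation ramps linearly over 0.5 s at the MI-phase edges to avoid
filter-edge ringing; analyses that quantify the plateau should skip the first
half second of the MI window. The summed signal is band-limited to 5-100 Hz
(the acquisition filter) and digitized-rate white sensor noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .io import (MI_CLASSES, EEGRecording, Montage, PhaseTiming, TrialSet,
                 ValidationError, default_montage)

#: seconds over which MI-phase amplitude modulation ramps in and out
RAMP_S = 0.5

#: acquisition band limit (Hz), matching the amplifier's analog filtering
ACQUISITION_BAND = (5.0, 100.0)

BANDS = {"mu": (8.0, 13.0), "beta": (25.0, 35.0)}


@dataclass(frozen=True)
class SubjectModel:
    """Statistical model of one subject's sensorimotor EEG.

    ``rhythm_base`` maps (channel, band name) to the rhythm's RMS amplitude in
    microvolts; ``modulation`` maps (MI class, channel, band name) to the
    multiplicative amplitude factor applied during the MI phase (e.g. 0.67
    means power x0.45, i.e. an ERD of -55%). ``background_rms`` is the RMS of
    the 1/f background over the acquisition band.
    """

    background_exponent: float = 1.0
    background_rms: float = 5.0
    rhythm_base: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("C3", "mu"): 12.0, ("C4", "mu"): 12.0, ("Cz", "mu"): 12.0,
        ("C3", "beta"): 8.0, ("C4", "beta"): 8.0, ("Cz", "beta"): 8.0,
    })
    modulation: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    sensor_noise_sd: float = 1.0

    def __post_init__(self):
        if any(a < 0 for a in self.rhythm_base.values()):
            raise ValidationError("rhythm base amplitudes must be >= 0")
        if any(g <= 0 for g in self.modulation.values()):
            raise ValidationError("modulation amplitude factors must be > 0")
        for cls, _, band in self.modulation:
            if cls not in MI_CLASSES:
                raise ValidationError(f"modulation references unknown class {cls!r}")
            if band not in BANDS:
                raise ValidationError(f"modulation references unknown band {band!r}")

    @classmethod
    def trained(cls) -> "SubjectModel":
        """Somatotopic modulation at post-training depth: mu ERD -55% at Cz
        (feet), -42% at C4 (left hand), -51% at C3 (right hand); beta ERS
        +31% at Cz (feet)."""
        return cls(modulation={
            ("feet", "Cz", "mu"): np.sqrt(0.45),
            ("feet", "Cz", "beta"): np.sqrt(1.31),
            ("left_hand", "C4", "mu"): np.sqrt(0.58),
            ("right_hand", "C3", "mu"): np.sqrt(0.49),
        })

    @classmethod
    def naive(cls) -> "SubjectModel":
        """Pre-training modulation depth: mu ERD -29%/-23%/-22%, beta ERS +21%."""
        return cls(modulation={
            ("feet", "Cz", "mu"): np.sqrt(0.71),
            ("feet", "Cz", "beta"): np.sqrt(1.21),
            ("left_hand", "C4", "mu"): np.sqrt(0.77),
            ("right_hand", "C3", "mu"): np.sqrt(0.78),
        })

    def to_dict(self) -> dict:
        return {
            "background_exponent": self.background_exponent,
            "background_rms": self.background_rms,
            "sensor_noise_sd": self.sensor_noise_sd,
            "rhythm_base": {f"{ch}:{b}": float(a) for (ch, b), a in self.rhythm_base.items()},
            "modulation": {f"{c}:{ch}:{b}": float(g)
                           for (c, ch, b), g in self.modulation.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubjectModel":
        kw = dict(d)
        if "rhythm_base" in kw:
            kw["rhythm_base"] = {tuple(k.split(":")): float(v)
                                 for k, v in kw["rhythm_base"].items()}
        if "modulation" in kw:
            kw["modulation"] = {tuple(k.split(":")): float(v)
                                for k, v in kw["modulation"].items()}
        return cls(**kw)


@dataclass(frozen=True)
class SessionProtocol:
    """Cue-paced session layout: trial count, class set, phase timing."""

    n_trials: int = 40
    classes: tuple[str, ...] = ("left_hand", "right_hand")
    phase_timing: PhaseTiming = field(default_factory=PhaseTiming)
    randomize: bool = True
    seed: int = 0

    def __post_init__(self):
        bad = sorted(set(self.classes) - set(MI_CLASSES))
        if bad:
            raise ValidationError(f"unknown classes {bad}; allowed: {list(MI_CLASSES)}")
        if self.n_trials <= 0:
            raise ValidationError("n_trials must be positive")
        if self.n_trials % len(self.classes) != 0:
            raise ValidationError(
                f"{self.n_trials} trials cannot be balanced over {len(self.classes)} classes")


def schedule_cue_paced(protocol: SessionProtocol, seed: int | None = None) -> TrialSet:
    """Balanced, seed-reproducibly shuffled trial schedule.

    Trial k starts at ``k * trial_s`` seconds; each class appears
    ``n_trials / n_classes`` times.
    """
    per_class = protocol.n_trials // len(protocol.classes)
    classes = [c for c in protocol.classes for _ in range(per_class)]
    if protocol.randomize:
        rng = np.random.default_rng(protocol.seed if seed is None else seed)
        classes = [classes[i] for i in rng.permutation(len(classes))]
    onsets = np.arange(protocol.n_trials) * protocol.phase_timing.trial_s
    return TrialSet(onsets, tuple(classes), protocol.phase_timing)


def _one_over_f(rng, n, rate, exponent, rms):
    """Gaussian noise with a 1/f^exponent power spectrum, unit-rms then scaled.
    The spectrum is flattened below 1 Hz to keep the variance finite."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec *= 1.0 / np.maximum(f, 1.0) ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _narrowband(rng, n, rate, band):
    """Unit-rms band-limited stochastic oscillation (filtered white noise)."""
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _mi_envelope(n, rate, trials: TrialSet, factors: Mapping[str, float]) -> np.ndarray:
    """Amplitude envelope: ``factors[cls]`` during each MI phase of class
    ``cls``, 1 elsewhere, with linear ramps of RAMP_S at the phase edges."""
    env = np.ones(n)
    t = np.arange(n) / rate
    timing = trials.phase_timing
    for onset, cls in zip(trials.onsets, trials.classes):
        g = factors.get(cls, 1.0)
        if g == 1.0:
            continue
        a, b = onset + timing.mi_start_s, onset + timing.mi_end_s
        up = (t >= a) & (t < a + RAMP_S)
        env[up] = 1.0 + (g - 1.0) * (t[up] - a) / RAMP_S
        env[(t >= a + RAMP_S) & (t < b)] = g
        down = (t >= b) & (t < b + RAMP_S)
        env[down] = g + (1.0 - g) * (t[down] - b) / RAMP_S
    return env


def generate_session(protocol: SessionProtocol, subject: SubjectModel,
                     montage: Montage | None = None, rate: float = 256.0,
                     seed: int | None = None) -> tuple[EEGRecording, TrialSet]:
    """Generate one monopolar cue-paced session.

    Returns a recording with one channel per montage position (including the
    synthetic bipolar cathodes) and the trial schedule. The class sequence is
    governed by ``protocol.seed``; ``seed`` drives the signal noise, so
    sessions with different seeds share the schedule.
    """
    montage = montage or default_montage()
    top = max(max(b) for b in BANDS.values())
    if rate < 2 * top:
        raise ValidationError(f"rate {rate} Hz cannot represent the {top} Hz band top")
    for cls, ch, band in subject.modulation:
        if ch not in montage.positions:
            raise ValidationError(f"modulation references unknown channel {ch!r}")
    trials = schedule_cue_paced(protocol)
    n = int(round(protocol.n_trials * protocol.phase_timing.trial_s * rate))
    rng = np.random.default_rng(seed)
    acq_sos = sps.butter(4, ACQUISITION_BAND, btype="bandpass", fs=rate, output="sos")

    channels = montage.labels
    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        x = _one_over_f(rng, n, rate, subject.background_exponent, subject.background_rms)
        for band_name, band in BANDS.items():
            amp = subject.rhythm_base.get((ch, band_name), 0.0)
            if amp <= 0:
                continue
            factors = {cls: g for (cls, c, b), g in subject.modulation.items()
                       if c == ch and b == band_name}
            env = _mi_envelope(n, rate, trials, factors) if factors else 1.0
            x = x + amp * env * _narrowband(rng, n, rate, band)
        x = sps.sosfiltfilt(acq_sos, x)
        if subject.sensor_noise_sd > 0:
            x = x + subject.sensor_noise_sd * rng.standard_normal(n)
        data[i] = x
    rec = EEGRecording(rate, channels, data, reference="monopolar")
    return rec, trials


def inject_artifact(rec: EEGRecording, kind: str, params: Mapping) -> EEGRecording:
    """Add a deterministic artifact (test fixture): ``line_noise`` (freq_hz,
    amplitude_uv) on every channel, or ``step_drift`` (time_s, amplitude_uv)."""
    t = np.arange(rec.n_samples) / rec.sample_rate
    if kind == "line_noise":
        add = params["amplitude_uv"] * np.sin(2 * np.pi * params["freq_hz"] * t)
    elif kind == "step_drift":
        add = np.where(t >= params["time_s"], params["amplitude_uv"], 0.0)
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return replace(rec, data=rec.data + add[None, :])
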