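"""Minimal EDF (European Data Format) writer.

Writes 16-bit EDF files with one signal per EEG channel, physical units in
microvolts. Layout: 1-second data records when the sample count divides the
sampling rate evenly, otherwise a single data record holding the whole
recording (avoids zero-padding, so read(write(x)) returns exactly the original
sample count). Only what the package itself needs is implemented; reading is
delegated to :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sample_rate: float, labels, unit: str = "uV"):
    """Write ``data`` (channels x samples, physical units) to an EDF file."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if n_ch == 0 or n_samp == 0:
        raise ValueError("cannot write an EDF file with no channels or samples")
    if len(labels) != n_ch:
        raise ValueError("label count does not match channel count")

    if sample_rate == int(sample_rate) and n_samp % int(sample_rate) == 0:
        n_records, samp_per_rec = n_samp // int(sample_rate), int(sample_rate)
        rec_dur = 1.0
    else:
        # single record spanning the whole file: no zero-padding, exact roundtrip
        n_records, samp_per_rec = 1, n_samp
        rec_dur = n_samp / sample_rate

    # per-channel physical range; digital range fixed at the 16-bit extremes
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    hdr = bytearray()
    hdr += _field("0", 8)                       # version
    hdr += _field("X X X X", 80)                # patient id (anonymous)
    hdr += _field("Startdate 01-JAN-2000 X X X", 80)
    hdr += _field("01.01.00", 8)                # start date
    hdr += _field("00.00.00", 8)                # start time
    hdr += _field(str(256 * (n_ch + 1)), 8)     # header bytes
    hdr += _field("", 44)                       # reserved
    hdr += _field(str(n_records), 8)
    dur = f"{rec_dur:.6f}".rstrip("0").rstrip(".") if rec_dur != int(rec_dur) else str(int(rec_dur))
    hdr += _field(dur, 8)
    hdr += _field(str(n_ch), 4)

    def per_channel(fmt, width):
        for c in range(n_ch):
            hdr.extend(_field(fmt(c), width))

    per_channel(lambda c: str(labels[c]), 16)
    per_channel(lambda c: "AgAgCl electrode", 80)
    per_channel(lambda c: unit, 8)
    per_channel(lambda c: f"{pmin[c]:.6g}", 8)
    per_channel(lambda c: f"{pmax[c]:.6g}", 8)
    per_channel(lambda c: str(_DIG_MIN), 8)
    per_channel(lambda c: str(_DIG_MAX), 8)
    per_channel(lambda c: "", 80)               # prefiltering
    per_channel(lambda c: str(samp_per_rec), 8)
    per_channel(lambda c: "", 32)               # reserved

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint((data - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_records):
            block = digital[:, r * samp_per_rec:(r + 1) * samp_per_rec]
            fh.write(block.tobytes())  # channel-major within the record


def quantization_step(data: np.ndarray) -> np.ndarray:
    """Per-channel physical value of one digital unit, as written by write_edf."""
    data = np.asarray(data, dtype=float)
    pmin, pmax = data.min(axis=1), data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    return (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
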