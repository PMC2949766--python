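"""Domain types, the sensorimotor montage, and recording/event/config I/O.

Conventions used throughout the package:

* all event times are in **seconds** from recording start;
* intervals are half-open ``[start, end)``;
* the sample holding time ``t`` is ``floor(t * rate)``;
* EEG amplitudes are in **microvolts**.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MI_CLASSES = ("feet", "left_hand", "right_hand")

#: 27 sensorimotor electrodes (10/20 extended) as a 3 x 9 grid:
#: frontocentral, central and centroparietal rows, left to right.
SENSORIMOTOR_GRID = (
    ("FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"),
    ("T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"),
    ("TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"),
)


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class FormatError(ValueError):
    """A file does not parse under the named format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    sample_rate: float
    channel_labels: tuple[str, ...]
    data: np.ndarray
    reference: str = "monopolar"
    start_time: float = 0.0

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.data.ndim != 2:
            raise ValidationError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            dupes = {l for l in self.channel_labels if self.channel_labels.count(l) > 1}
            raise ValidationError(f"duplicate channel labels: {sorted(dupes)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording "
                           f"(has {list(self.channel_labels)})") from None

    def pick(self, labels: Sequence[str]) -> "EEGRecording":
        rows = [self.channel(l) for l in labels]
        return replace(self, channel_labels=tuple(labels), data=np.vstack(rows))

    def sample_index(self, t: float) -> int:
        return int(math.floor((t - self.start_time) * self.sample_rate))


@dataclass(frozen=True)
class Montage:
    """Electrode geometry: schematic 2-D positions, 4-neighbour map, bipolar pairs."""

    positions: Mapping[str, tuple[float, float]]
    neighbor_map: Mapping[str, tuple[str, ...]]
    bipolar_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        known = set(self.positions)
        for label, nbrs in self.neighbor_map.items():
            missing = [n for n in (label, *nbrs) if n not in known]
            if missing:
                raise ValidationError(f"neighbor map references unknown labels {missing}")
        for anode, cathode in self.bipolar_pairs:
            if anode not in known or cathode not in known:
                raise ValidationError(f"bipolar pair ({anode}, {cathode}) references unknown labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.positions)


@dataclass(frozen=True)
class PhaseTiming:
    """Cue-paced trial phases, in seconds. Default is the 13-s protocol:
    4 s fixation cross, 1 s visual guidance, 5 s motor imagery, 3 s blank."""

    fixation_s: float = 4.0
    guidance_s: float = 1.0
    mi_s: float = 5.0
    iti_s: float = 3.0

    def __post_init__(self):
        if min(self.fixation_s, self.guidance_s, self.mi_s, self.iti_s) <= 0:
            raise ValidationError("all phase durations must be > 0")

    @property
    def trial_s(self) -> float:
        return self.fixation_s + self.guidance_s + self.mi_s + self.iti_s

    @property
    def mi_start_s(self) -> float:
        """MI onset on the trial axis (after fixation + guidance)."""
        return self.fixation_s + self.guidance_s

    @property
    def mi_end_s(self) -> float:
        return self.mi_start_s + self.mi_s


@dataclass
class TrialSet:
    """Trial starts (seconds from recording start) and their MI classes."""

    onsets: np.ndarray
    classes: tuple[str, ...]
    phase_timing: PhaseTiming = field(default_factory=PhaseTiming)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.classes = tuple(self.classes)
        if self.onsets.ndim != 1 or len(self.onsets) != len(self.classes):
            raise ValidationError("onsets and classes must be equal-length 1-D sequences")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValidationError("onsets must be strictly increasing")
        bad = sorted(set(self.classes) - set(MI_CLASSES))
        if bad:
            raise ValidationError(
                f"unknown classes {bad}; allowed: {list(MI_CLASSES)}")

    def __len__(self) -> int:
        return len(self.onsets)

    def class_counts(self) -> dict[str, int]:
        return {c: self.classes.count(c) for c in sorted(set(self.classes))}

    def select(self, cls: str) -> "TrialSet":
        keep = [i for i, c in enumerate(self.classes) if c == cls]
        return TrialSet(self.onsets[keep], tuple(self.classes[i] for i in keep),
                        self.phase_timing)

    def mi_windows(self) -> np.ndarray:
        """(n_trials, 2) array of [start, end) MI intervals in recording time."""
        t = self.phase_timing
        return np.column_stack([self.onsets + t.mi_start_s, self.onsets + t.mi_end_s])


@dataclass
class RunConfig:
    """Pipeline configuration with the protocol's defaults."""

    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (25.0, 35.0)
    bp_window_s: float = 1.0
    update_rate: float = 16.0
    feet_threshold: float | None = None
    hand_threshold: float | None = None
    cv_folds: int = 10
    lda_timestep_s: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("mu_band", "beta_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValidationError(f"{name} must be a non-empty interval in (0, Nyquist)")
            setattr(self, name, (float(lo), float(hi)))
        if self.bp_window_s <= 0 or self.update_rate <= 0 or self.lda_timestep_s <= 0:
            raise ValidationError("bp_window_s, update_rate and lda_timestep_s must be > 0")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        raw = raw or {}
        for key in ("mu_band", "beta_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path):
        path = Path(path)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d))


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def default_montage() -> Montage:
    """The 27-electrode sensorimotor montage.

    Neighbours are the four orthogonal grid neighbours (anterior, left, right,
    posterior); edge electrodes keep whichever of those exist. Three synthetic
    bipolar cathodes Cz', C4', C3' sit anterior of their anodes (25 mm on the
    scalp; the 2-D coordinates are schematic, one grid step = one unit).
    """
    positions: dict[str, tuple[float, float]] = {}
    neighbor_map: dict[str, tuple[str, ...]] = {}
    grid = SENSORIMOTOR_GRID
    n_rows, n_cols = len(grid), len(grid[0])
    for r in range(n_rows):
        for c in range(n_cols):
            positions[grid[r][c]] = (float(c - n_cols // 2), float(n_rows // 2 - r))
    for r in range(n_rows):
        for c in range(n_cols):
            nbrs = []
            for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):  # ant, left, right, post
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    nbrs.append(grid[rr][cc])
            neighbor_map[grid[r][c]] = tuple(nbrs)
    pairs = []
    for anode in ("Cz", "C4", "C3"):
        cathode = anode + "'"
        x, y = positions[anode]
        positions[cathode] = (x, y + 0.25)
        pairs.append((anode, cathode))
    return Montage(positions, neighbor_map, tuple(pairs))


def montage_subset(montage: Montage, labels: Sequence[str]) -> Montage:
    """Restrict a montage to ``labels``: neighbour entries keep only surviving
    neighbours; bipolar pairs survive only if both members do. Useful for
    small simulations that need just a few channels."""
    keep = set(labels)
    missing = sorted(keep - set(montage.positions))
    if missing:
        raise ValidationError(f"labels not in montage: {missing}")
    positions = {l: montage.positions[l] for l in labels}
    neighbor_map = {l: tuple(n for n in nbrs if n in keep)
                    for l, nbrs in montage.neighbor_map.items() if l in keep}
    neighbor_map = {l: nbrs for l, nbrs in neighbor_map.items() if nbrs}
    pairs = tuple(p for p in montage.bipolar_pairs if p[0] in keep and p[1] in keep)
    return Montage(positions, neighbor_map, pairs)


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: EEGRecording, path, fmt: str = "edf") -> None:
    """Write a recording as EDF (16-bit) or CSV (full double precision).

    The CSV dialect is one header row of channel labels and one column per
    channel; it does not store the sampling rate.
    """
    if rec.n_channels == 0:
        raise ValidationError("cannot write a recording with no channels")
    if fmt == "edf":
        from . import _edf
        _edf.write_edf(path, rec.data, rec.sample_rate, rec.channel_labels)
    elif fmt == "csv":
        df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown recording format {fmt!r} (use 'edf' or 'csv')")


def read_recording(path, fmt: str = "edf", sample_rate: float | None = None) -> EEGRecording:
    """Read an EDF or CSV recording.

    CSV files carry no rate, so ``sample_rate`` is required for ``fmt="csv"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "edf":
        import mne
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # mne raises assorted types on malformed files
            raise FormatError(f"{path} is not a readable EDF file: {exc}") from exc
        data_uv = raw.get_data() * 1e6  # mne returns volts
        return EEGRecording(sample_rate=float(raw.info["sfreq"]),
                            channel_labels=tuple(raw.ch_names), data=data_uv)
    if fmt == "csv":
        if sample_rate is None:
            raise ValueError("sample_rate is required when reading CSV recordings")
        with open(path) as fh:  # pandas mangles duplicate headers, so read them raw
            labels = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate channel labels in {path}")
        try:
            df = pd.read_csv(path, header=0, names=labels)
        except Exception as exc:
            raise FormatError(f"{path} is not a readable CSV file: {exc}") from exc
        return EEGRecording(sample_rate=float(sample_rate), channel_labels=tuple(labels),
                            data=df.to_numpy(dtype=float).T)
    raise ValueError(f"unknown recording format {fmt!r} (use 'edf' or 'csv')")


# ---------------------------------------------------------------------------
# event I/O
# ---------------------------------------------------------------------------

def write_events(trials: TrialSet, path) -> None:
    """Write trials as TSV with columns ``onset_s`` and ``class``."""
    df = pd.DataFrame({"onset_s": trials.onsets, "class": list(trials.classes)})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path, phase_timing: PhaseTiming | None = None) -> TrialSet:
    """Read a TSV trial table (columns onset_s, class) into a TrialSet."""
    df = pd.read_csv(path, sep="\t", dtype={"class": str})
    for col in ("onset_s", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        return TrialSet(np.empty(0), (), phase_timing or PhaseTiming())
    return TrialSet(df["onset_s"].to_numpy(float), tuple(df["class"]),
                    phase_timing or PhaseTiming())
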