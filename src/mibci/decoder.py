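"""Asynchronous online decoding, replayable offline.

Two detectors run in parallel on the streaming band-power features: a single
threshold on beta log band power at Cz (feet MI -> move forward) and the hand
LDA with a symmetric dead zone (output beyond +/- the hand threshold ->
rotate left / rotate right). Feedback bars and avatar commands are emitted at
the display update rate (16 Hz by default, one frame every
``sample_rate / update_rate`` samples); no command is sent while a bar stays
below its threshold. Filter and window state carry across streamed blocks, so
block-streamed replay is bit-identical to whole-record replay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import LDAModel
from .evaluation import best_threshold, mi_window_mask, sample_roc
from .features import HAND_FEATURES, FeatureStreamer, bipolar_derive
from .io import EEGRecording, Montage, RunConfig, TrialSet, ValidationError, default_montage

FEET_ACTION = "forward"
LEFT_ACTION = "rotate_left"
RIGHT_ACTION = "rotate_right"


@dataclass(frozen=True)
class AvatarCommand:
    """One display frame: time of the frame and the set of avatar actions."""

    frame_time: float
    actions: frozenset[str]

    def __post_init__(self):
        if LEFT_ACTION in self.actions and RIGHT_ACTION in self.actions:
            raise ValidationError("rotate_left and rotate_right cannot co-occur")

    def to_json(self) -> str:
        return json.dumps({"frame_time": self.frame_time,
                           "actions": sorted(self.actions)})


@dataclass
class DetectorState:
    """Operating thresholds and the current feedback-bar values."""

    feet_threshold: float | None = None
    hand_threshold: float | None = None
    hand_threshold_neg: float | None = None  # optional asymmetric lower bound
    feet_bar: float = float("-inf")
    hand_bar: float = 0.0

    def require_set(self):
        if self.feet_threshold is None or self.hand_threshold is None:
            raise ValidationError(
                "detector thresholds are unset; call set_thresholds() first")
        if not (np.isfinite(self.feet_threshold) and np.isfinite(self.hand_threshold)):
            raise ValidationError("detector thresholds must be finite")
        if self.hand_threshold < 0:
            raise ValidationError("hand_threshold is a dead-zone half-width and must be >= 0")

    @property
    def lower(self) -> float:
        """Negative-side hand bound (defaults to the symmetric -threshold)."""
        if self.hand_threshold_neg is not None:
            return self.hand_threshold_neg
        return -float(self.hand_threshold)


class OnlineDecoder:
    """Streaming decoding engine; feed blocks of bipolar samples in order.

    ``process(block)`` consumes channels x samples arrays (any block length,
    including sizes that straddle frame boundaries) and returns the avatar
    commands whose frames completed inside the block.
    """

    def __init__(self, model: LDAModel, state: DetectorState,
                 config: RunConfig | None = None, rate: float = 256.0,
                 channel_labels=("Cz", "C4", "C3"), dwell_frames: int = 0):
        config = config or RunConfig()
        state.require_set()
        if rate % config.update_rate != 0:
            raise ValidationError(
                f"update rate {config.update_rate} Hz must divide the sampling rate {rate} Hz")
        self.model = model
        self.state = state
        self.config = config
        self.rate = rate
        self.step = int(rate // config.update_rate)
        self.dwell_frames = int(dwell_frames)
        self._streamer = FeatureStreamer(channel_labels, config, rate)
        self._pending: dict[str, list] = {name: [] for name in (*HAND_FEATURES, "beta_Cz")}
        self._n_seen = 0          # samples consumed so far
        self._n_framed = 0        # samples already attributed to emitted frames
        self._dwell: dict[str, int] = {FEET_ACTION: 0, LEFT_ACTION: 0, RIGHT_ACTION: 0}

    def process(self, block: np.ndarray) -> list[AvatarCommand]:
        block = np.atleast_2d(np.asarray(block, dtype=float))
        series = self._streamer.process(block)
        for name, vals in series.items():
            self._pending[name].append(vals)
        self._n_seen += block.shape[1]
        commands = []
        n_frames = (self._n_seen - self._n_framed) // self.step
        if n_frames == 0:
            return commands
        buf = {name: np.concatenate(chunks) for name, chunks in self._pending.items()}
        for f in range(n_frames):
            # bar values are read at the last sample of each frame interval
            i = (f + 1) * self.step - 1
            feet_bar = buf["beta_Cz"][i]
            x = np.array([buf[name][i] for name in HAND_FEATURES])
            hand_out = float(self.model.decision(x)[0])
            frame_time = (self._n_framed + (f + 1) * self.step) / self.rate
            commands.append(self._emit(frame_time, feet_bar, hand_out))
        consumed = n_frames * self.step
        self._pending = {name: [vals[consumed:]] for name, vals in buf.items()}
        self._n_framed += consumed
        return commands

    def _emit(self, frame_time: float, feet_bar: float, hand_out: float) -> AvatarCommand:
        st = self.state
        st.feet_bar, st.hand_bar = float(feet_bar), float(hand_out)
        raw = set()
        if feet_bar > st.feet_threshold:
            raw.add(FEET_ACTION)
        if hand_out > st.hand_threshold:
            raw.add(LEFT_ACTION)
        elif hand_out < st.lower:
            raw.add(RIGHT_ACTION)
        actions = set()
        for act in (FEET_ACTION, LEFT_ACTION, RIGHT_ACTION):
            self._dwell[act] = self._dwell[act] + 1 if act in raw else 0
            if act in raw and self._dwell[act] > self.dwell_frames:
                actions.add(act)
        return AvatarCommand(frame_time, frozenset(actions))


def decode_stream(rec: EEGRecording, model: LDAModel, state: DetectorState,
                  config: RunConfig | None = None, montage: Montage | None = None,
                  dwell_frames: int = 0) -> list[AvatarCommand]:
    """Replay a whole recording through the online decoding engine.

    Monopolar recordings are bipolar-derived through the montage first.
    """
    config = config or RunConfig()
    if rec.reference != "bipolar":
        rec = bipolar_derive(rec, montage or default_montage())
    dec = OnlineDecoder(model, state, config, rec.sample_rate,
                        rec.channel_labels, dwell_frames)
    return dec.process(rec.data)


def set_thresholds(policy: str = "manual", feet_threshold: float | None = None,
                   hand_threshold: float | None = None,
                   feet_bar: np.ndarray | None = None,
                   hand_output: np.ndarray | None = None,
                   bar_times: np.ndarray | None = None,
                   trials: TrialSet | None = None) -> DetectorState:
    """Populate a DetectorState.

    ``manual`` echoes explicit threshold values (the protocol's default:
    thresholds were hand-set at the start of training). ``roc_best`` derives
    each threshold from a labelled calibration stream: the sample-wise ROC of
    the feet bar (and of |LDA output| for the hand detector) against the MI
    mask, taking the balanced operating point closest to R_TP = 1 - R_FP.
    """
    if policy == "manual":
        if feet_threshold is None or hand_threshold is None:
            raise ValidationError("manual policy needs explicit feet and hand thresholds")
        return DetectorState(float(feet_threshold), float(hand_threshold))
    if policy == "roc_best":
        if feet_bar is None or hand_output is None or bar_times is None or trials is None:
            raise ValidationError(
                "roc_best policy needs feet_bar, hand_output, bar_times and trials")
        mask = mi_window_mask(np.asarray(bar_times, dtype=float), trials)
        feet_pt = best_threshold(sample_roc(np.asarray(feet_bar, float), mask))
        hand_pt = best_threshold(sample_roc(np.abs(np.asarray(hand_output, float)), mask))
        return DetectorState(feet_pt.threshold, hand_pt.threshold)
    raise ValueError(f"unknown threshold policy {policy!r}")


def replay_report(commands: list[AvatarCommand], trials: TrialSet) -> pd.DataFrame:
    """Per-trial hit/miss table for a replayed command stream.

    A trial is a *hit* if any frame inside its MI window (half-open) carries
    the action its class maps to. ``attrs['rest_trigger_fraction']`` is the
    fraction of rest-period frames carrying any action.
    """
    action_for = {"feet": FEET_ACTION, "left_hand": LEFT_ACTION,
                  "right_hand": RIGHT_ACTION}
    times = np.array([c.frame_time for c in commands])
    windows = trials.mi_windows()
    rows = []
    in_any_mi = np.zeros(len(commands), dtype=bool)
    for j, (onset, cls) in enumerate(zip(trials.onsets, trials.classes)):
        start, end = windows[j]
        in_win = (times >= start) & (times < end) if len(commands) else np.array([], bool)
        in_any_mi |= in_win
        hits = sum(1 for i in np.flatnonzero(in_win)
                   if action_for[cls] in commands[i].actions)
        rows.append({"trial": j, "class": cls, "n_frames_mi": int(in_win.sum()),
                     "n_hits": int(hits), "hit": hits > 0})
    table = pd.DataFrame(rows, columns=["trial", "class", "n_frames_mi", "n_hits", "hit"])
    rest_idx = np.flatnonzero(~in_any_mi)
    triggered = sum(1 for i in rest_idx if commands[i].actions)
    table.attrs["rest_trigger_fraction"] = (triggered / len(rest_idx)) if len(rest_idx) else 0.0
    return table


def write_commands(commands: list[AvatarCommand], path) -> None:
    """JSON-lines export: one {frame_time, actions} record per frame."""
    with open(path, "w") as fh:
        for c in commands:
            fh.write(c.to_json() + "\n")


def read_commands(path) -> list[AvatarCommand]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(AvatarCommand(float(d["frame_time"]),
                                         frozenset(d["actions"])))
    return out
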