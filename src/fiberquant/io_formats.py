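"""Readers/writers for the file dialects the pipeline touches.

Photometry recordings arrive as frame-interleaved CSV (one row per camera
frame, two LED states alternating), behaviour tracks as a two-column CSV
export of an automated tracker. Both get small dataclass containers with
eager invariant checking so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

#: LED-state column encodings accepted by default: literal wavelengths and
#: the common 1/2 flag dialect.
DEFAULT_LED_MAP = {1: 415, 2: 470, 415: 415, 470: 470}

FREEZING = 1
MOVING = 0

STATE_NAMES = {FREEZING: "freezing", MOVING: "moving"}


@dataclass
class RawPhotometrySession:
    """Frame-interleaved two-LED recording.

    Attributes
    ----------
    frame_index : int array, one entry per frame.
    timestamp_s : strictly increasing frame timestamps (seconds).
    led_state : per-frame LED wavelength, 415 or 470, alternating.
    fluorescence : per-frame fluorescence value (arbitrary units).
    ttl_events : timestamps of TTL sync pulses, within the recording span.
    """

    frame_index: np.ndarray
    timestamp_s: np.ndarray
    led_state: np.ndarray
    fluorescence: np.ndarray
    ttl_events: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.timestamp_s = np.asarray(self.timestamp_s, dtype=float)
        self.led_state = np.asarray(self.led_state, dtype=np.int64)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.ttl_events = np.asarray(self.ttl_events, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamp_s)
        if n == 0:
            raise IntegrityError("empty photometry session")
        if not (len(self.frame_index) == len(self.led_state) == len(self.fluorescence) == n):
            raise IntegrityError("photometry session columns have unequal lengths")
        if np.any(np.diff(self.timestamp_s) <= 0):
            bad = int(np.argmax(np.diff(self.timestamp_s) <= 0)) + 1
            raise IntegrityError(f"timestamps not strictly increasing at frame {bad}")
        bad_states = set(np.unique(self.led_state)) - {415, 470}
        if bad_states:
            raise IntegrityError(f"unknown LED states: {sorted(bad_states)}")
        if n > 1 and np.any(self.led_state[1:] == self.led_state[:-1]):
            bad = int(np.argmax(self.led_state[1:] == self.led_state[:-1])) + 1
            raise IntegrityError(f"LED state does not alternate at frame {bad}")
        if self.ttl_events.size:
            lo, hi = self.timestamp_s[0], self.timestamp_s[-1]
            if self.ttl_events.min() < lo or self.ttl_events.max() > hi:
                raise IntegrityError("TTL events outside recording span")

    @property
    def n_frames(self) -> int:
        return len(self.timestamp_s)


@dataclass
class ChannelPair:
    """Deinterleaved 470/415 streams on a common uniform time grid."""

    time_s: np.ndarray
    f470: np.ndarray
    f415: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f470 = np.asarray(self.f470, dtype=float)
        self.f415 = np.asarray(self.f415, dtype=float)
        if not (len(self.time_s) == len(self.f470) == len(self.f415)):
            raise IntegrityError("channel pair vectors have unequal lengths")


@dataclass
class BehaviorTrack:
    """Time-stamped binary behaviour samples (1 = freezing, 0 = moving)."""

    time_s: np.ndarray
    state: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int8)
        if len(self.time_s) != len(self.state):
            raise IntegrityError("behaviour track vectors have unequal lengths")
        if len(self.time_s) == 0:
            raise IntegrityError("empty behaviour track")
        if np.any(np.diff(self.time_s) < 0):
            raise IntegrityError("behaviour timestamps must be nondecreasing")
        if not np.isin(self.state, (0, 1)).all():
            raise IntegrityError("behaviour states must be 0 or 1")


REQUIRED_PHOTOMETRY_COLUMNS = ("FrameCounter", "Timestamp", "LedState", "Fluorescence")


def read_photometry_csv(path, led_map=None) -> RawPhotometrySession:
    """Parse a frame-interleaved photometry CSV.

    Required columns: FrameCounter, Timestamp, LedState, Fluorescence.
    An optional TTL column (0/1 flags) marks sync pulses. ``led_map``
    translates the LedState encoding; defaults accept {1,2} and {415,470}.
    """
    led_map = dict(DEFAULT_LED_MAP if led_map is None else led_map)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty photometry file") from None
    for col in REQUIRED_PHOTOMETRY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    try:
        led = np.array([led_map[int(v)] for v in df["LedState"]])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: unmappable LedState value ({exc})") from None
    ttl = np.empty(0)
    if "TTL" in df.columns:
        ttl = df["Timestamp"].to_numpy(float)[df["TTL"].to_numpy() != 0]
    return RawPhotometrySession(
        frame_index=df["FrameCounter"].to_numpy(),
        timestamp_s=df["Timestamp"].to_numpy(float),
        led_state=led,
        fluorescence=df["Fluorescence"].to_numpy(float),
        ttl_events=ttl,
    )


def write_photometry_csv(session: RawPhotometrySession, path) -> None:
    ttl_flags = np.isin(session.timestamp_s, session.ttl_events).astype(int)
    pd.DataFrame(
        {
            "FrameCounter": session.frame_index,
            "Timestamp": session.timestamp_s,
            "LedState": session.led_state,
            "Fluorescence": session.fluorescence,
            "TTL": ttl_flags,
        }
    ).to_csv(path, index=False)


def deinterleave(session: RawPhotometrySession) -> ChannelPair:
    """Split an interleaved session into aligned 470/415 streams.

    The common time grid is the 470-frame timestamps (signal channel
    governs); each 415 value is paired with the 415 frame of matching
    order index. Lengths are equalized by dropping at most one trailing
    frame, so the effective rate is half the acquisition rate.
    """
    m470 = session.led_state == 470
    m415 = session.led_state == 415
    f470 = session.fluorescence[m470]
    f415 = session.fluorescence[m415]
    if f470.size == 0 or f415.size == 0:
        raise IntegrityError("deinterleave requires frames from both channels")
    n = min(f470.size, f415.size)
    return ChannelPair(
        time_s=session.timestamp_s[m470][:n],
        f470=f470[:n],
        f415=f415[:n],
    )


def read_behavior_csv(path) -> BehaviorTrack:
    """Parse a behaviour CSV with columns Time and Freezing (0/1)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty behaviour file") from None
    for col in ("Time", "Freezing"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise FormatError(f"{path}: behaviour file has no rows")
    states = np.empty(len(df), dtype=np.int8)
    for i, v in enumerate(df["Freezing"]):
        try:
            iv = int(v)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: unparseable Freezing value at row {i + 2}") from None
        if iv not in (0, 1):
            raise FormatError(f"{path}: Freezing value must be 0/1 at row {i + 2}")
        states[i] = iv
    return BehaviorTrack(time_s=df["Time"].to_numpy(float), state=states)


def write_behavior_csv(track: BehaviorTrack, path) -> None:
    pd.DataFrame({"Time": track.time_s, "Freezing": track.state}).to_csv(path, index=False)
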