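"""Synchronize behaviour with the photometry time base and build epochs.

Each photometry sample takes the state of the behaviour sample with the
minimum absolute timestamp difference (ties go to the earlier behaviour
sample). Maximal constant-state runs become epochs; runs shorter than the
minimum bout duration are dropped outright — they leave gaps, they are not
merged into neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ConfigError
from .io_formats import STATE_NAMES, BehaviorTrack, RawPhotometrySession

#: Minimum bout duration retained in epoch metrics, seconds.
DEFAULT_MIN_BOUT_S = 2.0

_TIE_TOL_S = 1e-9


@dataclass
class AlignedLabels:
    """Per-photometry-frame behaviour state and its source timestamp."""

    time_s: np.ndarray
    state: np.ndarray
    source_time_s: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int8)
        self.source_time_s = np.asarray(self.source_time_s, dtype=float)
        if not (len(self.time_s) == len(self.state) == len(self.source_time_s)):
            raise ConfigError("aligned label vectors have unequal lengths")


@dataclass
class EpochSet:
    """Ordered, non-overlapping behaviour epochs surviving the bout filter."""

    epochs: list  # (start_s, end_s, state_name)
    min_bout_s: float = DEFAULT_MIN_BOUT_S

    def duration(self, state_name: str) -> float:
        return float(sum(e - s for s, e, st in self.epochs if st == state_name))

    def states(self) -> set:
        return {st for _, _, st in self.epochs}


def ttl_zeroed_times(session: RawPhotometrySession) -> np.ndarray:
    """Photometry timestamps re-based so the first TTL pulse is time zero.

    The behaviour protocol start emits a TTL pulse into the photometry
    system; subtracting the first pulse puts both recordings on the
    behaviour clock. Without TTL events the timestamps are returned as-is.
    """
    if session.ttl_events.size == 0:
        return session.timestamp_s.copy()
    return session.timestamp_s - session.ttl_events[0]


def align_behavior(track: BehaviorTrack, time_s: np.ndarray) -> AlignedLabels:
    """Label each photometry sample by nearest-timestamp behaviour state."""
    t = np.asarray(time_s, dtype=float)
    bt = track.time_s
    if t.size == 0:
        raise AlignmentError("empty photometry time grid")
    if bt[-1] < t[0] or bt[0] > t[-1]:
        raise AlignmentError("behaviour and photometry time ranges are disjoint")
    idx = np.searchsorted(bt, t)
    idx = np.clip(idx, 1, len(bt) - 1) if len(bt) > 1 else np.zeros_like(idx)
    if len(bt) == 1:
        chosen = np.zeros(t.shape, dtype=int)
    else:
        d_prev = np.abs(t - bt[idx - 1])
        d_next = np.abs(bt[idx] - t)
        take_prev = d_prev <= d_next + _TIE_TOL_S
        chosen = np.where(take_prev, idx - 1, idx)
    return AlignedLabels(time_s=t, state=track.state[chosen], source_time_s=bt[chosen])


def extract_epochs(labels: AlignedLabels, min_bout_s: float = DEFAULT_MIN_BOUT_S) -> EpochSet:
    """Maximal constant-state runs, keeping those at least ``min_bout_s`` long.

    A run's duration counts one frame period past its last sample:
    ``(t_last - t_first) + dt``. Runs strictly shorter than the threshold
    are excluded (a run of exactly the threshold duration is retained).
    """
    t = labels.time_s
    s = labels.state
    if t.size == 0:
        return EpochSet(epochs=[], min_bout_s=min_bout_s)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    boundaries = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [t.size]))  # exclusive sample index
    epochs = []
    for i0, i1 in zip(starts, ends):
        duration = (t[i1 - 1] - t[i0]) + dt
        if duration >= min_bout_s - _TIE_TOL_S:
            epochs.append((float(t[i0]), float(t[i1 - 1] + dt), STATE_NAMES[int(s[i0])]))
    return EpochSet(epochs=epochs, min_bout_s=min_bout_s)
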