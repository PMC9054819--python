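"""Trace metrics: area under the curve, peak frequency, mean peak height.

AUC is the positive-part rectangle sum — samples above the x-axis times the
frame period; negative excursions contribute nothing (the baseline shift
exists precisely to lift traces onto the axis). Per-state values are
normalized by the summed duration of that state's epochs. Peaks are local
maxima exceeding ``median + 2*SD`` of the whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .behavior_align import EpochSet
from .dff_pipeline import DffTrace
from .errors import ConfigError

#: Minimum separation between detected peaks, seconds. 0 disables.
DEFAULT_MIN_PEAK_GAP_S = 0.25


@dataclass
class PeakSet:
    """Detected transient peaks and the threshold that admitted them."""

    peak_times_s: np.ndarray
    peak_heights: np.ndarray
    threshold: float

    def __post_init__(self):
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_s)


@dataclass
class TraceMetrics:
    """Session- and state-level summary of one dF/F trace.

    Per-state entries exist only for states with nonzero retained epoch
    duration; a missing state means "undefined", never zero.
    ``mean_peak_height`` is None when no peaks were detected.
    """

    auc_total: float
    auc_per_state: dict = field(default_factory=dict)
    peak_frequency_per_state: dict = field(default_factory=dict)
    mean_peak_height: float | None = None
    n_peaks: int = 0
    peak_threshold: float = float("nan")


def _dt(trace: DffTrace) -> float:
    if len(trace.time_s) < 2:
        raise ConfigError("trace too short to determine frame period")
    return float(np.median(np.diff(trace.time_s)))


def compute_auc(trace: DffTrace, epochs: EpochSet | None = None):
    """Positive-part AUC (dF/F * s); per-state values normalized by duration.

    Returns ``auc_total`` when ``epochs`` is None, else
    ``(auc_total, {state: normalized_auc})``. Sample membership in an epoch
    is half-open: ``start <= t < end``.
    """
    dt = _dt(trace)
    pos = np.maximum(trace.dff, 0.0)
    auc_total = float(pos.sum() * dt)
    if epochs is None:
        return auc_total
    per_state = {}
    for state in sorted(epochs.states()):
        dur = epochs.duration(state)
        if dur <= 0:
            continue
        sel = np.zeros(len(trace.time_s), dtype=bool)
        for s, e, st in epochs.epochs:
            if st == state:
                sel |= (trace.time_s >= s) & (trace.time_s < e)
        per_state[state] = float(pos[sel].sum() * dt / dur)
    return auc_total, per_state


def detect_peaks(trace: DffTrace, min_peak_gap_s: float = DEFAULT_MIN_PEAK_GAP_S) -> PeakSet:
    """Local maxima strictly above ``median + 2*SD`` of the session.

    SD uses the sample convention (ddof=1). Peaks closer than
    ``min_peak_gap_s`` are thinned keeping the higher one.
    """
    if len(trace.dff) < 3:
        raise ConfigError("need at least 3 samples for peak detection")
    dff = trace.dff
    sd = float(np.std(dff, ddof=1))
    threshold = float(np.median(dff)) + 2.0 * sd
    dt = _dt(trace)
    distance = max(1, int(round(min_peak_gap_s / dt))) if min_peak_gap_s > 0 else 1
    idx, _ = find_peaks(dff, height=np.nextafter(threshold, np.inf), distance=distance)
    return PeakSet(peak_times_s=trace.time_s[idx], peak_heights=dff[idx], threshold=threshold)


def peak_frequency(peaks: PeakSet, epochs: EpochSet) -> dict:
    """Peaks per second per state; states with zero duration are omitted."""
    out = {}
    for state in sorted(epochs.states()):
        dur = epochs.duration(state)
        if dur <= 0:
            continue
        count = 0
        for s, e, st in epochs.epochs:
            if st == state:
                count += int(np.sum((peaks.peak_times_s >= s) & (peaks.peak_times_s < e)))
        out[state] = count / dur
    return out


def mean_peak_height(peaks: PeakSet) -> float | None:
    """Arithmetic mean of peak heights; None when there are no peaks."""
    if peaks.n_peaks == 0:
        return None
    return float(peaks.peak_heights.mean())


def compute_metrics(
    trace: DffTrace,
    epochs: EpochSet | None = None,
    min_peak_gap_s: float = DEFAULT_MIN_PEAK_GAP_S,
) -> TraceMetrics:
    """All three metrics in one pass."""
    peaks = detect_peaks(trace, min_peak_gap_s=min_peak_gap_s)
    if epochs is None:
        auc_total = compute_auc(trace)
        per_state, freq = {}, {}
    else:
        auc_total, per_state = compute_auc(trace, epochs)
        freq = peak_frequency(peaks, epochs)
    return TraceMetrics(
        auc_total=auc_total,
        auc_per_state=per_state,
        peak_frequency_per_state=freq,
        mean_peak_height=mean_peak_height(peaks),
        n_peaks=peaks.n_peaks,
        peak_threshold=peaks.threshold,
    )
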