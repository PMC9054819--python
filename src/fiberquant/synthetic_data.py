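"""Ground-truthed synthetic generators for every input kind the pipeline consumes.

Each generator takes an explicit integer seed, draws all randomness from a
single ``numpy.random.Generator``, and returns the injected ground truth
alongside the artifact, so every downstream stage can be tested against known
answers without any external data.

Signal model for the two-channel recording:

* 470 nm (calcium-dependent): ``bleach(t) * (1 + sum of transients) +
  artifacts + noise``. Transients are difference-of-exponential kernels
  (rise/decay), multiplicative on the bleach curve so their raw amplitude
  tracks the instantaneous fluorescence level.
* 415 nm (isosbestic): its own biexponential bleach curve, the *same*
  additive motion artifacts scaled by ``shared_gain``, plus noise — and no
  calcium transients.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError
from .io_formats import FREEZING, MOVING, BehaviorTrack, RawPhotometrySession
from .pnn_quant import ImageStack


@dataclass
class PhotomSimConfig:
    """Parameters of a simulated two-channel photometry session.

    Rates are in Hz, times in seconds, amplitudes of transients in
    dimensionless dF/F units (multiplicative on the bleach curve), artifact
    amplitude and noise SD in raw fluorescence units. The 415-channel bleach
    parameters default to the 470 ones when left as None.
    """

    duration_s: float = 300.0
    frame_rate_hz: float = 40.0
    event_rate_hz: float = 0.1
    event_amplitude_dff: float = 0.05
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.5
    bleach_amp1: float = 0.3
    bleach_tau1_s: float = 60.0
    bleach_amp2: float = 0.2
    bleach_tau2_s: float = 600.0
    bleach_offset: float = 1.0
    artifact_rate_hz: float = 0.0
    artifact_amplitude: float = 0.1
    artifact_width_s: float = 0.2
    shared_gain: float = 1.0
    noise_sd: float = 0.0
    min_event_gap_s: float = 2.0
    bleach415_amp1: float | None = None
    bleach415_tau1_s: float | None = None
    bleach415_amp2: float | None = None
    bleach415_tau2_s: float | None = None
    bleach415_offset: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame_rate_hz must be positive")
        if round(self.frame_rate_hz) % 2:
            raise ConfigError("frame_rate_hz must be even (two alternating channels)")
        for name in ("event_rate_hz", "artifact_rate_hz", "noise_sd", "min_event_gap_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("tau_rise_s", "tau_decay_s", "bleach_tau1_s", "bleach_tau2_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.tau_rise_s >= self.tau_decay_s:
            raise ConfigError("tau_rise_s must be < tau_decay_s")


@dataclass
class GroundTruth:
    """Everything injected by a generator, for downstream verification."""

    event_times_s: np.ndarray | None = None
    event_amplitudes: np.ndarray | None = None
    artifact_times_s: np.ndarray | None = None
    true_bouts: list | None = None
    true_contiguity: list | None = None
    ring_rois: list | None = None
    true_effect_size: float | None = None

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                continue
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def transient_kernel(t, tau_rise, tau_decay):
    """Difference-of-exponentials kernel normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return k / peak


def _poisson_times(rng, rate, duration, min_gap=0.0):
    """Event times from a Poisson process with a refractory minimum gap."""
    if rate <= 0:
        return np.empty(0)
    times = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        times.append(t)
        t += min_gap + rng.exponential(1.0 / rate)
    return np.array(times)


def simulate_session(config: PhotomSimConfig):
    """Simulate a frame-interleaved two-channel recording.

    Returns ``(RawPhotometrySession, GroundTruth)``. Frame 0 carries the
    415 nm LED, frame 1 the 470 nm LED, and so on; the effective per-channel
    rate is half the acquisition frame rate. A TTL pulse is placed at the
    first frame (behaviour clock zero).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n_frames) / cfg.frame_rate_hz
    led = np.where(np.arange(n_frames) % 2 == 0, 415, 470)

    event_times = _poisson_times(rng, cfg.event_rate_hz, cfg.duration_s, cfg.min_event_gap_s)
    artifact_times = _poisson_times(rng, cfg.artifact_rate_hz, cfg.duration_s)

    m470 = led == 470
    m415 = led == 415
    t470, t415 = t[m470], t[m415]

    b470 = _biexp(t470, cfg.bleach_amp1, cfg.bleach_tau1_s, cfg.bleach_amp2, cfg.bleach_tau2_s, cfg.bleach_offset)
    b415 = _biexp(
        t415,
        cfg.bleach415_amp1 if cfg.bleach415_amp1 is not None else cfg.bleach_amp1,
        cfg.bleach415_tau1_s if cfg.bleach415_tau1_s is not None else cfg.bleach_tau1_s,
        cfg.bleach415_amp2 if cfg.bleach415_amp2 is not None else cfg.bleach_amp2,
        cfg.bleach415_tau2_s if cfg.bleach415_tau2_s is not None else cfg.bleach_tau2_s,
        cfg.bleach415_offset if cfg.bleach415_offset is not None else cfg.bleach_offset,
    )

    transients = np.zeros_like(t470)
    for te in event_times:
        transients += cfg.event_amplitude_dff * transient_kernel(t470 - te, cfg.tau_rise_s, cfg.tau_decay_s)

    def artifacts_on(grid):
        out = np.zeros_like(grid)
        w = cfg.artifact_width_s / 2.0
        for ta in artifact_times:
            out += cfg.artifact_amplitude * np.exp(-0.5 * ((grid - ta) / w) ** 2)
        return out

    f470 = b470 * (1.0 + transients) + artifacts_on(t470)
    f415 = b415 + cfg.shared_gain * artifacts_on(t415)
    if cfg.noise_sd > 0:
        f470 = f470 + rng.normal(0.0, cfg.noise_sd, f470.shape)
        f415 = f415 + rng.normal(0.0, cfg.noise_sd, f415.shape)

    fluor = np.empty(n_frames)
    fluor[m470] = f470
    fluor[m415] = f415

    session = RawPhotometrySession(
        frame_index=np.arange(n_frames),
        timestamp_s=t,
        led_state=led,
        fluorescence=fluor,
        ttl_events=np.array([t[0]]),
    )
    truth = GroundTruth(
        event_times_s=event_times,
        event_amplitudes=np.full(event_times.shape, cfg.event_amplitude_dff),
        artifact_times_s=artifact_times,
    )
    return session, truth


def simulate_behavior(
    duration_s: float,
    bout_rate: float = 0.05,
    mean_bout_s: float = 20.0,
    seed: int = 0,
    sample_rate_hz: float = 10.0,
    quantize_s: float | None = None,
):
    """Simulate alternating freezing/moving bouts tiling [0, duration].

    Bout durations are exponential with mean ``mean_bout_s``; ``bout_rate``
    acts as an on/off switch — when zero (or negative) a single bout covers
    the whole session. ``quantize_s`` snaps bout boundaries to a grid
    (useful for exact downstream recovery). Returns a track sampled at
    ``sample_rate_hz`` plus the full bout list, including bouts below any
    downstream filter threshold.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if sample_rate_hz <= 0:
        raise ConfigError("sample_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    state = int(rng.integers(0, 2))
    bouts = []
    if bout_rate <= 0:
        bouts = [(0.0, float(duration_s), state)]
    else:
        if mean_bout_s <= 0:
            raise ConfigError("mean_bout_s must be positive")
        t = 0.0
        while t < duration_s:
            dur = rng.exponential(mean_bout_s)
            if quantize_s:
                dur = max(quantize_s, round(dur / quantize_s) * quantize_s)
            end = min(t + dur, duration_s)
            if end > t:
                bouts.append((t, end, state))
            t = end
            state = 1 - state

    n = int(round(duration_s * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    states = np.empty(n, dtype=np.int8)
    starts = np.array([b[0] for b in bouts])
    labels = np.array([b[2] for b in bouts], dtype=np.int8)
    # tiny tolerance so samples landing a float-ulp before a quantized bout
    # boundary are assigned to the bout that starts there
    idx = np.clip(np.searchsorted(starts, times + 1e-9, side="right") - 1, 0, len(bouts) - 1)
    states[:] = labels[idx]

    track = BehaviorTrack(time_s=times, state=states)
    truth = GroundTruth(true_bouts=[(s, e, STATE_NAME[st]) for s, e, st in bouts])
    return track, truth


STATE_NAME = {FREEZING: "freezing", MOVING: "moving"}


def simulate_pnn_image(
    n_rings: int = 5,
    fragmentation: float = 0.2,
    image_px: int = 128,
    um_per_px: float = 0.2,
    seed: int = 0,
    n_planes: int = 8,
    ring_radius_px: int | None = None,
    ring_thickness_px: int = 3,
    noise_sd: float = 0.0,
):
    """Draw ring-shaped bright structures mimicking labelled net surfaces.

    ``fragmentation`` is the fraction of each ring's circumference removed as
    angular gaps (3 gaps per ring when > 0), so rings split into arcs. The
    true largest-component fraction of each ring is measured directly on the
    generated noise-free mask (8-connectivity) and stored in the ground
    truth, along with a square ROI polygon around each ring.

    The ring is bright in the top half of the z-stack and dim in the bottom
    half, so a top-half maximum projection isolates the clean structure.
    """
    if not 0.0 <= fragmentation <= 1.0:
        raise ConfigError("fragmentation must be in [0, 1]")
    if n_rings < 1:
        raise ConfigError("n_rings must be >= 1")
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    grid_cols = int(math.ceil(math.sqrt(n_rings)))
    grid_rows = int(math.ceil(n_rings / grid_cols))
    cell = image_px // max(grid_cols, grid_rows)
    radius = ring_radius_px if ring_radius_px is not None else max(4, cell // 3)

    yy, xx = np.mgrid[0:image_px, 0:image_px]
    mask = np.zeros((image_px, image_px), dtype=bool)
    contiguities = []
    rois = []
    for k in range(n_rings):
        r_cell, c_cell = divmod(k, grid_cols)
        cy = r_cell * cell + cell // 2
        cx = c_cell * cell + cell // 2
        dist = np.hypot(yy - cy, xx - cx)
        ring = np.abs(dist - radius) <= ring_thickness_px / 2.0
        if fragmentation > 0:
            theta = np.arctan2(yy - cy, xx - cx)  # [-pi, pi]
            n_gaps = 3
            gap_width = fragmentation * 2 * math.pi / n_gaps
            centers = rng.uniform(-math.pi, math.pi, n_gaps)
            for gc in centers:
                d = np.abs(np.angle(np.exp(1j * (theta - gc))))
                ring &= d > gap_width / 2.0
        mask |= ring
        lab, n_comp = ndimage.label(ring, structure=np.ones((3, 3), dtype=int))
        total = int(ring.sum())
        if total == 0:
            contiguities.append(0.0)
        else:
            sizes = np.bincount(lab.ravel())[1:]
            contiguities.append(float(sizes.max() / total))
        half = radius + ring_thickness_px + 2
        rois.append(
            [
                [cy - half, cx - half],
                [cy - half, cx + half],
                [cy + half, cx + half],
                [cy + half, cx - half],
            ]
        )

    nz_top = n_planes // 2
    stack = np.full((n_planes, image_px, image_px), 10.0)
    for z in range(n_planes):
        level = 200.0 if z < nz_top else 40.0
        stack[z][mask] = level
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)

    image = ImageStack(voxels=stack, um_per_px=um_per_px, z_step_um=0.37)
    truth = GroundTruth(true_contiguity=contiguities, ring_rois=rois)
    return image, truth


def simulate_two_groups(n1: int, n2: int, true_d: float, seed: int = 0):
    """Two normal samples with unit SD separated by ``true_d``."""
    if n1 < 2 or n2 < 2:
        raise ConfigError("group sizes must be >= 2")
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, 1.0, n1)
    g2 = rng.normal(true_d, 1.0, n2)
    return g1, g2
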