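"""Transform a deinterleaved channel pair into a baseline-corrected dF/F trace.

Processing stages, in order:

1. ``fit_biexponential`` — fit the isosbestic (415 nm) channel to
   ``F(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) + c`` to capture photobleaching.
2. ``scale_reference`` — ordinary least squares mapping of the reference
   vector (fitted curve by default, raw 415 optionally) onto the
   calcium-dependent 470 nm channel.
3. ``compute_dff`` — ``(f470 - scaled) / scaled``.
4. ``baseline_correct`` — shift the test-session trace upward by the absolute
   difference between the home-cage baseline mean (middle window of the
   home-cage recording) and the test-session minimum, so traces that dipped
   below the x-axis are lifted onto it.

The baseline shift is a pure translation: it changes no variance, peak
count, or relative structure, only the area measured against the x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, IntegrityError
from .io_formats import ChannelPair


@dataclass
class BleachFit:
    """Biexponential bleach model ``a1*exp(-t/tau1) + a2*exp(-t/tau2) + c``."""

    a1: float
    tau1_s: float
    a2: float
    tau2_s: float
    c: float
    sse: float
    fallback: str | None = None  # None, "single_exp" or "constant"

    def curve(self, time_s: np.ndarray) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        return self.a1 * np.exp(-t / self.tau1_s) + self.a2 * np.exp(-t / self.tau2_s) + self.c


@dataclass
class ScaledReference:
    """Linear map of a reference vector onto the signal channel."""

    slope: float
    intercept: float
    scaled: np.ndarray


@dataclass
class DffTrace:
    """Uniformly sampled dF/F with processing provenance."""

    time_s: np.ndarray
    dff: np.ndarray
    baseline_offset: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.time_s) != len(self.dff):
            raise IntegrityError("time and dff vectors have unequal lengths")
        if not np.isfinite(self.dff).all():
            raise IntegrityError("dff contains non-finite values")

    @property
    def dt(self) -> float:
        if len(self.time_s) < 2:
            return float("nan")
        return float(np.median(np.diff(self.time_s)))


@dataclass
class BaselineSpec:
    """Inputs of the baseline shift.

    ``hc`` is the home-cage dF/F on its own time grid ``hc_time_s``;
    ``hc_window`` selects the stretch averaged as the baseline (default the
    middle 3 min of a 5-min recording, chosen to avoid handling stress at
    the edges). ``test`` is the test-session dF/F to be corrected.
    """

    hc: np.ndarray
    hc_time_s: np.ndarray
    test: np.ndarray
    hc_window: tuple = (60.0, 240.0)

    def __post_init__(self):
        self.hc = np.asarray(self.hc, dtype=float)
        self.hc_time_s = np.asarray(self.hc_time_s, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if len(self.hc) != len(self.hc_time_s):
            raise ConfigError("hc and hc_time_s must have equal lengths")
        if len(self.test) < 1:
            raise ConfigError("test trace must be non-empty")


def _sse(y, yhat):
    r = np.asarray(y) - np.asarray(yhat)
    return float(np.dot(r, r))


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def _single_exp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_biexponential(f415: np.ndarray, time_s: np.ndarray) -> BleachFit:
    """Nonlinear least-squares biexponential fit of the isosbestic channel.

    Initialization: ``a1 = a2 = (F[0]-F[-1])/2``, ``tau1 = span/10``,
    ``tau2 = span``, ``c = F[-1]``; amplitudes and time constants bounded
    below by zero. A single-exponential fit is always run as well: if it
    beats the biexponential, the biexponential is restarted from it, and if
    it still wins it is returned embedded (``a2 = 0``) with
    ``fallback="single_exp"`` — so the reported SSE never exceeds the
    single-exponential special case. Near-constant input short-circuits to
    a constant model.
    """
    f = np.asarray(f415, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if f.size < 5:
        raise ConfigError("need at least 5 samples to fit a biexponential")
    if f.size != t.size:
        raise ConfigError("f415 and time_s must have equal lengths")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ConfigError("time span must be positive")
    t0 = t - t[0]

    if np.ptp(f) < 1e-12 * max(1.0, abs(f[0])):
        c = float(f.mean())
        return BleachFit(0.0, span / 10, 0.0, span, c, _sse(f, c), fallback="constant")

    amp0 = (f[0] - f[-1]) / 2.0
    p0 = [amp0, span / 10, amp0, span, f[-1]]
    lo = [0.0, 1e-9, 0.0, 1e-9, -np.inf]
    hi = [np.inf] * 4 + [np.inf]

    def try_fit(func, p0, bounds):
        try:
            popt, _ = curve_fit(func, t0, f, p0=p0, bounds=bounds, maxfev=20000)
            return popt, _sse(f, func(t0, *popt))
        except (RuntimeError, ValueError):
            return None, np.inf

    popt_bi, sse_bi = try_fit(_biexp, p0, (lo, hi))
    popt_si, sse_si = try_fit(_single_exp, [max(amp0 * 2, 0.0), span / 5, f[-1]], ([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]))

    if popt_si is not None and sse_si < sse_bi:
        a, tau, c = popt_si
        popt_bi2, sse_bi2 = try_fit(_biexp, [a, tau, 0.0, span, c], (lo, hi))
        if popt_bi2 is not None and sse_bi2 < sse_bi:
            popt_bi, sse_bi = popt_bi2, sse_bi2

    if popt_bi is not None and sse_bi <= sse_si:
        a1, tau1, a2, tau2, c = popt_bi
        return BleachFit(float(a1), float(tau1), float(a2), float(tau2), float(c), sse_bi)
    if popt_si is not None:
        a, tau, c = popt_si
        return BleachFit(float(a), float(tau), 0.0, span, float(c), sse_si, fallback="single_exp")
    c = float(f.mean())
    return BleachFit(0.0, span / 10, 0.0, span, c, _sse(f, c), fallback="constant")


def scale_reference(fit_curve: np.ndarray, f470: np.ndarray) -> ScaledReference:
    """OLS slope/intercept mapping the reference onto the 470 channel."""
    x = np.asarray(fit_curve, dtype=float)
    y = np.asarray(f470, dtype=float)
    if x.size != y.size:
        raise ConfigError("fit_curve and f470 must have equal lengths")
    vx = x.var()
    if vx == 0:
        raise ConfigError("zero-variance reference: degenerate regression")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    return ScaledReference(slope=slope, intercept=intercept, scaled=slope * x + intercept)


def compute_dff(f470: np.ndarray, scaled: ScaledReference, time_s: np.ndarray | None = None) -> DffTrace:
    """``dff[i] = (f470[i] - scaled[i]) / scaled[i]``."""
    f = np.asarray(f470, dtype=float)
    s = np.asarray(scaled.scaled, dtype=float)
    if f.size != s.size:
        raise ConfigError("f470 and scaled must have equal lengths")
    nonpos = np.flatnonzero(s <= 0)
    if nonpos.size:
        raise ConfigError(f"scaled reference non-positive at index {int(nonpos[0])}: dF/F undefined")
    t = np.arange(f.size, dtype=float) if time_s is None else np.asarray(time_s, dtype=float)
    return DffTrace(
        time_s=t,
        dff=(f - s) / s,
        provenance={"slope": scaled.slope, "intercept": scaled.intercept},
    )


def baseline_correct(spec: BaselineSpec) -> DffTrace:
    """Shift the test trace by ``|mean(hc window) - min(test)|``.

    The offset is always added, so whenever the test minimum sits at or
    below the home-cage baseline mean, the corrected minimum lands exactly
    on that mean. The corrected trace differs from the input by a constant:
    variance and peak structure are untouched.
    """
    sel = (spec.hc_time_s >= spec.hc_window[0]) & (spec.hc_time_s <= spec.hc_window[1])
    if not sel.any():
        raise ConfigError("empty home-cage baseline window")
    hc_mean = float(spec.hc[sel].mean())
    offset = abs(hc_mean - float(spec.test.min()))
    return DffTrace(
        time_s=np.arange(spec.test.size, dtype=float),
        dff=spec.test + offset,
        baseline_offset=offset,
        provenance={"hc_mean": hc_mean, "test_min": float(spec.test.min())},
    )


def process_session(pair: ChannelPair, reference: str = "fit") -> DffTrace:
    """Channel pair → dF/F: bleach fit, linear scaling, normalization.

    ``reference="fit"`` scales the fitted bleach curve onto the 470 channel
    (smooth reference; suppresses isosbestic noise). ``reference="raw"``
    scales the raw 415 samples instead, which also subtracts shared motion
    artifacts at the cost of adding isosbestic noise.
    """
    fit = fit_biexponential(pair.f415, pair.time_s)
    curve = fit.curve(pair.time_s - pair.time_s[0])
    if reference == "fit":
        ref = curve
    elif reference == "raw":
        ref = pair.f415
    else:
        raise ConfigError(f"unknown reference mode '{reference}'")
    scaled = scale_reference(ref, pair.f470)
    trace = compute_dff(pair.f470, scaled, time_s=pair.time_s)
    trace.provenance.update(
        {
            "reference": reference,
            "bleach_fit": {
                "a1": fit.a1,
                "tau1_s": fit.tau1_s,
                "a2": fit.a2,
                "tau2_s": fit.tau2_s,
                "c": fit.c,
                "sse": fit.sse,
                "fallback": fit.fallback,
            },
        }
    )
    return trace


def correct_with_homecage(test: DffTrace, homecage: DffTrace, hc_window: tuple = (60.0, 240.0)) -> DffTrace:
    """Baseline-correct a test trace against a home-cage trace."""
    spec = BaselineSpec(hc=homecage.dff, hc_time_s=homecage.time_s, test=test.dff, hc_window=hc_window)
    shifted = baseline_correct(spec)
    return DffTrace(
        time_s=test.time_s,
        dff=shifted.dff,
        baseline_offset=shifted.baseline_offset,
        provenance={**test.provenance, **shifted.provenance},
    )
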