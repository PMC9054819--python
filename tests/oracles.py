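"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — loops, stacks, direct formula
transcriptions — kept free of any package internals so they can stand as
second opinions against the library code paths.
"""

import numpy as np


def flood_fill_fraction(mask):
    """Largest connected component fraction via explicit stack flood fill, 8-conn."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty mask")
    best = 0
    n_comp = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not visited[r0, c0]:
                n_comp += 1
                size = 0
                stack = [(r0, c0)]
                visited[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == 0 and dc == 0:
                                continue
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not visited[rr, cc]:
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                best = max(best, size)
    return best / total, n_comp


def brute_auc(dff, dt):
    """Positive-part rectangle sum, one sample at a time."""
    total = 0.0
    for v in dff:
        if v > 0:
            total += v * dt
    return total


def brute_auc_per_state(times, dff, dt, epochs):
    """Per-state normalized AUC by exhaustive sample membership."""
    sums, durs = {}, {}
    for s, e, st in epochs:
        durs[st] = durs.get(st, 0.0) + (e - s)
        for t, v in zip(times, dff):
            if s <= t < e and v > 0:
                sums[st] = sums.get(st, 0.0) + v * dt
    return {st: sums.get(st, 0.0) / durs[st] for st in durs if durs[st] > 0}


def brute_peak_frequency(peak_times, epochs):
    """Peaks/s per state by exhaustive interval membership."""
    counts, durs = {}, {}
    for s, e, st in epochs:
        durs[st] = durs.get(st, 0.0) + (e - s)
        for pt in peak_times:
            if s <= pt < e:
                counts[st] = counts.get(st, 0) + 1
    return {st: counts.get(st, 0) / durs[st] for st in durs if durs[st] > 0}


def eq1_corrected(hc_mean, test):
    """Direct transcription of the printed baseline-correction formula."""
    test = np.asarray(test, dtype=float)
    offset = abs(-hc_mean - (-np.min(test)))
    return test + offset


def ols_slope_intercept(x, y):
    """Normal-equations OLS, written out longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def nearest_state_bruteforce(behavior_times, behavior_states, photometry_times):
    """All-pairs nearest-timestamp labelling; ties to the earlier sample."""
    out = np.empty(len(photometry_times), dtype=np.int8)
    for i, t in enumerate(photometry_times):
        best_j = 0
        best_d = abs(t - behavior_times[0])
        for j in range(1, len(behavior_times)):
            d = abs(t - behavior_times[j])
            if d < best_d - 1e-9:
                best_d = d
                best_j = j
        out[i] = behavior_states[best_j]
    return out


def shoelace_mm2(vertices, um_per_px):
    """Polygon area by the shoelace formula, term by term."""
    v = list(vertices)
    acc = 0.0
    for i in range(len(v)):
        r1, c1 = v[i]
        r2, c2 = v[(i + 1) % len(v)]
        acc += r1 * c2 - r2 * c1
    return abs(acc) / 2.0 * (um_per_px**2) / 1e6


def cohen_d_formula(g1, g2):
    """Pooled-SD standardized mean difference, transcribed directly."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    s1 = sum((v - m1) ** 2 for v in g1) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in g2) / (n2 - 1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return (m2 - m1) / pooled**0.5


def biexp_sse(t, f, params):
    a1, tau1, a2, tau2, c = params
    pred = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c
    r = f - pred
    return float(r @ r)


def random_search_biexp(t, f, n_draws=1000, seed=0):
    """Best SSE over random biexponential parameter draws."""
    rng = np.random.default_rng(seed)
    span = t[-1] - t[0]
    amp_scale = max(np.ptp(f), 1e-6)
    best = np.inf
    for _ in range(n_draws):
        params = (
            rng.uniform(0, 2 * amp_scale),
            rng.uniform(span / 100, span * 2),
            rng.uniform(0, 2 * amp_scale),
            rng.uniform(span / 100, span * 2),
            rng.uniform(f.min() - amp_scale, f.max() + amp_scale),
        )
        best = min(best, biexp_sse(t, f, params))
    return best
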