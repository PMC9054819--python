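"""Two-group effect-size estimation: Cohen's d with bootstrap BCa intervals.

This is estimation, not testing: each comparison gets an effect size and a
confidence interval; no multiplicity adjustment is applied across
comparisons. Conventions where the literature leaves slack:

* pooled-SD Cohen's d (no small-sample correction; Hedges' g by flag);
* within-group independent resampling with replacement;
* the bias-correction fraction counts ties as one half;
* acceleration from the leave-one-out jackknife over all observations of
  both groups.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .errors import ConfigError

DEFAULT_N_RESAMPLES = 5000
DEFAULT_CI_LEVEL = 0.95


@dataclass
class TwoGroupEffect:
    """Cohen's d with a bootstrap confidence interval."""

    d: float
    ci_low: float
    ci_high: float
    n_resamples: int = DEFAULT_N_RESAMPLES
    ci_level: float = DEFAULT_CI_LEVEL
    method: str = "BCa"
    seed: int = 0
    label: str | None = None
    n_degenerate: int = 0
    resamples: np.ndarray | None = None


def _validate_group(g, name):
    g = np.asarray(g, dtype=float)
    if g.size < 2:
        raise ConfigError(f"{name} needs at least 2 values")
    if not np.isfinite(g).all():
        raise ConfigError(f"{name} contains non-finite values")
    return g


def cohen_d(g1, g2) -> float:
    """``(mean(g2) - mean(g1)) / pooled SD`` with (n-1)-weighted pooling."""
    g1 = _validate_group(g1, "g1")
    g2 = _validate_group(g2, "g2")
    n1, n2 = g1.size, g2.size
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ConfigError("zero pooled SD: Cohen's d undefined")
    return float((g2.mean() - g1.mean()) / np.sqrt(pooled_var))


def hedges_g(g1, g2) -> float:
    """Cohen's d with the small-sample bias correction factor."""
    g1 = _validate_group(g1, "g1")
    g2 = _validate_group(g2, "g2")
    dof = g1.size + g2.size - 2
    return cohen_d(g1, g2) * (1.0 - 3.0 / (4.0 * dof - 1.0))


def _bootstrap_d(rng, g1, g2, n_resamples):
    """Vectorized bootstrap replicates of Cohen's d; NaN where degenerate."""
    n1, n2 = g1.size, g2.size
    s1 = g1[rng.integers(0, n1, size=(n_resamples, n1))]
    s2 = g2[rng.integers(0, n2, size=(n_resamples, n2))]
    v1 = s1.var(axis=1, ddof=1)
    v2 = s2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (s2.mean(axis=1) - s1.mean(axis=1)) / np.sqrt(pooled)
    d[pooled <= 0] = np.nan
    return d


def _jackknife_acceleration(g1, g2):
    n1, n2 = g1.size, g2.size
    d_jack = np.empty(n1 + n2)
    for i in range(n1):
        d_jack[i] = cohen_d(np.delete(g1, i), g2)
    for j in range(n2):
        d_jack[n1 + j] = cohen_d(g1, np.delete(g2, j))
    resid = d_jack.mean() - d_jack
    denom = np.sum(resid**2) ** 1.5
    if denom == 0:
        return 0.0
    return float(np.sum(resid**3) / (6.0 * denom))


def bootstrap_effect(
    g1,
    g2,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int = 0,
    method: str = "BCa",
    keep_resamples: bool = False,
    label: str | None = None,
) -> TwoGroupEffect:
    """Bootstrap Cohen's d with a BCa (or percentile) confidence interval.

    Degenerate resamples (zero pooled variance) are dropped and counted;
    more than half degenerate is an error. Deterministic under a fixed seed.
    """
    g1 = _validate_group(g1, "g1")
    g2 = _validate_group(g2, "g2")
    if n_resamples < 1:
        raise ConfigError("n_resamples must be >= 1")
    if not 0.0 <= ci_level < 1.0:
        raise ConfigError("ci_level must be in [0, 1)")
    d_obs = cohen_d(g1, g2)
    rng = np.random.default_rng(seed)
    d_star = _bootstrap_d(rng, g1, g2, n_resamples)
    degenerate = np.isnan(d_star)
    n_degen = int(degenerate.sum())
    if n_degen > n_resamples / 2:
        raise ConfigError(f"{n_degen}/{n_resamples} degenerate resamples: bootstrap unreliable")
    d_star = d_star[~degenerate]
    b = d_star.size

    alpha = 1.0 - ci_level
    if method == "percentile":
        lo = float(np.quantile(d_star, alpha / 2))
        hi = float(np.quantile(d_star, 1 - alpha / 2))
    elif method == "BCa":
        # bias correction: fraction of resamples below the observed d, ties half
        p = (np.sum(d_star < d_obs) + 0.5 * np.sum(d_star == d_obs)) / b
        p = min(max(p, 1.0 / (2 * b)), 1.0 - 1.0 / (2 * b))
        z0 = ndtri(p)
        a = _jackknife_acceleration(g1, g2)
        z_lo, z_hi = ndtri(alpha / 2), ndtri(1 - alpha / 2)

        def adj(z):
            return ndtr(z0 + (z0 + z) / (1.0 - a * (z0 + z)))

        lo = float(np.quantile(d_star, adj(z_lo)))
        hi = float(np.quantile(d_star, adj(z_hi)))
    else:
        raise ConfigError(f"unknown CI method '{method}'")

    return TwoGroupEffect(
        d=d_obs,
        ci_low=lo,
        ci_high=hi,
        n_resamples=n_resamples,
        ci_level=ci_level,
        method=method,
        seed=seed,
        label=label,
        n_degenerate=n_degen,
        resamples=d_star if keep_resamples else None,
    )


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-label seed so pair order never changes results."""
    digest = hashlib.sha256(f"{master_seed}|{label}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def multi_two_group(
    pairs,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int = 0,
    method: str = "BCa",
) -> list:
    """One independent TwoGroupEffect per (label, g1, g2) pair.

    Pairs that fail (e.g. zero variance) yield an entry carrying the error
    rather than aborting the remaining comparisons. Per-pair seeds are
    derived from the master seed and the label, so results are stable under
    reordering.
    """
    if not pairs:
        raise ConfigError("need at least one pair")
    results = []
    for label, g1, g2 in pairs:
        pair_seed = derive_seed(seed, str(label))
        try:
            results.append(
                bootstrap_effect(
                    g1, g2, n_resamples=n_resamples, ci_level=ci_level, seed=pair_seed, method=method, label=str(label)
                )
            )
        except ConfigError as exc:
            results.append(("error", str(label), str(exc)))
    return results
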