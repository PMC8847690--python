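"""Experiment-wide significance for correlated multi-trait genome scans.

Running K correlated genome scans multiplies the number of tests, but a plain
Bonferroni correction over-counts because the scans share traits and samples.
This module provides both the Bonferroni comparator and an empirical
family-wise threshold obtained by resampling the maximum |Z| from the
multivariate normal null implied by the observed cross-scan Z-score
correlation: draw S sets of M K-dimensional null vectors, keep the most
extreme |Z| per set, and take a percentile (default 95th) of those maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "z_to_p",
    "p_to_z",
    "bonferroni_threshold",
    "repair_correlation",
    "resampling_threshold",
    "ThresholdEstimate",
]


def z_to_p(z):
    """Two-sided normal tail probability of a Z-score.

    Uses the survival function directly so that very large |z| (well past
    the double-precision limit of ``1 - cdf``) keep full relative accuracy.
    """
    return 2.0 * norm.sf(np.abs(z))


def p_to_z(p):
    """Positive Z-score whose two-sided tail probability is ``p``."""
    return norm.isf(np.asarray(p) / 2.0)


def bonferroni_threshold(alpha_gw: float, n_scans: int) -> float:
    """Per-scan p-value cutoff from a genome-wide alpha split over scans."""
    if not 0.0 < alpha_gw < 1.0:
        raise ValueError(f"alpha_gw must be in (0,1), got {alpha_gw}")
    if n_scans < 1:
        raise ValueError(f"n_scans must be >= 1, got {n_scans}")
    return alpha_gw / n_scans


def repair_correlation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Return the nearest valid correlation matrix by eigenvalue clipping.

    Negative eigenvalues are clipped at zero and the diagonal rescaled to 1.
    A matrix already positive semi-definite (within ``tol``) is returned
    symmetrized but otherwise untouched.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() >= -tol:
        return R
    w = np.clip(w, 0.0, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    d[d == 0] = 1.0
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return 0.5 * (R2 + R2.T)


def _mvn_factor(R: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = R, valid for singular PSD matrices."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


@dataclass(frozen=True)
class ThresholdEstimate:
    """A resampled experiment-wide significance cutoff and its provenance."""

    z_star: float
    p_star: float
    percentile: float
    n_sets: int
    set_size: int
    scan_correlation: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_star < 1.0:
            raise ValueError("p_star out of (0,1)")


def resampling_threshold(
    R: np.ndarray,
    set_size: int = 1_000_000,
    n_sets: int = 10_000,
    percentile: float = 0.95,
    seed: int = 0,
    chunk: int = 262_144,
) -> ThresholdEstimate:
    """Empirical FWER threshold via max-|Z| resampling from MVN(0, R).

    For each of ``n_sets`` sets, ``set_size`` independent K-vectors are drawn
    from the multivariate normal with correlation ``R`` (the cross-scan null),
    the maximum |Z| over the set is recorded, and ``z_star`` is the requested
    percentile of the ``n_sets`` maxima (linear interpolation between order
    statistics). Sampling is chunked so memory stays bounded at roughly
    ``chunk × K`` doubles regardless of ``set_size``.
    """
    if set_size < 1 or n_sets < 1:
        raise ValueError("set_size and n_sets must be >= 1")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0,1)")
    R = repair_correlation(np.asarray(R, dtype=float))
    L = _mvn_factor(R)
    K = R.shape[0]
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_sets)
    for s in range(n_sets):
        best = 0.0
        done = 0
        while done < set_size:
            m = min(chunk, set_size - done)
            z = rng.standard_normal((m, K)) @ L.T
            best = max(best, float(np.abs(z).max()))
            done += m
        maxima[s] = best
    z_star = float(np.quantile(maxima, percentile))
    return ThresholdEstimate(
        z_star=z_star,
        p_star=float(z_to_p(z_star)),
        percentile=percentile,
        n_sets=n_sets,
        set_size=set_size,
        scan_correlation=R,
        seed=seed,
    )
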