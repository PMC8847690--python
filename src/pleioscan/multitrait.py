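"""N-weighted multivariate meta-analysis of correlated GWAS Z-scores.

A scan combines K traits' per-variant Z-scores into one statistic

    z_multi = Σ_i w_i z_i / sqrt(w' R w),      w_i = sqrt(N_i),

where R is the cross-trait correlation of Z-scores under the null (driven by
phenotypic correlation and sample overlap). With R = I and equal N this
reduces to sample-size-weighted fixed-effect meta-analysis, (Σ z_i)/√K; with
perfectly correlated traits it returns the shared z unchanged, so redundancy
is never rewarded. R is estimated from the genome-wide Z-score correlation
across all shared variants (optionally restricted to variants that are null
in every trait, since strong signals inflate the estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .significance import repair_correlation, z_to_p
from .sumstats import HarmonizedPanel

__all__ = [
    "ScanDefinition",
    "CrossTraitZCorrelation",
    "MultiTraitResult",
    "enumerate_scans",
    "estimate_z_correlation",
    "ngwama_combine",
    "run_scan",
    "direction_string",
]


@dataclass(frozen=True)
class ScanDefinition:
    """An ordered subset of panel traits analyzed jointly (size 2 or 3)."""

    traits: tuple

    def __post_init__(self):
        if len(set(self.traits)) != len(self.traits):
            raise ValueError(f"duplicate traits in scan: {self.traits}")
        if not 1 <= len(self.traits) <= 3:
            raise ValueError("scans combine 1-3 traits (1 allowed for testing only)")

    @property
    def label(self) -> str:
        return ",".join(self.traits)

    def __len__(self):
        return len(self.traits)


def enumerate_scans(core, risk=()):
    """Scan design around a core disease pair plus individual risk factors.

    Returns, in deterministic order: the core bivariate scan, one trivariate
    scan per risk factor (core + risk), and one bivariate scan pairing the
    first core trait with each risk factor. Two core traits and R risk
    factors therefore yield 1 + 2R scans (15 for the nine-trait design).
    """
    core = tuple(core)
    risk = tuple(risk)
    if len(core) != 2:
        raise ValueError("core must contain exactly two traits")
    all_labels = core + risk
    if len(set(all_labels)) != len(all_labels):
        raise ValueError(f"duplicate trait labels in scan design: {all_labels}")
    scans = [ScanDefinition(core)]
    scans += [ScanDefinition(core + (r,)) for r in risk]
    scans += [ScanDefinition((core[0], r)) for r in risk]
    return scans


@dataclass(frozen=True)
class CrossTraitZCorrelation:
    """Cross-trait null correlation of Z-scores (unit diagonal, PSD)."""

    traits: tuple
    matrix: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (len(self.traits), len(self.traits)):
            raise ValueError("matrix shape does not match trait count")
        if not np.allclose(M, M.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(M) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1,1]")
        object.__setattr__(self, "matrix", M)

    def restrict(self, traits):
        """Sub-correlation for an ordered subset of traits."""
        idx = [self.traits.index(t) for t in traits]
        return CrossTraitZCorrelation(tuple(traits), self.matrix[np.ix_(idx, idx)])


def estimate_z_correlation(panel: HarmonizedPanel, null_restrict=None) -> CrossTraitZCorrelation:
    """Pairwise Pearson correlation of per-trait Z columns over the panel.

    ``null_restrict`` (e.g. 1.96) keeps, for each trait pair, only variants
    with |z| below the cutoff in both traits, approximating the null
    correlation when strong signals are present. The estimate is repaired to
    the nearest positive semi-definite correlation when pairwise restriction
    breaks joint consistency.
    """
    Z = panel.z
    K = Z.shape[1]
    if Z.shape[0] < 1000:
        warnings.warn(f"z correlation estimated from only {Z.shape[0]} variants "
                      "(>=1000 recommended)", stacklevel=2)
    if null_restrict is None:
        R = np.corrcoef(Z, rowvar=False)
        if K == 1:
            R = np.array([[1.0]])
    else:
        R = np.eye(K)
        for i in range(K):
            for j in range(i + 1, K):
                mask = (np.abs(Z[:, i]) < null_restrict) & (np.abs(Z[:, j]) < null_restrict)
                if mask.sum() < 3:
                    raise ValueError(
                        f"fewer than 3 usable variants for pair "
                        f"({panel.traits[i]}, {panel.traits[j]}) after restriction")
                R[i, j] = R[j, i] = np.corrcoef(Z[mask, i], Z[mask, j])[0, 1]
    R = repair_correlation(R)
    return CrossTraitZCorrelation(tuple(panel.traits), R)


def ngwama_combine(z, n, R: CrossTraitZCorrelation, scan_label: str = ""):
    """Combine per-trait Z-scores into (z_multi, p_multi).

    ``z`` and ``n`` are either K-vectors (one variant) or (V, K) arrays;
    weights sqrt(n) are recomputed per variant when sample sizes vary.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    M = R.matrix if isinstance(R, CrossTraitZCorrelation) else np.asarray(R, dtype=float)
    w = np.sqrt(n)
    if z.ndim == 1:
        denom2 = float(w @ M @ w)
        if denom2 <= 0:
            raise ValueError(f"non-positive combination variance in scan {scan_label!r}")
        z_multi = float((w * z).sum() / np.sqrt(denom2))
        return z_multi, float(z_to_p(z_multi))
    if w.ndim == 1:
        w = np.broadcast_to(w, z.shape)
    denom2 = np.einsum("vi,ij,vj->v", w, M, w)
    if np.any(denom2 <= 0):
        raise ValueError(f"non-positive combination variance in scan {scan_label!r}")
    z_multi = (w * z).sum(axis=1) / np.sqrt(denom2)
    return z_multi, z_to_p(z_multi)


def direction_string(z_row) -> str:
    """Per-trait sign summary at a variant, e.g. ``-/-/-`` for a trivariate scan."""
    return "/".join("+" if v > 0 else "-" for v in z_row)


@dataclass
class MultiTraitResult:
    """Per-variant multivariate statistics for one scan.

    ``df`` carries the variant index plus ``z_<trait>``/``p_<trait>`` columns
    for each scan trait, ``z_multi``, ``p_multi`` and the direction string.
    """

    scan: ScanDefinition
    df: pd.DataFrame

    def trait_p_at(self, variant_id: str) -> dict:
        row = self.df.loc[self.df["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        row = row.iloc[0]
        return {t: float(row[f"p_{t}"]) for t in self.scan.traits}


def run_scan(panel: HarmonizedPanel, scan: ScanDefinition,
             R: CrossTraitZCorrelation) -> MultiTraitResult:
    """Apply the N-weighted combination to every panel variant for one scan.

    The panel has no missing cells by construction, so every variant is
    complete-case for every scan; subsetting and sign bookkeeping were
    already resolved at harmonization.
    """
    idx = [panel.trait_index(t) for t in scan.traits]
    Z = panel.z[:, idx]
    N = panel.n[:, idx]
    Rs = R.restrict(scan.traits)
    z_multi, p_multi = ngwama_combine(Z, N, Rs, scan_label=scan.label)
    df = panel.index.copy()
    df["eaf"] = panel.eaf
    for k, t in enumerate(scan.traits):
        df[f"z_{t}"] = Z[:, k]
        df[f"p_{t}"] = z_to_p(Z[:, k])
    df["z_multi"] = z_multi
    df["p_multi"] = p_multi
    df["direction"] = [direction_string(row) for row in Z]
    return MultiTraitResult(scan=scan, df=df)
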