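"""Effective number of independent tests (simpleM) and Bonferroni LOD cutoffs.

The effective test count is estimated chromosome-wise: markers are split into
consecutive map-ordered windows of at most ``window_size``, the Pearson
correlation matrix of genotype codes (missing calls mean-imputed per marker)
is eigendecomposed in each window, and the window's count is the smallest k
whose top-k eigenvalues capture at least a fraction C of the total variance.
The genome-wide m_eff is the sum over windows; windows never span
chromosomes and a final short window is kept as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeMatrix


@dataclass(frozen=True)
class MeffEstimate:
    m_eff: int
    window_size: int
    variance_fraction_C: float
    per_window_counts: tuple

    def __post_init__(self):
        if self.m_eff != sum(self.per_window_counts):
            raise ValueError("m_eff must equal the sum of per-window counts")


@dataclass(frozen=True)
class ThresholdSet:
    alpha_levels: tuple
    lod_thresholds: tuple

    def lod_threshold(self, alpha: float) -> float:
        return self.lod_thresholds[self.alpha_levels.index(alpha)]


def window_effective_count(codes: np.ndarray, C: float = 0.995) -> int:
    """Effective test count of one window.

    ``codes`` is (n_markers, n_animals) of genotype codes with missing as -1.
    Zero-variance markers are excluded (with a warning) since their Pearson
    correlation is undefined. Eigenvalues pushed below zero by rounding are
    clamped before the cumulative sum.
    """
    X = np.asarray(codes, dtype=float)
    X = np.where(X < 0, np.nan, X)
    col_means = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), col_means, X)
    sd = X.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance marker(s) "
                      "excluded from a simpleM window")
        X = X[sd > 0]
    if X.shape[0] == 0:
        return 0
    corr = np.corrcoef(X)
    if corr.ndim == 0:  # single marker
        return 1
    ev = np.linalg.eigvalsh(corr)
    ev = np.clip(ev, 0.0, None)[::-1]
    total = ev.sum()
    k = int(np.searchsorted(np.cumsum(ev), C * total - 1e-12)) + 1
    return min(k, X.shape[0])


def m_eff_simpleM(geno: GenotypeMatrix, window_size: int = 820,
                  C: float = 0.995) -> MeffEstimate:
    """simpleM effective number of independent tests across the genome."""
    if geno.n_markers < 1:
        raise ValueError("need at least one marker")
    if not (0 < C <= 1):
        raise ValueError("variance fraction C must lie in (0, 1]")
    counts = []
    chroms = geno.map.table["chromosome"].to_numpy()
    for chrom in geno.map.chromosomes:
        rows = np.flatnonzero(chroms == chrom)
        for start in range(0, len(rows), window_size):
            block = rows[start:start + window_size]
            counts.append(window_effective_count(geno.calls[block], C))
    return MeffEstimate(m_eff=int(sum(counts)), window_size=window_size,
                        variance_fraction_C=C, per_window_counts=tuple(counts))


def bonferroni_lod_thresholds(m_eff: int,
                              alphas=(0.05, 0.01)) -> ThresholdSet:
    """Genome-wide LOD cutoffs: -log10(alpha / m_eff) for each alpha level."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    for a in alphas:
        if not (0 < a < 1):
            raise ValueError(f"alpha {a} outside (0, 1)")
    lods = tuple(float(-np.log10(a / m_eff)) for a in alphas)
    return ThresholdSet(alpha_levels=tuple(alphas), lod_thresholds=lods)
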