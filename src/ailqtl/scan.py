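"""Per-week single-marker association scans and effect summaries.

Each week is tested independently (no longitudinal covariance model). The
default test is a one-way fixed-effects ANOVA with genotype as a three-level
factor, which yields the genotype-class means reported alongside each QTL;
an additive (allele-dosage) regression is available as an alternative.
Evidence is expressed as LOD = -log10(p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, PhenotypeSeries

_P_FLOOR = 1e-300  # avoids lod = inf when SSE underflows to zero

CLASS_LABELS = {0: "S2S2", 1: "H", 2: "S1S1"}


@dataclass(frozen=True)
class AssociationModelSpec:
    model: str = "genotype_factor_anova"
    min_class_n: int = 5

    def __post_init__(self):
        if self.model not in ("genotype_factor_anova", "additive_regression"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class WeeklyScanResult:
    """One week's scan: a per-marker table of p, LOD, n and class statistics."""

    week: int
    table: pd.DataFrame  # marker_id, chromosome, position_bp, tested, n_used,
    #                      p_value, lod, r_squared, n/mean/sd per genotype class


def lod_from_p(p):
    """LOD = -log10(p); defined for 0 < p <= 1."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    out = -np.log10(p)
    return float(out) if out.ndim == 0 else out


def _class_stats(calls: np.ndarray, y: np.ndarray):
    """Vectorised per-marker, per-class counts, sums and sums of squares.

    calls: int8 (M, N) with -1 missing; y: float (N,) with NaN missing.
    Returns n, s, ss arrays of shape (3, M).
    """
    y_ok = ~np.isnan(y)
    y0 = np.where(y_ok, y, 0.0)
    n = np.empty((3, calls.shape[0]))
    s = np.empty_like(n)
    ss = np.empty_like(n)
    for g in range(3):
        ind = (calls == g) & y_ok[None, :]
        n[g] = ind.sum(axis=1)
        s[g] = ind @ y0
        ss[g] = ind @ (y0 * y0)
    return n, s, ss


def scan_week(geno: GenotypeMatrix, y: np.ndarray, week: int,
              spec: AssociationModelSpec = AssociationModelSpec()
              ) -> WeeklyScanResult:
    """Test every marker against one week's weights (vectorised)."""
    n, s, ss = _class_stats(geno.calls, np.asarray(y, dtype=float))
    valid = n >= spec.min_class_n
    k = valid.sum(axis=0)
    N = np.where(valid, n, 0.0).sum(axis=0)
    S = np.where(valid, s, 0.0).sum(axis=0)
    SS = np.where(valid, ss, 0.0).sum(axis=0)
    tested = (k >= 2) & (N - k >= 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(n > 0, s / n, np.nan)
        var = np.where(n > 1, (ss - n * means**2) / (n - 1), np.nan)
        sds = np.sqrt(np.clip(var, 0.0, None))
        grand = S / np.maximum(N, 1)
        sst = SS - N * grand**2
        ssb = np.where(valid, n * means**2, 0.0).sum(axis=0) - N * grand**2
        ssb = np.clip(ssb, 0.0, None)
        ssw = np.clip(sst - ssb, 0.0, None)
        if spec.model == "genotype_factor_anova":
            F = (ssb / np.maximum(k - 1, 1)) / \
                np.where(ssw > 0, ssw / np.maximum(N - k, 1), np.nan)
            p = stats.f.sf(F, np.maximum(k - 1, 1), np.maximum(N - k, 1))
            # zero within-class variance: perfect separation unless means equal
            degen = tested & (ssw == 0)
            p = np.where(degen & (ssb > 0), _P_FLOOR, p)
            p = np.where(degen & (ssb == 0), 1.0, p)
            r2 = np.where(sst > 0, ssb / sst, 0.0)
        else:
            p, r2 = _additive_regression(geno.calls, y, n, valid, spec)
    p = np.where(tested, np.clip(p, _P_FLOOR, 1.0), np.nan)
    lod = np.where(tested, -np.log10(p), np.nan)
    r2 = np.where(tested, r2, np.nan)

    t = geno.map.table
    table = pd.DataFrame({
        "marker_id": t["marker_id"], "chromosome": t["chromosome"],
        "position_bp": t["position_bp"], "tested": tested,
        "n_used": N.astype(int), "p_value": p, "lod": lod, "r_squared": r2,
    })
    for g, label in CLASS_LABELS.items():
        table[f"n_{label}"] = n[g].astype(int)
        table[f"mean_{label}"] = means[g]
        table[f"sd_{label}"] = sds[g]
    return WeeklyScanResult(week=week, table=table)


def _additive_regression(calls, y, n, valid, spec):
    """Least-squares slope on allele dosage {0,1,2}, two-sided t-test."""
    y = np.asarray(y, dtype=float)
    y_ok = ~np.isnan(y)
    keep = (calls >= 0) & y_ok[None, :]
    # restrict to animals in classes that pass min_class_n
    for g in range(3):
        keep &= ~((calls == g) & ~valid[g][:, None])
    x = np.where(keep, calls, 0.0).astype(float)
    yv = np.where(keep, y[None, :], 0.0)
    N = keep.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx, sy = x.sum(axis=1), yv.sum(axis=1)
        sxx = (x * x).sum(axis=1) - sx**2 / N
        syy = (yv * yv).sum(axis=1) - sy**2 / N
        sxy = (x * yv).sum(axis=1) - sx * sy / N
        r = sxy / np.sqrt(sxx * syy)
        r = np.clip(r, -1.0, 1.0)
        df = N - 2
        tstat = r * np.sqrt(df / np.clip(1 - r**2, 1e-15, None))
        p = 2 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
    return p, r**2


def association_test(geno_row: np.ndarray, pheno_week: np.ndarray,
                     spec: AssociationModelSpec = AssociationModelSpec()):
    """Single-marker test; returns (p_value, r_squared, class_stats) or flags
    the marker untested (p is None) when fewer than two genotype classes pass
    ``min_class_n``."""
    calls = np.asarray(geno_row, dtype=np.int8)[None, :]
    n, s, ss = _class_stats(calls, np.asarray(pheno_week, dtype=float))
    valid = n[:, 0] >= spec.min_class_n
    stats_by_class = {}
    for g, label in CLASS_LABELS.items():
        cnt = int(n[g, 0])
        mean = s[g, 0] / cnt if cnt else None
        sd = None
        if cnt > 1:
            sd = float(np.sqrt(max((ss[g, 0] - cnt * mean**2) / (cnt - 1), 0.0)))
        stats_by_class[label] = {"n": cnt, "mean": mean, "sd": sd}
    if valid.sum() < 2:
        return None, None, stats_by_class
    res = scan_week(_single_marker_matrix(calls), pheno_week, week=0, spec=spec)
    row = res.table.iloc[0]
    if not row["tested"]:
        return None, None, stats_by_class
    return float(row["p_value"]), float(row["r_squared"]), stats_by_class


def _single_marker_matrix(calls: np.ndarray) -> GenotypeMatrix:
    from .types import MarkerMap
    mm = MarkerMap.from_records([("m", "chr0", 1)])
    return GenotypeMatrix(mm, [f"a{i}" for i in range(calls.shape[1])], calls)


def scan_timeseries(geno: GenotypeMatrix, pheno: PhenotypeSeries,
                    spec: AssociationModelSpec = AssociationModelSpec(),
                    weeks: Optional[Sequence[int]] = None
                    ) -> list[WeeklyScanResult]:
    """Run the single-marker scan for every phenotyped week."""
    overlap = [a for a in geno.animal_ids if a in set(pheno.animal_ids)]
    if not overlap:
        raise ValueError("no overlapping animals between genotypes and phenotypes")
    row_of = {a: i for i, a in enumerate(pheno.animal_ids)}
    y_rows = np.array([row_of.get(a, -1) for a in geno.animal_ids])
    results = []
    for week in (weeks if weeks is not None else pheno.weeks):
        col = pheno.week_values(week)
        y = np.where(y_rows >= 0, col[y_rows], np.nan)
        if np.isnan(y).all():
            warnings.warn(f"week {week}: no phenotypes for genotyped animals, skipped")
            continue
        results.append(scan_week(geno, y, week, spec))
    return results


def top_snp(results: Sequence[WeeklyScanResult], region=None):
    """Global (marker, week) LOD maximum, optionally inside a region.

    ``region`` is a chromosome name or a (chromosome, start_bp, end_bp) tuple.
    Ties break by smaller p (same as higher LOD), then smaller bp, then
    earlier week.
    """
    best = None
    for res in results:
        t = res.table
        sel = t["tested"].to_numpy(copy=True)
        if region is not None:
            if isinstance(region, str):
                sel &= (t["chromosome"] == region).to_numpy()
            else:
                chrom, start, end = region
                sel &= ((t["chromosome"] == chrom) &
                        (t["position_bp"] >= start) &
                        (t["position_bp"] <= end)).to_numpy()
        sub = t[sel]
        for _, row in sub.iterrows():
            key = (-row["lod"], row["p_value"], row["position_bp"], res.week)
            if best is None or key < best[0]:
                best = (key, (row["marker_id"], res.week, float(row["lod"])))
    if best is None:
        raise ValueError("no tested markers in the requested region")
    return best[1]


@dataclass
class EffectSummary:
    """Genotype-class means and the S1-anchored difference statistics.

    Differences are oriented so a positive value means the S1/S1 class is
    heavier; percentages are relative to the reference class mean.
    """

    marker_id: Optional[str] = None
    week: Optional[int] = None
    mean_S1S1: Optional[float] = None
    mean_H: Optional[float] = None
    mean_S2S2: Optional[float] = None
    sd_S1S1: Optional[float] = None
    sd_H: Optional[float] = None
    sd_S2S2: Optional[float] = None
    diff_S1_S2_g: Optional[float] = None
    pct_S1_over_S2: Optional[float] = None
    diff_S1_H_g: Optional[float] = None
    pct_S1_over_H: Optional[float] = None
    r_squared: Optional[float] = None


def effect_summary_from_means(mean_s1s1, mean_h, mean_s2s2, sds=None,
                              marker_id=None, week=None,
                              r_squared=None) -> EffectSummary:
    out = EffectSummary(marker_id=marker_id, week=week, mean_S1S1=mean_s1s1,
                        mean_H=mean_h, mean_S2S2=mean_s2s2,
                        r_squared=r_squared)
    if sds is not None:
        out.sd_S1S1, out.sd_H, out.sd_S2S2 = sds
    if mean_s1s1 is not None and mean_s2s2 is not None:
        out.diff_S1_S2_g = mean_s1s1 - mean_s2s2
        out.pct_S1_over_S2 = 100.0 * out.diff_S1_S2_g / mean_s2s2
    if mean_s1s1 is not None and mean_h is not None:
        out.diff_S1_H_g = mean_s1s1 - mean_h
        out.pct_S1_over_H = 100.0 * out.diff_S1_H_g / mean_h
    return out


def effect_summary(geno_row: np.ndarray, pheno_week: np.ndarray,
                   marker_id=None, week=None,
                   spec: AssociationModelSpec = AssociationModelSpec()
                   ) -> EffectSummary:
    """Class means +- SD and the four S1-anchored difference statistics for
    one marker/week; fields for absent genotype classes stay None."""
    p, r2, by_class = association_test(geno_row, pheno_week, spec)
    means = {lab: by_class[lab]["mean"] for lab in ("S1S1", "H", "S2S2")}
    sds = tuple(by_class[lab]["sd"] for lab in ("S1S1", "H", "S2S2"))
    return effect_summary_from_means(means["S1S1"], means["H"], means["S2S2"],
                                     sds=sds, marker_id=marker_id, week=week,
                                     r_squared=r2)
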