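"""Seeded simulation studies of the full pipeline's operating characteristics.

These studies run the whole chain - simulate, select extremes, two-stage
merge, weekly scans, simpleM thresholds, LOD-drop intervals - on reduced
marker panels (the statistics under test do not need the full array density)
and summarise detection power, interval coverage of the true QTL, the
disappear/reappear significance pattern under diet attenuation, and null
calibration (p-value uniformity and family-wise error at the simpleM
Bonferroni threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .intervals import aggregate_intervals, lod_drop_interval, significance_span
from .multiplicity import bonferroni_lod_thresholds, m_eff_simpleM
from .preprocess import merge_two_stage, remove_outliers
from .scan import AssociationModelSpec, scan_timeseries, scan_week
from .simulate import (GrowthCurve, QtlSpec, SimConfig, choose_targeted_markers,
                       select_extremes, simulate_dataset)


def study_config(seed: int, attenuate_diet_switch: bool = False,
                 n_chromosomes: int = 5, markers_per_chromosome: int = 100,
                 chrom_length_bp: int = 100_000_000) -> SimConfig:
    """Reduced-density study conditions: 397 males, F10, 500 markers over five
    100-Mb chromosomes, one adult-acting QTL with a homozygote contrast of
    5.4 g (~13% of the ~42 g adult mean, mirroring the reported top-QTL
    effect), residual+polygenic SD ~4 g in adults, selective genotyping of
    200 extremes. ``attenuate_diet_switch`` multiplies the QTL effect by 0.2
    in weeks 21-23 to emulate the diet-switch attenuation."""
    week_mult = {21: 0.2, 22: 0.2, 23: 0.2} if attenuate_diet_switch else {}
    qtl = QtlSpec(chromosome="chr3", position_bp=chrom_length_bp // 2,
                  additive_effect_g=2.7, dominance_effect_g=0.0,
                  week_multiplier=week_mult, scale_with_growth=True)
    chroms = [(f"chr{i + 1}", chrom_length_bp, markers_per_chromosome)
              for i in range(n_chromosomes)]
    return SimConfig(seed=seed, n_animals=397, n_generations=10, pop_size=100,
                     chromosomes=chroms, cm_per_mb=0.5, qtls=[qtl],
                     residual_sd_adult_g=3.5, polygenic_sd_adult_g=2.0,
                     selective_n=200)


@dataclass
class ReplicateOutcome:
    seed: int
    detected: bool
    max_lod: float
    interval: Optional[tuple[int, int]]
    covered: bool
    n_significance_runs: int
    m_eff: int
    n_used_targeted: int
    n_used_array_only: int


def run_replicate(config: SimConfig, lod_threshold: float = 4.2,
                  ld_window_bp: int = 15_000_000,
                  spec: AssociationModelSpec = AssociationModelSpec()
                  ) -> ReplicateOutcome:
    """One full two-stage pipeline pass on a simulated dataset.

    Detection: any marker within ``ld_window_bp`` of the true QTL exceeds the
    LOD threshold in any week (the merged scan). Coverage: the aggregated
    LOD-drop interval - computed, as in the study design, on the
    array-genotyped stage only - contains the true position.
    """
    geno, pheno, truth = simulate_dataset(config)
    pheno, _ = remove_outliers(pheno)
    extremes = select_extremes(pheno, n=config.selective_n)
    array_geno = geno.subset_animals(extremes)
    targeted_ids = choose_targeted_markers(array_geno, pheno, n_markers=2,
                                           spec=spec)
    rest = [a for a in geno.animal_ids if a not in set(extremes)]
    targeted_geno = geno.subset_markers(targeted_ids).subset_animals(rest)
    merged = merge_two_stage(array_geno, targeted_geno)

    full_scan = scan_timeseries(merged, pheno, spec)
    array_scan = scan_timeseries(array_geno, pheno, spec)
    meff = m_eff_simpleM(array_geno)

    qtl_chrom, qtl_pos = truth.qtl_positions[0]
    region = (qtl_chrom, qtl_pos - ld_window_bp, qtl_pos + ld_window_bp)
    max_lod = 0.0
    for res in full_scan:
        t = res.table
        sel = (t["tested"] & (t["chromosome"] == qtl_chrom) &
               (t["position_bp"] >= region[1]) & (t["position_bp"] <= region[2]))
        if sel.any():
            max_lod = max(max_lod, float(t.loc[sel, "lod"].max()))
    detected = max_lod > lod_threshold

    interval = covered = None
    weekly = [lod_drop_interval(res, qtl_chrom, drop=1.5,
                                threshold=lod_threshold)
              for res in array_scan]
    if any(w.significant for w in weekly):
        agg = aggregate_intervals(weekly, only_significant=True)
        interval = (agg.final_start_bp, agg.final_end_bp)
        covered = agg.final_start_bp <= qtl_pos <= agg.final_end_bp
    weekly_full = [lod_drop_interval(res, qtl_chrom, drop=1.5,
                                     threshold=lod_threshold)
                   for res in full_scan]
    runs = significance_span(weekly_full, lod_threshold)

    week0 = full_scan[-1].table
    targ = week0["marker_id"].isin(set(targeted_ids))
    return ReplicateOutcome(
        seed=config.seed, detected=detected, max_lod=max_lod,
        interval=interval, covered=bool(covered) if covered is not None else False,
        n_significance_runs=len(runs), m_eff=meff.m_eff,
        n_used_targeted=int(week0.loc[targ, "n_used"].max()),
        n_used_array_only=int(week0.loc[~targ, "n_used"].max()))


@dataclass
class PowerStudyResult:
    outcomes: list
    detection_rate: float
    coverage_rate_given_detection: float
    two_run_fraction: float  # fraction of replicates with exactly two runs


def power_study(n_replicates: int = 20, seed: int = 0,
                attenuate_diet_switch: bool = False,
                lod_threshold: float = 4.2) -> PowerStudyResult:
    """Detection power, interval coverage and significance-run pattern over
    seeded replicates of the reduced-density study conditions."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    outcomes = []
    for s in child_seeds:
        cfg = study_config(int(s) % (2**31 - 1),
                           attenuate_diet_switch=attenuate_diet_switch)
        outcomes.append(run_replicate(cfg, lod_threshold=lod_threshold))
    detected = [o for o in outcomes if o.detected]
    covered = [o for o in detected if o.covered]
    two_runs = [o for o in outcomes if o.n_significance_runs == 2]
    return PowerStudyResult(
        outcomes=outcomes,
        detection_rate=len(detected) / len(outcomes),
        coverage_rate_given_detection=(len(covered) / len(detected)
                                       if detected else float("nan")),
        two_run_fraction=len(two_runs) / len(outcomes))


def null_config(seed: int, n_animals: int = 400) -> SimConfig:
    """No-QTL calibration conditions: 200 markers spread over 20 mouse-like
    chromosomes (10 markers at 10 Mb spacing) so that between-marker LD is
    moderate, 400 animals, adult-scale noise."""
    chroms = [(f"chr{i + 1}", 100_000_000, 10) for i in range(20)]
    return SimConfig(seed=seed, n_animals=n_animals, n_generations=10,
                     pop_size=100, chromosomes=chroms, qtls=[],
                     residual_sd_adult_g=3.5, polygenic_sd_adult_g=2.0,
                     selective_n=n_animals)


@dataclass
class NullCalibrationResult:
    ks_distance: float
    n_pvalues: int
    fwer: float
    n_scans: int
    m_eff: int
    lod_threshold: float


def null_calibration(seed: int = 0, n_pvalue_draws: int = 25,
                     n_fwer_scans: int = 200, alpha: float = 0.05
                     ) -> NullCalibrationResult:
    """Uniformity of null p-values and family-wise error at the simpleM
    Bonferroni threshold.

    One genotype matrix is simulated; phenotypes are redrawn per replicate
    (pure noise around the growth mean at an adult week). The KS distance
    pools ``n_pvalue_draws`` independent scans; the FWER is the fraction of
    ``n_fwer_scans`` scans whose maximum LOD crosses the threshold.
    """
    rng = np.random.default_rng(seed)
    cfg = null_config(seed)
    geno, _, _ = simulate_dataset(cfg)
    meff = m_eff_simpleM(geno)
    threshold = bonferroni_lod_thresholds(meff.m_eff, (alpha,)).lod_thresholds[0]

    def null_scan():
        y = 42.0 + rng.normal(0.0, 4.0, size=geno.n_animals)
        res = scan_week(geno, y, week=20)
        return res.table.loc[res.table["tested"], ["p_value", "lod"]]

    pvals = np.concatenate([null_scan()["p_value"].to_numpy()
                            for _ in range(n_pvalue_draws)])
    ks = stats.kstest(pvals, "uniform").statistic
    hits = sum(float(null_scan()["lod"].max()) >= threshold
               for _ in range(n_fwer_scans))
    return NullCalibrationResult(ks_distance=float(ks), n_pvalues=len(pvals),
                                 fwer=hits / n_fwer_scans,
                                 n_scans=n_fwer_scans, m_eff=meff.m_eff,
                                 lod_threshold=float(threshold))
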