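"""End-to-end pipeline: simulate/load -> preprocess -> two-step scan ->
thresholds -> intervals -> (optional) prioritization and motif scan, writing
one immutable run directory with every artifact and a markdown report.

The run is deterministic given the config (and its seed); the config hash is
recorded so identical hashes imply identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import io as ailio
from .intervals import aggregate_intervals, lod_drop_interval, significance_span
from .multiplicity import bonferroni_lod_thresholds, m_eff_simpleM
from .preprocess import merge_two_stage, filter_informative, remove_outliers
from .prioritize import ScoringConfig, prioritize_interval
from .motif import CHORE_A, CHORE_B, hits_to_bed, scan_gene_set
from .scan import AssociationModelSpec, scan_timeseries
from .simulate import (QtlSpec, SimConfig, choose_targeted_markers,
                       select_extremes, simulate_dataset)

log = logging.getLogger("ailqtl")


def _load_config(config: Union[dict, str, Path]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sim_config_from_dict(d: dict, seed: int) -> SimConfig:
    qtls = [QtlSpec(chromosome=q["chromosome"], position_bp=q["position_bp"],
                    additive_effect_g=q.get("additive_effect_g", 0.0),
                    dominance_effect_g=q.get("dominance_effect_g", 0.0),
                    week_multiplier={int(k): float(v) for k, v in
                                     q.get("week_multiplier", {}).items()})
            for q in d.get("qtls", [])]
    kwargs = {k: d[k] for k in ("n_animals", "n_generations", "pop_size",
                                "cm_per_mb", "residual_sd_adult_g",
                                "polygenic_sd_adult_g", "selective_n")
              if k in d}
    if "chromosomes" in d:
        kwargs["chromosomes"] = [tuple(c) for c in d["chromosomes"]]
    return SimConfig(seed=seed, qtls=qtls, **kwargs)


def run_full(config: Union[dict, str, Path], out_dir: Union[str, Path]) -> Path:
    """Run the whole pipeline per the config; returns the run directory."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_full_inner(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_full_inner(cfg: dict, out: Path) -> Path:
    seed = int(cfg.get("seed", 0))
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    log.info("config hash %s", _config_hash(cfg))

    spec = AssociationModelSpec(
        model=cfg.get("scan", {}).get("model", "genotype_factor_anova"),
        min_class_n=int(cfg.get("scan", {}).get("min_class_n", 5)))
    alphas = tuple(cfg.get("alpha", [0.05, 0.01]))

    # ---- inputs: simulation block or file paths -------------------------
    if "simulate" in cfg:
        sim_cfg = _sim_config_from_dict(cfg["simulate"], seed)
        geno, pheno, truth = simulate_dataset(sim_cfg)
        extremes = select_extremes(pheno, n=sim_cfg.selective_n)
        array_geno = geno.subset_animals(extremes)
        rest = [a for a in geno.animal_ids if a not in set(extremes)]
        (out / "truth.json").write_text(json.dumps({
            "qtls": [{"chromosome": c, "position_bp": p}
                     for c, p in truth.qtl_positions]}, indent=1))
    elif "inputs" in cfg:
        paths = cfg["inputs"]
        for key in ("genotypes", "phenotypes"):
            if key not in paths or not Path(paths[key]).exists():
                raise FileNotFoundError(f"missing input {key!r}")
        array_geno = ailio.read_genotypes(paths["genotypes"])
        pheno = ailio.read_phenotypes(paths["phenotypes"])
        rest = None
        geno = None
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' section")

    # ---- preprocess -----------------------------------------------------
    pheno, removals = remove_outliers(pheno, k_sd=float(cfg.get("outlier_k_sd", 3)))
    pd.DataFrame([(r.animal_id, r.week, r.value_g) for r in removals],
                 columns=["animal", "week", "weight_g"]).to_csv(
        out / "outliers_removed.tsv", sep="\t", index=False)
    array_geno = filter_informative(
        array_geno, max_missing_rate=float(cfg.get("max_missing_rate", 0.10)))
    log.info("preprocess: %d markers, %d array animals, %d outlier cells removed",
             array_geno.n_markers, array_geno.n_animals, len(removals))

    # ---- two-step scan --------------------------------------------------
    initial_scan = scan_timeseries(array_geno, pheno, spec)
    targeted_ids = []
    if "simulate" in cfg:
        targeted_ids = choose_targeted_markers(
            array_geno, pheno,
            n_markers=int(cfg.get("selective", {}).get("n_targeted_markers", 2)),
            spec=spec)
        targeted_geno = geno.subset_markers(targeted_ids).subset_animals(rest)
        merged = merge_two_stage(array_geno, targeted_geno)
    elif "targeted_genotypes" in cfg.get("inputs", {}):
        targeted_geno = ailio.read_genotypes(cfg["inputs"]["targeted_genotypes"])
        targeted_ids = targeted_geno.map.marker_ids
        merged = merge_two_stage(array_geno, targeted_geno)
    else:
        merged = array_geno
    final_scan = scan_timeseries(merged, pheno, spec)
    scan_table = pd.concat([r.table.assign(week=r.week) for r in final_scan])
    scan_table.to_csv(out / "scan_full.tsv", sep="\t", index=False,
                      float_format="%.6g")
    pd.concat([r.table.assign(week=r.week) for r in initial_scan]).to_csv(
        out / "scan_array.tsv", sep="\t", index=False, float_format="%.6g")

    # ---- thresholds -----------------------------------------------------
    meff_cfg = cfg.get("meff", {})
    meff = m_eff_simpleM(array_geno,
                         window_size=int(meff_cfg.get("window_size", 820)),
                         C=float(meff_cfg.get("C", 0.995)))
    thresholds = bonferroni_lod_thresholds(meff.m_eff, alphas)
    (out / "meff.json").write_text(json.dumps({
        "m_eff": meff.m_eff, "window_size": meff.window_size,
        "C": meff.variance_fraction_C,
        "per_window_counts": list(meff.per_window_counts)}, indent=1))
    (out / "thresholds.json").write_text(json.dumps({
        "alpha": list(thresholds.alpha_levels),
        "lod": [round(t, 4) for t in thresholds.lod_thresholds]}, indent=1))
    sig_lod = thresholds.lod_thresholds[0]
    log.info("m_eff=%d; LOD thresholds %s", meff.m_eff,
             dict(zip(thresholds.alpha_levels, thresholds.lod_thresholds)))

    # ---- intervals (LOD drop on the array stage, per the design) --------
    drop = float(cfg.get("intervals", {}).get("drop", 1.5))
    interval_rows, bed_rows, spans = [], [], {}
    qtls = {}
    for chrom in array_geno.map.chromosomes:
        weekly = [lod_drop_interval(res, chrom, drop=drop, threshold=sig_lod)
                  for res in initial_scan]
        weekly_full = [lod_drop_interval(res, chrom, drop=drop,
                                         threshold=sig_lod)
                       for res in final_scan]
        for w in weekly:
            interval_rows.append((chrom, w.week, w.start_bp, w.end_bp,
                                  w.top_marker, round(w.top_lod, 4),
                                  w.significant))
        if any(w.significant for w in weekly):
            agg = aggregate_intervals(weekly, only_significant=True)
            qtls[chrom] = agg
            bed_rows.append((chrom, agg.final_start_bp - 1, agg.final_end_bp,
                             f"QTL_{chrom}", 0, "."))
            spans[chrom] = significance_span(weekly_full, sig_lod)
    pd.DataFrame(interval_rows,
                 columns=["chromosome", "week", "start_bp", "end_bp",
                          "top_marker", "top_lod", "significant"]).to_csv(
        out / "intervals.tsv", sep="\t", index=False)
    pd.DataFrame(bed_rows).to_csv(out / "qtl_regions.bed", sep="\t",
                                  index=False, header=False)
    (out / "significance_spans.json").write_text(json.dumps(
        {c: [list(r) for r in runs] for c, runs in spans.items()}, indent=1))
    log.info("QTLs: %s", {c: (q.final_start_bp, q.final_end_bp)
                          for c, q in qtls.items()})

    # ---- optional: candidate prioritization -----------------------------
    pri = cfg.get("prioritize")
    if pri and qtls:
        genes = ailio.read_gene_models(pri["genes"])
        consequences = ailio.read_consequences(pri["consequences"])
        expression = (ailio.read_expression(pri["expression"])
                      if "expression" in pri else [])
        rows = []
        for chrom, agg in qtls.items():
            cards = prioritize_interval(genes, agg, consequences, expression,
                                        kegg_members=pri.get("kegg", ()))
            for card in cards:
                rows.append({"chromosome": chrom, "gene_id": card.gene_id,
                             "score": card.score, "rank": card.rank,
                             **{k: v for k, v in card.flags.items()},
                             "de_adipose": card.de_adipose,
                             "de_liver": card.de_liver})
        pd.DataFrame(rows).to_csv(out / "candidates.tsv", sep="\t", index=False)

    # ---- optional: ChoRE motif scan -------------------------------------
    mot = cfg.get("motif")
    if mot and qtls:
        genes = ailio.read_gene_models(mot["genes"])
        in_qtl = [g for g in genes if g.chromosome in qtls and
                  g.end_bp >= qtls[g.chromosome].final_start_bp and
                  g.start_bp <= qtls[g.chromosome].final_end_bp]
        hits = scan_gene_set(in_qtl, mot["fasta"],
                             upstream=int(mot.get("upstream", 2000)),
                             min_score=float(mot.get("min_score", 0.90)))
        hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        hits_to_bed(hits).to_csv(out / "motif_hits.bed", sep="\t",
                                 index=False, header=False)

    _plot_lod_curves(scan_table, sig_lod, out / "lod_curves.png")
    report(out)
    return out


def _plot_lod_curves(scan_table: pd.DataFrame, threshold: float,
                     path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    chroms = list(dict.fromkeys(scan_table["chromosome"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2.2 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = scan_table[(scan_table["chromosome"] == chrom) &
                         scan_table["tested"]]
        for week, grp in sub.groupby("week"):
            ax.plot(grp["position_bp"] / 1e6, grp["lod"], lw=0.6, alpha=0.6)
        ax.axhline(threshold, color="red", ls="--", lw=0.8)
        ax.set_ylabel("LOD")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def report(run_dir: Union[str, Path]) -> Path:
    """Summarise a completed run as markdown; errors name missing artifacts."""
    run_dir = Path(run_dir)
    for artifact in ("scan_full.tsv", "thresholds.json", "intervals.tsv"):
        if not (run_dir / artifact).exists():
            raise FileNotFoundError(f"incomplete run: missing {artifact}")
    scan = pd.read_csv(run_dir / "scan_full.tsv", sep="\t")
    thresholds = json.loads((run_dir / "thresholds.json").read_text())
    intervals = pd.read_csv(run_dir / "intervals.tsv", sep="\t")
    spans = json.loads((run_dir / "significance_spans.json").read_text()) \
        if (run_dir / "significance_spans.json").exists() else {}

    lines = ["# QTL pipeline report", "",
             f"LOD thresholds: {dict(zip(thresholds['alpha'], thresholds['lod']))}",
             ""]
    sig = intervals[intervals["significant"]]
    for chrom in sig["chromosome"].unique():
        sub = sig[sig["chromosome"] == chrom]
        start, end = sub["start_bp"].min(), sub["end_bp"].max()
        lines += [f"## QTL on {chrom}: {start:,}-{end:,} bp",
                  f"significant weeks: {sorted(sub['week'])}",
                  f"significance runs: {spans.get(chrom, [])}", "",
                  "| week | top marker | LOD | n | mean S1/S1 | mean H | mean S2/S2 |",
                  "|---|---|---|---|---|---|---|"]
        for _, row in sub.iterrows():
            best = scan[(scan["week"] == row["week"]) &
                        (scan["marker_id"] == row["top_marker"])]
            if best.empty:
                continue
            b = best.iloc[0]
            lines.append(
                f"| {row['week']} | {row['top_marker']} | {b['lod']:.2f} | "
                f"{b['n_used']} | {b['mean_S1S1']:.2f} | {b['mean_H']:.2f} | "
                f"{b['mean_S2S2']:.2f} |")
        lines.append("")
    if (run_dir / "candidates.tsv").exists():
        cands = pd.read_csv(run_dir / "candidates.tsv", sep="\t")
        lines += ["## Candidate genes", "",
                  cands.head(20).to_markdown(index=False), ""]
    else:
        lines += ["## Candidate genes", "",
                  "No prioritization inputs configured for this run.", ""]
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
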