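"""Synthetic advanced-intercross-line data with known truth.

The generator emulates the study design end to end: two fully inbred founder
lines that are opposite-homozygous at every informative marker, an initial
S1 male x S2 female cross, successive generations of random mating (full-sib
pairs avoided when possible), Haldane recombination at a configurable
cM-per-Mb rate, weekly body weights following a logistic growth mean with one
or more additive QTLs whose effect can attenuate in chosen weeks (the
diet-switch window), a per-animal polygenic deviation plus independent weekly
noise, and selective genotyping of the phenotypic extremes followed by
targeted-assay genotypes at top markers for the remaining animals.

QTLs are simulated as hidden loci inserted into the haplotypes and removed
from the emitted marker panel, so a scan must localise them through linkage,
exactly as with real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as ailio
from .scan import AssociationModelSpec, scan_timeseries
from .types import DietSchedule, GenotypeMatrix, MarkerMap, PhenotypeSeries

# approximate mm10 autosome lengths (bp), used for the full-scale default map
_MOUSE_AUTOSOME_MB = (195, 182, 160, 157, 152, 150, 145, 129, 125, 131,
                      122, 120, 121, 125, 104, 98, 95, 91, 61)


@dataclass(frozen=True)
class GrowthCurve:
    """Logistic growth mean: asymptote / (1 + exp(-rate * (week - inflection)))."""
    asymptote_g: float = 45.0
    rate_per_week: float = 0.25
    inflection_week: float = 9.0

    def mean(self, weeks) -> np.ndarray:
        w = np.asarray(weeks, dtype=float)
        return self.asymptote_g / (1.0 + np.exp(-self.rate_per_week *
                                                (w - self.inflection_week)))

    def fraction(self, weeks) -> np.ndarray:
        return self.mean(weeks) / self.asymptote_g


@dataclass(frozen=True)
class QtlSpec:
    """One additive QTL.

    ``additive_effect_g`` is the adult per-allele effect (homozygote contrast
    is twice this). With ``scale_with_growth`` the weekly effect follows the
    growth fraction, so juveniles show proportionally smaller effects.
    ``week_multiplier`` rescales the effect in specific weeks (e.g. 0.2 in a
    diet-switch window to emulate transient attenuation).
    """
    chromosome: str
    position_bp: int
    additive_effect_g: float
    dominance_effect_g: float = 0.0
    week_multiplier: Mapping[int, float] = field(default_factory=dict)
    scale_with_growth: bool = True

    def effect_at(self, week: int, growth: GrowthCurve) -> tuple[float, float]:
        scale = float(growth.fraction(week)) if self.scale_with_growth else 1.0
        mult = float(self.week_multiplier.get(week, 1.0))
        return (self.additive_effect_g * scale * mult,
                self.dominance_effect_g * scale * mult)


def attenuation_for_phases(schedule: DietSchedule,
                           multipliers: Mapping[str, float]) -> dict[int, float]:
    """Expand a diet-phase -> multiplier map into a week -> multiplier map."""
    out = {}
    for start, end, label in schedule.phases:
        if label in multipliers:
            for week in range(start, end + 1):
                out[week] = float(multipliers[label])
    return out


def default_chromosomes(n_markers_total: int = 5171) -> list[tuple[str, int, int]]:
    """Mouse-like 19-autosome map with markers allotted by physical length."""
    total_mb = sum(_MOUSE_AUTOSOME_MB)
    chroms = []
    assigned = 0
    for i, mb in enumerate(_MOUSE_AUTOSOME_MB, start=1):
        n = round(n_markers_total * mb / total_mb)
        if i == len(_MOUSE_AUTOSOME_MB):
            n = n_markers_total - assigned
        assigned += n
        chroms.append((f"chr{i}", mb * 1_000_000, n))
    return chroms


@dataclass
class SimConfig:
    seed: int = 0
    n_animals: int = 397
    n_generations: int = 10
    pop_size: int = 100  # breeding-population size in intermediate generations
    chromosomes: Sequence[tuple[str, int, int]] = field(
        default_factory=default_chromosomes)
    cm_per_mb: float = 0.5
    qtls: Sequence[QtlSpec] = ()
    growth: GrowthCurve = field(default_factory=GrowthCurve)
    weeks: Sequence[int] = tuple(range(3, 26))
    residual_sd_adult_g: float = 3.5
    polygenic_sd_adult_g: float = 2.0
    sd_scales_with_growth: bool = True
    diet_schedule: DietSchedule = field(default_factory=DietSchedule.study_default)
    selective_n: int = 200
    targeted_markers: Sequence[str] = ()

    def __post_init__(self):
        if self.selective_n > self.n_animals:
            raise ValueError("selective_n cannot exceed n_animals")
        if self.pop_size < 4:
            raise ValueError("need at least 2 breeding pairs")


@dataclass
class TruthRecord:
    seed: int
    qtl_positions: list        # (chromosome, position_bp) per QTL
    qtl_effects: list          # (additive_adult_g, dominance_adult_g)
    qtl_genotypes: np.ndarray  # (n_qtl, n_animals) S1-allele dosage 0/1/2
    final_parent_pairs: np.ndarray  # (n_animals, 2) indices into parent matrix
    final_parent_calls: np.ndarray  # (n_parents, n_loci) dosage incl. QTL loci
    marker_is_qtl: np.ndarray  # mask over simulated loci (QTLs are hidden)
    genetic_values: Optional[np.ndarray] = None  # (n_animals, n_weeks)


def _build_locus_map(config: SimConfig):
    """Marker panel plus hidden QTL loci, as one sorted locus table."""
    rows = []
    for chrom, length, n in config.chromosomes:
        if n <= 0:
            continue
        pos = np.round((np.arange(n) + 0.5) * length / n).astype(np.int64)
        pos = np.maximum(pos, 1)
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_m{i + 1:04d}", chrom, int(p), False))
    marker_pos = {(c, p) for _, c, p, _ in rows}
    for qi, q in enumerate(config.qtls):
        pos = q.position_bp
        while (q.chromosome, pos) in marker_pos:  # avoid exact collision
            pos += 1
        rows.append((f"QTL{qi + 1}", q.chromosome, pos, True))
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome",
                                     "position_bp", "is_qtl"])
    from .types import chromosome_sort_key
    df = df.sort_values(by=["chromosome", "position_bp"],
                        key=lambda s: (s.map(chromosome_sort_key)
                                       if s.name == "chromosome" else s))
    return df.reset_index(drop=True)


def _recomb_fractions(locus_df: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    """Haldane recombination fraction between consecutive loci; 0.5 across
    chromosome boundaries (independent assortment)."""
    chrom = locus_df["chromosome"].to_numpy()
    pos = locus_df["position_bp"].to_numpy(dtype=float)
    d_cm = np.diff(pos) / 1e6 * cm_per_mb
    r = 0.5 * (1.0 - np.exp(-0.02 * d_cm))
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def _gametes(rng: np.random.Generator, haps: np.ndarray,
             parent_idx: np.ndarray, r: np.ndarray) -> np.ndarray:
    """One recombinant gamete per requested parent (vectorised)."""
    n = len(parent_idx)
    L = haps.shape[2]
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    if L > 1:
        switches = (rng.random((n, L - 1)) < r[None, :]).astype(np.int8)
        parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
        origin = np.concatenate([start, start ^ parity.astype(np.int8)], axis=1)
    else:
        origin = start
    pa = haps[parent_idx, 0, :]
    pb = haps[parent_idx, 1, :]
    return np.where(origin == 0, pa, pb).astype(np.uint8)


def _pair_up(rng: np.random.Generator, n: int,
             parents_of: Optional[np.ndarray]) -> np.ndarray:
    """Random mating pairs, re-drawing to avoid full-sib pairs when possible."""
    for _ in range(100):
        perm = rng.permutation(n)
        pairs = perm[: (n // 2) * 2].reshape(-1, 2)
        if parents_of is None:
            return pairs
        sibs = np.all(parents_of[pairs[:, 0]] == parents_of[pairs[:, 1]], axis=1)
        if not sibs.any():
            return pairs
    return pairs  # fully related population (e.g. F1): accept


def simulate_ail_genotypes(config: SimConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> tuple[GenotypeMatrix, TruthRecord]:
    """Drop an AIL population through ``n_generations`` and return the final
    generation's marker genotypes with the hidden-QTL truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    locus_df = _build_locus_map(config)
    r = _recomb_fractions(locus_df, config.cm_per_mb)
    L = len(locus_df)
    is_qtl = locus_df["is_qtl"].to_numpy()

    # generation 1 (F1): every animal carries one S1 and one S2 haplotype
    haps = np.empty((config.pop_size, 2, L), dtype=np.uint8)
    haps[:, 0, :] = 1  # S1 gamete
    haps[:, 1, :] = 0  # S2 gamete
    parents_of = None
    pairs = None
    if config.n_generations < 2:
        raise ValueError("need at least 2 generations (F1 is generation 1)")
    for gen in range(2, config.n_generations + 1):
        last = gen == config.n_generations
        n_off = config.n_animals if last else config.pop_size
        pairs = _pair_up(rng, haps.shape[0], parents_of)
        pair_idx = np.arange(n_off) % len(pairs)
        mothers = pairs[pair_idx, 0]
        fathers = pairs[pair_idx, 1]
        parent_haps = haps
        new = np.empty((n_off, 2, L), dtype=np.uint8)
        new[:, 0, :] = _gametes(rng, parent_haps, mothers, r)
        new[:, 1, :] = _gametes(rng, parent_haps, fathers, r)
        parents_of = np.column_stack([mothers, fathers])
        haps = new

    dosage = haps.sum(axis=1).astype(np.int8)  # (n_animals, L) S1-allele count
    marker_rows = ~is_qtl
    markers = MarkerMap(locus_df.loc[marker_rows,
                                     ["marker_id", "chromosome", "position_bp"]]
                        .reset_index(drop=True))
    animal_ids = [f"AIL{i + 1:04d}" for i in range(config.n_animals)]
    geno = GenotypeMatrix(markers, animal_ids, dosage[:, marker_rows].T)
    truth = TruthRecord(
        seed=config.seed,
        qtl_positions=[(q.chromosome, q.position_bp) for q in config.qtls],
        qtl_effects=[(q.additive_effect_g, q.dominance_effect_g)
                     for q in config.qtls],
        qtl_genotypes=dosage[:, is_qtl].T.copy(),
        final_parent_pairs=parents_of,
        final_parent_calls=parent_haps.sum(axis=1).astype(np.int8),
        marker_is_qtl=is_qtl)
    return geno, truth


def simulate_weight_series(truth: TruthRecord, config: SimConfig,
                           rng: Optional[np.random.Generator] = None,
                           animal_ids: Optional[Sequence[str]] = None
                           ) -> PhenotypeSeries:
    """Weekly weights: growth mean + QTL effects + polygenic value + noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = truth.qtl_genotypes.shape[1] if len(config.qtls) else config.n_animals
    weeks = np.asarray(list(config.weeks))
    mu = config.growth.mean(weeks)
    frac = config.growth.fraction(weeks) if config.sd_scales_with_growth \
        else np.ones_like(mu)
    genetic = np.zeros((n, len(weeks)))
    for qi, q in enumerate(config.qtls):
        g = truth.qtl_genotypes[qi].astype(float)
        het = (g == 1).astype(float)
        for wj, week in enumerate(weeks):
            a, d = q.effect_at(int(week), config.growth)
            genetic[:, wj] += a * (g - 1.0) + d * het
    poly = rng.normal(0.0, config.polygenic_sd_adult_g, size=n)
    noise = rng.normal(0.0, 1.0, size=(n, len(weeks)))
    weights = (mu[None, :] + genetic + poly[:, None] * frac[None, :] +
               noise * (config.residual_sd_adult_g * frac)[None, :])
    weights = np.clip(weights, 0.5, None)  # weights are physically positive
    truth.genetic_values = genetic
    if animal_ids is None:
        animal_ids = [f"AIL{i + 1:04d}" for i in range(n)]
    return PhenotypeSeries(list(animal_ids), [int(w) for w in weeks], weights)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genotypes, phenotypes and truth from one seed."""
    rng = np.random.default_rng(config.seed)
    geno, truth = simulate_ail_genotypes(config, rng)
    pheno = simulate_weight_series(truth, config, rng, geno.animal_ids)
    return geno, pheno, truth


def select_extremes(pheno: PhenotypeSeries, proxy=None, n: int = 200) -> list[str]:
    """The n/2 lowest plus n/2 highest animals by a proxy value.

    ``proxy`` is a week number, an array of per-animal values, or None for
    the last phenotyped week. Ties at the cutoff break by animal id;
    animals missing the proxy value are not selectable. Returns ids in the
    phenotype table's animal order.
    """
    if n > pheno.n_animals:
        raise ValueError("cannot select more animals than exist")
    if proxy is None:
        values = pheno.weights[:, -1]
    elif np.isscalar(proxy):
        values = pheno.week_values(int(proxy))
    else:
        values = np.asarray(proxy, dtype=float)
    order = sorted((i for i in range(pheno.n_animals) if not np.isnan(values[i])),
                   key=lambda i: (values[i], pheno.animal_ids[i]))
    if n > len(order):
        raise ValueError("not enough non-missing proxy values")
    chosen = set(order[:n // 2]) | set(order[len(order) - (n - n // 2):])
    return [a for i, a in enumerate(pheno.animal_ids) if i in chosen]


def choose_targeted_markers(geno: GenotypeMatrix, pheno: PhenotypeSeries,
                            n_markers: int = 2,
                            spec: AssociationModelSpec = AssociationModelSpec(),
                            distinct_chromosomes: bool = True) -> list[str]:
    """Top markers from an initial scan, for targeted-assay follow-up.

    Ranks markers by their maximum LOD over weeks; with
    ``distinct_chromosomes`` at most one marker is taken per chromosome.
    """
    results = scan_timeseries(geno, pheno, spec)
    best: dict[str, tuple[float, int, str]] = {}
    for res in results:
        t = res.table[res.table["tested"]]
        for _, row in t.iterrows():
            cur = best.get(row["marker_id"])
            if cur is None or row["lod"] > cur[0]:
                best[row["marker_id"]] = (float(row["lod"]),
                                          int(row["position_bp"]),
                                          str(row["chromosome"]))
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][2], kv[1][1]))
    out, seen_chrom = [], set()
    for marker, (_, _, chrom) in ranked:
        if distinct_chromosomes and chrom in seen_chrom:
            continue
        out.append(marker)
        seen_chrom.add(chrom)
        if len(out) == n_markers:
            break
    return out


def emit_dataset(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write the two-stage dataset: array genotypes for the selected extremes,
    targeted genotypes for the rest, a long phenotype CSV and a truth JSON.
    Byte-identical across runs with the same seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geno, pheno, truth = simulate_dataset(config)
    extremes = select_extremes(pheno, n=config.selective_n)
    rest = [a for a in geno.animal_ids if a not in set(extremes)]
    targeted = list(config.targeted_markers)
    if not targeted:
        targeted = choose_targeted_markers(geno.subset_animals(extremes), pheno,
                                           n_markers=min(2, geno.n_markers))
    paths = {
        "array_genotypes": out_dir / "genotypes_array.tsv",
        "targeted_genotypes": out_dir / "genotypes_targeted.tsv",
        "phenotypes": out_dir / "phenotypes.csv",
        "truth": out_dir / "truth.json",
    }
    ailio.write_genotypes(geno.subset_animals(extremes), paths["array_genotypes"])
    ailio.write_genotypes(geno.subset_markers(targeted).subset_animals(rest),
                          paths["targeted_genotypes"])
    ailio.write_phenotypes(pheno, paths["phenotypes"], layout="long")
    truth_json = {
        "seed": config.seed,
        "qtls": [{"chromosome": c, "position_bp": p,
                  "additive_effect_g": a, "dominance_effect_g": d}
                 for (c, p), (a, d) in zip(truth.qtl_positions,
                                           truth.qtl_effects)],
        "qtl_genotypes": {f"QTL{i + 1}": truth.qtl_genotypes[i].tolist()
                          for i in range(truth.qtl_genotypes.shape[0])},
        "targeted_markers": targeted,
        "array_animals": extremes,
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return paths
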