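"""Phenotype outlier removal, marker QC, and the two-stage genotype merge."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import GenotypeMatrix, MarkerMap, PhenotypeSeries


@dataclass(frozen=True)
class OutlierRemoval:
    animal_id: str
    week: int
    value_g: float


def remove_outliers(pheno: PhenotypeSeries, k_sd: float = 3.0
                    ) -> tuple[PhenotypeSeries, list[OutlierRemoval]]:
    """Blank weekly weights deviating from that week's population mean by
    more than ``k_sd`` standard deviations.

    Mean and SD (sample SD, ddof=1) are computed once per week over the
    non-missing values; removal is a single pass, never iterated. Weeks with
    fewer than two values are skipped with a warning. Returns the cleaned
    series and a log of removed (animal, week, value) cells.
    """
    out = pheno.copy()
    log: list[OutlierRemoval] = []
    for j, week in enumerate(out.weeks):
        col = out.weights[:, j]
        present = ~np.isnan(col)
        if present.sum() < 2:
            warnings.warn(f"week {week}: fewer than 2 values, outlier rule skipped")
            continue
        mean = col[present].mean()
        sd = col[present].std(ddof=1)
        if sd == 0:
            continue  # rule vacuous when all values identical
        flag = present & (np.abs(col - mean) > k_sd * sd)
        for i in np.flatnonzero(flag):
            log.append(OutlierRemoval(out.animal_ids[i], week, float(col[i])))
            out.weights[i, j] = np.nan
    return out, log


def filter_informative(geno: GenotypeMatrix,
                       max_missing_rate: float = 0.10) -> GenotypeMatrix:
    """Drop monomorphic markers and markers exceeding the missing-rate QC cut."""
    calls = geno.calls
    missing = calls == -1
    miss_rate = missing.mean(axis=1)
    keep = np.empty(geno.n_markers, dtype=bool)
    for i in range(geno.n_markers):
        present = calls[i][~missing[i]]
        polymorphic = present.size > 0 and np.unique(present).size > 1
        keep[i] = polymorphic and miss_rate[i] <= max_missing_rate
    return GenotypeMatrix(
        MarkerMap(geno.map.table.loc[keep].reset_index(drop=True)),
        list(geno.animal_ids), calls[keep])


def merge_two_stage(array_geno: GenotypeMatrix,
                    targeted_geno: GenotypeMatrix) -> GenotypeMatrix:
    """Merge the array-genotyped stage with targeted-assay follow-up calls.

    The targeted markers must be a subset of the array map. The result covers
    the union of animals: targeted markers may be non-missing for everyone,
    array-only markers stay missing for targeted-only animals. A conflicting
    non-missing call for the same (marker, animal) is an error; every
    non-missing input call is preserved.
    """
    array_ids = set(array_geno.map.marker_ids)
    for m in targeted_geno.map.marker_ids:
        if m not in array_ids:
            raise ValueError(f"targeted marker {m!r} absent from the array map")
    animals = list(array_geno.animal_ids)
    animals += [a for a in targeted_geno.animal_ids if a not in set(animals)]
    col = {a: j for j, a in enumerate(animals)}
    calls = np.full((array_geno.n_markers, len(animals)), -1, dtype=np.int8)
    calls[:, :array_geno.n_animals] = array_geno.calls
    row = {m: i for i, m in enumerate(array_geno.map.marker_ids)}
    for ti, m in enumerate(targeted_geno.map.marker_ids):
        i = row[m]
        for tj, a in enumerate(targeted_geno.animal_ids):
            c = targeted_geno.calls[ti, tj]
            if c == -1:
                continue
            j = col[a]
            if calls[i, j] != -1 and calls[i, j] != c:
                raise ValueError(f"conflicting calls at marker {m!r}, "
                                 f"animal {a!r}: {calls[i, j]} vs {c}")
            calls[i, j] = c
    return GenotypeMatrix(array_geno.map, animals, calls)
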