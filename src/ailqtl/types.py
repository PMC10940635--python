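"""Core data containers for AIL QTL mapping.

Conventions used throughout the package:

* Genomic coordinates are 1-based and inclusive (BED input is converted on read).
* Genotype calls are coded ``2`` = S1/S1 (the founder whose allele increases
  body weight), ``1`` = heterozygous, ``0`` = S2/S2, ``-1`` = missing. This
  fixes the sign of every downstream effect estimate.
* Phenotypes are body weights in grams; missing cells are NaN.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

GENOTYPE_TOKENS = {"S1": 2, "H": 1, "S2": 0, "2": 2, "1": 1, "0": 0,
                   "NA": -1, "-": -1, "": -1}
TOKEN_OF_CODE = {2: "S1", 1: "H", 0: "S2", -1: "NA"}

CONSEQUENCE_CLASSES = frozenset({
    "deleterious_domain_missense", "tolerated_domain_missense", "utr",
    "promoter", "enhancer", "ctcf_binding", "splice_site", "other",
})

TISSUES = frozenset({"gonadal_adipose", "liver"})

DIET_PHASES = ("standard", "HF_LC", "HF_HC")


def chromosome_sort_key(chrom: str):
    """Natural ordering: numeric chromosome names before non-numeric ones."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map: unique ids, positions strictly increasing per chromosome."""

    table: pd.DataFrame  # columns: marker_id, chromosome, position_bp

    def __post_init__(self):
        t = self.table
        required = {"marker_id", "chromosome", "position_bp"}
        if not required.issubset(t.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        if (t["position_bp"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")

    @staticmethod
    def from_records(records: Iterable[tuple]) -> "MarkerMap":
        df = pd.DataFrame(records, columns=["marker_id", "chromosome", "position_bp"])
        return MarkerMap(sort_markers(df))

    def __len__(self):
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.table["chromosome"])
        return list(seen)


def sort_markers(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chromosome"].map(chromosome_sort_key)
    order = sorted(range(len(df)),
                   key=lambda i: (key.iloc[i], df["position_bp"].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Marker x animal call matrix with its map.

    ``calls`` is int8, shape (n_markers, n_animals); -1 marks missing.
    """

    map: MarkerMap
    animal_ids: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.map), len(self.animal_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.map)} markers, {len(self.animal_ids)} animals)")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("animal ids not unique")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at marker "
                f"{self.map.marker_ids[i]!r}, animal {self.animal_ids[j]!r}")

    @property
    def n_markers(self) -> int:
        return len(self.map)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def marker_index(self, marker_id: str) -> int:
        idx = self.map.table.index[self.map.table["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def row(self, marker_id: str) -> np.ndarray:
        return self.calls[self.marker_index(marker_id)]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        keep = set(marker_ids)
        mask = self.map.table["marker_id"].isin(keep).to_numpy()
        return GenotypeMatrix(
            MarkerMap(self.map.table.loc[mask].reset_index(drop=True)),
            list(self.animal_ids), self.calls[mask])

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: j for j, a in enumerate(self.animal_ids)}
        cols = [pos[a] for a in animal_ids]
        return GenotypeMatrix(self.map, list(animal_ids), self.calls[:, cols])


@dataclass
class PhenotypeSeries:
    """Animal x week body-weight matrix in grams; NaN marks missing."""

    animal_ids: list[str]
    weeks: list[int]
    weights: np.ndarray  # float64 (n_animals, n_weeks)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.animal_ids), len(self.weeks)):
            raise ValueError("weights shape does not match animals x weeks")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("animal ids not unique")
        if (np.diff(self.weeks) <= 0).any():
            raise ValueError("weeks must be strictly increasing")
        present = ~np.isnan(self.weights)
        if (self.weights[present] <= 0).any():
            raise ValueError("non-positive weight present")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def week_index(self, week: int) -> int:
        try:
            return self.weeks.index(week)
        except ValueError:
            raise KeyError(f"week {week} not phenotyped") from None

    def week_values(self, week: int) -> np.ndarray:
        return self.weights[:, self.week_index(week)]

    def copy(self) -> "PhenotypeSeries":
        return PhenotypeSeries(list(self.animal_ids), list(self.weeks),
                               self.weights.copy())


@dataclass(frozen=True)
class DietSchedule:
    """Contiguous, non-overlapping diet phases over the phenotyped weeks."""

    phases: tuple  # of (week_start, week_end, label)

    def __post_init__(self):
        last_end = None
        for start, end, label in self.phases:
            if label not in DIET_PHASES:
                raise ValueError(f"unknown diet phase {label!r}")
            if end < start:
                raise ValueError("phase end before start")
            if last_end is not None and start != last_end + 1:
                raise ValueError("diet phases must be contiguous and non-overlapping")
            last_end = end

    def phase(self, week: int) -> str:
        for start, end, label in self.phases:
            if start <= week <= end:
                return label
        raise KeyError(f"week {week} outside the diet schedule")

    @staticmethod
    def study_default() -> "DietSchedule":
        """Standard chow weeks 3-20, high-fat/low-carb 21-22, high-fat/high-carb 23-25."""
        return DietSchedule(((3, 20, "standard"), (21, 22, "HF_LC"), (23, 25, "HF_HC")))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def tss_bp(self) -> int:
        return self.start_bp if self.strand == "+" else self.end_bp


@dataclass(frozen=True)
class VariantConsequenceRecord:
    gene_id: str
    variant_id: str
    consequence_class: str
    sift_score: Optional[float] = None

    def __post_init__(self):
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"unknown consequence class {self.consequence_class!r} "
                f"(variant {self.variant_id}, gene {self.gene_id})")
        if self.sift_score is not None and not (0.0 <= self.sift_score <= 1.0):
            raise ValueError(f"SIFT score out of [0,1]: {self.sift_score}")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    fold_change: Optional[float] = None  # S1/S2
    p_raw: Optional[float] = None

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.fold_change is not None and self.fold_change <= 0:
            raise ValueError("fold change must be > 0")
        if self.p_raw is not None and not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_raw}")
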