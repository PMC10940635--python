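"""Readers and writers for the plain-text formats the pipeline touches.

Genotypes travel as a marker-per-row TSV/CSV (columns ``marker_id``,
``chromosome``, ``position`` then one column per animal, calls as S1/H/S2 or
0/1/2 tokens), phenotypes as a long or wide CSV, gene models as GFF3 or BED6,
variant consequences and expression as TSV. All readers accept gzip
transparently (pandas/open infer from the ``.gz`` suffix). Readers
canonicalise ordering so output is independent of input row order.
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (CONSEQUENCE_CLASSES, GENOTYPE_TOKENS, TOKEN_OF_CODE,
                    GeneModel, GenotypeMatrix, MarkerMap, PhenotypeSeries,
                    VariantConsequenceRecord, ExpressionRecord, sort_markers)

PathLike = Union[str, Path]

_META_COLS = ("marker_id", "chromosome", "position")


def _sep_for(path: PathLike, dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def _open_text(path: PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genotypes(path: PathLike, dialect: str = "auto") -> GenotypeMatrix:
    """Read a marker x animal genotype table into a validated, sorted matrix.

    Calls may be S1/H/S2 tokens or 0/1/2 codes; NA, ``-`` and the empty string
    mark missing. Duplicate marker ids and out-of-vocabulary tokens raise.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str,
                     keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in _META_COLS if c not in cols and
               (c != "position" or "position_bp" not in cols)]
    if missing:
        raise ValueError(f"genotype file lacks columns {missing}")
    pos_col = cols.get("position", cols.get("position_bp"))
    meta = pd.DataFrame({
        "marker_id": df[cols["marker_id"]],
        "chromosome": df[cols["chromosome"]],
        "position_bp": pd.to_numeric(df[pos_col]).astype(int),
    })
    animal_cols = [c for c in df.columns
                   if c not in (cols["marker_id"], cols["chromosome"], pos_col)]
    calls = np.empty((len(df), len(animal_cols)), dtype=np.int8)
    for j, col in enumerate(animal_cols):
        tokens = df[col].str.strip()
        for i, tok in enumerate(tokens):
            code = GENOTYPE_TOKENS.get(tok)
            if code is None:
                raise ValueError(
                    f"invalid genotype token {tok!r} at marker "
                    f"{meta['marker_id'].iloc[i]!r}, animal column {col!r}")
            calls[i, j] = code
    meta_sorted = sort_markers(meta)
    id_to_row = {m: i for i, m in enumerate(meta["marker_id"])}
    order = [id_to_row[m] for m in meta_sorted["marker_id"]]
    return GenotypeMatrix(MarkerMap(meta_sorted), list(animal_cols), calls[order])


def write_genotypes(geno: GenotypeMatrix, path: PathLike) -> None:
    sep = _sep_for(path, "auto")
    t = geno.map.table
    tokens = np.array([TOKEN_OF_CODE[c] for c in (-1, 0, 1, 2)])
    call_cols = pd.DataFrame(tokens[geno.calls.astype(int) + 1],
                             columns=geno.animal_ids)
    out = pd.concat([pd.DataFrame({"marker_id": t["marker_id"],
                                   "chromosome": t["chromosome"],
                                   "position": t["position_bp"]}),
                     call_cols], axis=1)
    out.to_csv(path, sep=sep, index=False)


def read_phenotypes(path: PathLike) -> PhenotypeSeries:
    """Read weekly weights from a long (animal, week, weight) or wide table."""
    df = pd.read_csv(path, sep=_sep_for(path, "auto"))
    cols = [c.lower() for c in df.columns]
    if {"animal", "week"}.issubset(cols):
        return _phenotypes_from_long(df.rename(columns=dict(zip(df.columns, cols))))
    return _phenotypes_from_wide(df)


def _phenotypes_from_long(df: pd.DataFrame) -> PhenotypeSeries:
    value_col = next(c for c in df.columns if c not in ("animal", "week"))
    if df.duplicated(subset=["animal", "week"]).any():
        dup = df[df.duplicated(subset=["animal", "week"])].iloc[0]
        raise ValueError(f"duplicate phenotype cell (animal {dup['animal']!r}, "
                         f"week {dup['week']})")
    vals = pd.to_numeric(df[value_col])
    if (vals.dropna() <= 0).any():
        bad = df.loc[vals <= 0].iloc[0]
        raise ValueError(f"non-positive weight {bad[value_col]} "
                         f"(animal {bad['animal']!r}, week {bad['week']})")
    wide = df.pivot(index="animal", columns="week", values=value_col)
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    return PhenotypeSeries([str(a) for a in wide.index],
                           [int(w) for w in wide.columns],
                           wide.to_numpy(dtype=float))


def _phenotypes_from_wide(df: pd.DataFrame) -> PhenotypeSeries:
    animal_col = df.columns[0]
    if df[animal_col].duplicated().any():
        raise ValueError("duplicate animal row in wide phenotype table")
    weeks = [int(str(c).lower().removeprefix("week_").removeprefix("w"))
             for c in df.columns[1:]]
    mat = df[df.columns[1:]].to_numpy(dtype=float)
    if (mat[~np.isnan(mat)] <= 0).any():
        raise ValueError("non-positive weight in wide phenotype table")
    order = np.argsort(weeks)
    df = df.sort_values(animal_col)
    mat = df[df.columns[1:]].to_numpy(dtype=float)[:, order]
    return PhenotypeSeries([str(a) for a in df[animal_col]],
                           sorted(weeks), mat)


def write_phenotypes(pheno: PhenotypeSeries, path: PathLike,
                     layout: str = "long") -> None:
    if layout == "long":
        rows = []
        for i, animal in enumerate(pheno.animal_ids):
            for j, week in enumerate(pheno.weeks):
                v = pheno.weights[i, j]
                if not math.isnan(v):
                    rows.append((animal, week, v))
        pd.DataFrame(rows, columns=["animal", "week", "weight_g"]).to_csv(
            path, sep=_sep_for(path, "auto"), index=False, float_format="%.6f")
    else:
        df = pd.DataFrame(pheno.weights, columns=pheno.weeks)
        df.insert(0, "animal", pheno.animal_ids)
        df.to_csv(path, sep=_sep_for(path, "auto"), index=False,
                  float_format="%.6f")


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GFF3 ``gene`` features.

    BED coordinates are converted to 1-based inclusive. The TSS is resolved by
    strand: gene start for '+', gene end for '-'.
    """
    with _open_text(path) as fh:
        first = fh.readline()
    is_gff = first.startswith("##gff") or len(first.rstrip("\n").split("\t")) == 9
    return _read_gff3_genes(path) if is_gff else _read_bed6_genes(path)


def _read_bed6_genes(path: PathLike) -> list[GeneModel]:
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            genes.append(GeneModel(gene_id=name, symbol=name, chromosome=chrom,
                                   start_bp=int(start) + 1, end_bp=int(end),
                                   strand=strand))
    return genes


def _gff_attributes(attr: str) -> dict:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3_genes(path: PathLike) -> list[GeneModel]:
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: gene record without "
                                 f"a '+'/'-' strand (got {strand!r})")
            a = _gff_attributes(attrs)
            gid = a.get("ID", a.get("gene_id", f"gene_line{lineno}"))
            symbol = a.get("Name", a.get("gene_name", gid))
            genes.append(GeneModel(gene_id=gid, symbol=symbol, chromosome=chrom,
                                   start_bp=int(start), end_bp=int(end),
                                   strand=strand))
    return genes


def read_consequences(path: PathLike) -> list[VariantConsequenceRecord]:
    """Read a VEP-style consequence TSV (gene, variant, class, optional SIFT)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path, "auto"))
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    cols = {c.lower(): c for c in df.columns}
    records = []
    for _, row in df.iterrows():
        cls = str(row[cols["consequence_class"]]).strip().lower().replace(" ", "_")
        if cls not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {cls!r} for variant "
                             f"{row[cols['variant_id']]!r}")
        sift = None
        if "sift_score" in cols:
            raw = row[cols["sift_score"]]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) \
                    and str(raw).strip() not in ("", "NA"):
                sift = float(raw)
        records.append(VariantConsequenceRecord(
            gene_id=str(row[cols["gene_id"]]),
            variant_id=str(row[cols["variant_id"]]),
            consequence_class=cls, sift_score=sift))
    return records


def read_expression(path: PathLike) -> list[ExpressionRecord]:
    """Read a differential-expression TSV: gene_id, tissue, fold_change, p_value."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path, "auto"))
    except pd.errors.EmptyDataError:
        return []
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        def _opt(col):
            if col not in cols:
                return None
            v = row[cols[col]]
            if v is None or (isinstance(v, float) and math.isnan(v)) or \
                    str(v).strip() in ("", "NA", "Not det."):
                return None
            return float(v)
        out.append(ExpressionRecord(gene_id=str(row[cols["gene_id"]]),
                                    tissue=str(row[cols["tissue"]]),
                                    fold_change=_opt("fold_change"),
                                    p_raw=_opt("p_value")))
    return out
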