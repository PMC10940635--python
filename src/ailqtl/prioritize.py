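"""Candidate-gene prioritization inside a QTL interval.

Genes are scored additively over evidence categories: predicted variant
consequences (missense in a functional domain split by SIFT deleteriousness,
UTR/promoter/enhancer/CTCF/splice-site hits), per-tissue differential
expression between the founder lines (BH-adjusted p < alpha), and pathway
membership. The weights are configurable; the packaged default reproduces
the published candidate ordering on the bundled fixture. A small neutral
weight is granted per tissue whose expression could not be measured, so
"no data" ranks between "differentially expressed" and "measured, not DE".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import AggregateQtl
from .types import ExpressionRecord, GeneModel, VariantConsequenceRecord

FLAG_CATEGORIES = ("deleterious_domain_missense", "tolerated_domain_missense",
                   "utr", "promoter", "enhancer", "ctcf_binding", "splice_site")

DEFAULT_WEIGHTS: Mapping[str, float] = {
    "deleterious_domain_missense": 8.0,
    "tolerated_domain_missense": 3.0,
    "utr": 1.0,
    "promoter": 1.5,
    "enhancer": 1.0,
    "ctcf_binding": 1.5,
    "splice_site": 1.0,
}


@dataclass(frozen=True)
class ScoringConfig:
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    de_weight: float = 2.0          # per tissue with adjusted p < de_alpha
    not_determined_weight: float = 0.5  # per tissue without expression data
    kegg_weight: float = 1.0
    de_alpha: float = 0.05
    sift_deleterious_below: float = 0.05
    padding_bp: int = 1000  # up/downstream slack when assigning variants to genes

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()) or self.de_weight < 0 \
                or self.kegg_weight < 0 or self.not_determined_weight < 0:
            raise ValueError("scoring weights must be >= 0")


@dataclass
class GeneScoreCard:
    gene_id: str
    flags: dict
    de_adipose: bool = False
    de_liver: bool = False
    fc_adipose: Optional[float] = None
    fc_liver: Optional[float] = None
    expr_measured_adipose: bool = True
    expr_measured_liver: bool = True
    kegg_member: bool = False
    score: float = 0.0
    rank: int = 0


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genes_in_interval(genes: Iterable[GeneModel], qtl) -> list[GeneModel]:
    """Genes overlapping the QTL span by any amount (1-based inclusive)."""
    if isinstance(qtl, AggregateQtl):
        chrom, start, end = qtl.chromosome, qtl.final_start_bp, qtl.final_end_bp
    else:
        chrom, start, end = qtl
    return [g for g in genes
            if g.chromosome == chrom and g.end_bp >= start and g.start_bp <= end]


def flags_from_consequences(records: Iterable[VariantConsequenceRecord],
                            config: ScoringConfig = ScoringConfig()
                            ) -> dict[str, dict]:
    """Collapse variant records to per-gene boolean evidence flags.

    A missense record with a SIFT score is re-labelled by the SIFT convention
    (deleterious below 0.05) regardless of its incoming class; without a
    score the incoming label is trusted.
    """
    out: dict[str, dict] = {}
    for rec in records:
        flags = out.setdefault(rec.gene_id, {c: False for c in FLAG_CATEGORIES})
        cls = rec.consequence_class
        if cls in ("deleterious_domain_missense", "tolerated_domain_missense") \
                and rec.sift_score is not None:
            cls = ("deleterious_domain_missense"
                   if rec.sift_score < config.sift_deleterious_below
                   else "tolerated_domain_missense")
        if cls in FLAG_CATEGORIES:
            flags[cls] = True
    return out


def score_gene(gene_id: str, flags: Mapping[str, bool],
               expression: Sequence[ExpressionRecord] = (),
               kegg_member: bool = False,
               config: ScoringConfig = ScoringConfig(),
               p_already_adjusted: bool = True) -> GeneScoreCard:
    """Additive evidence score for one gene; deterministic."""
    card = GeneScoreCard(gene_id=gene_id,
                         flags={c: bool(flags.get(c, False)) for c in FLAG_CATEGORIES},
                         kegg_member=kegg_member)
    by_tissue = {"gonadal_adipose": None, "liver": None}
    for rec in expression:
        if rec.gene_id == gene_id:
            by_tissue[rec.tissue] = rec
    for tissue, attr in (("gonadal_adipose", "adipose"), ("liver", "liver")):
        rec = by_tissue[tissue]
        measured = rec is not None and rec.p_raw is not None
        setattr(card, f"expr_measured_{attr}", measured)
        if measured:
            setattr(card, f"fc_{attr}", rec.fold_change)
            p = rec.p_raw if p_already_adjusted else float(bh_adjust([rec.p_raw])[0])
            setattr(card, f"de_{attr}", bool(p < config.de_alpha))
    score = sum(config.weights.get(c, 0.0) for c in FLAG_CATEGORIES
                if card.flags[c])
    score += config.de_weight * (card.de_adipose + card.de_liver)
    score += config.not_determined_weight * ((not card.expr_measured_adipose) +
                                             (not card.expr_measured_liver))
    score += config.kegg_weight * card.kegg_member
    card.score = float(score)
    return card


def rank_candidates(cards: Sequence[GeneScoreCard]) -> list[GeneScoreCard]:
    """Order by descending score; ties share a dense rank and sort by gene id."""
    if not cards:
        raise ValueError("no score cards to rank")
    ordered = sorted(cards, key=lambda c: (-c.score, c.gene_id))
    rank = 0
    last_score = None
    for card in ordered:
        if last_score is None or card.score != last_score:
            rank += 1
            last_score = card.score
        card.rank = rank
    return ordered


def prioritize_interval(genes: Sequence[GeneModel], qtl,
                        consequences: Sequence[VariantConsequenceRecord],
                        expression: Sequence[ExpressionRecord] = (),
                        kegg_members: Iterable[str] = (),
                        config: ScoringConfig = ScoringConfig(),
                        p_already_adjusted: bool = False
                        ) -> list[GeneScoreCard]:
    """Score and rank every gene overlapping the QTL interval.

    Raw expression p-values are BH-adjusted jointly per tissue across the
    interval's genes before thresholding (set ``p_already_adjusted`` when the
    table already carries adjusted values).
    """
    inside = genes_in_interval(genes, qtl)
    ids = {g.gene_id for g in inside}
    expr = [e for e in expression if e.gene_id in ids]
    if not p_already_adjusted and expr:
        for tissue in ("gonadal_adipose", "liver"):
            rows = [i for i, e in enumerate(expr)
                    if e.tissue == tissue and e.p_raw is not None]
            if rows:
                adj = bh_adjust([expr[i].p_raw for i in rows])
                for i, padj in zip(rows, adj):
                    expr[i] = replace(expr[i], p_raw=float(padj))
    flag_map = flags_from_consequences(
        [r for r in consequences if r.gene_id in ids], config)
    kegg = set(kegg_members)
    cards = [score_gene(g.gene_id, flag_map.get(g.gene_id, {}), expr,
                        kegg_member=g.gene_id in kegg, config=config,
                        p_already_adjusted=True)
             for g in inside]
    return rank_candidates(cards) if cards else []


def load_candidate_fixture() -> pd.DataFrame:
    """Bundled founder-line candidate-gene evidence table (synthetic fixture
    assembled from published summary statistics; see the file header)."""
    with resources.files("ailqtl.data").joinpath(
            "candidate_gene_fixture.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def cards_from_fixture(df: Optional[pd.DataFrame] = None,
                       config: ScoringConfig = ScoringConfig()
                       ) -> list[GeneScoreCard]:
    """Score the bundled evidence table. Fixture p-values are already
    BH-adjusted; 'not determined' expression cells are empty."""
    if df is None:
        df = load_candidate_fixture()
    cards = []
    for _, row in df.iterrows():
        flags = {c: bool(row[c]) for c in FLAG_CATEGORIES}
        expr = []
        for tissue, col in (("gonadal_adipose", "adipose"), ("liver", "liver")):
            p = row[f"p_{col}_adj"]
            fc = row[f"fc_{col}"]
            if not pd.isna(p):
                expr.append(ExpressionRecord(
                    gene_id=row["gene_id"], tissue=tissue,
                    fold_change=None if pd.isna(fc) else float(fc),
                    p_raw=float(p)))
        cards.append(score_gene(row["gene_id"], flags, expr,
                                kegg_member=bool(row["kegg_member"]),
                                config=config, p_already_adjusted=True))
    return rank_candidates(cards)
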