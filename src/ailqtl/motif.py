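"""Carbohydrate-response-element (ChoRE) detection in promoter regions.

A degenerate consensus (e.g. ChoRE-b ``CACACC(N)5CACGCG``) is turned into a
unit-weight position matrix: each informative (non-N) position contributes 1
for the consensus base and 0 otherwise; N positions carry zero weight and are
excluded from the score denominator. A window's score is therefore the
fraction of informative positions it matches, and ``min_score = 0.90`` admits
at most one mismatch over the 12 informative positions of either ChoRE
consensus. Scanning covers the 2000 bp upstream of each gene's TSS on both
strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .types import GeneModel

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    pattern: str  # over {A, C, G, T, N}

    def __post_init__(self):
        bad = set(self.pattern.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid consensus characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def informative(self) -> np.ndarray:
        return np.array([c != "N" for c in self.pattern.upper()])

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())


CHORE_A = ConsensusMotif("ChoRE-a", "CACGAG" + "N" * 5 + "CACGAG")
CHORE_B = ConsensusMotif("ChoRE-b", "CACACC" + "N" * 5 + "CACGCG")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    strand: str          # '+' = match on the sequence as given
    start: int           # 1-based inclusive, on the scanned sequence
    end: int
    score: float         # matched informative fraction, in [0, 1]
    matched_seq: str     # forward letters of the scanned sequence


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def pwm_from_consensus(motif: ConsensusMotif) -> np.ndarray:
    """4 x L unit-weight matrix (rows A, C, G, T); N columns are all-zero.
    The maximum achievable score equals the number of informative positions."""
    pwm = np.zeros((4, motif.length))
    for j, c in enumerate(motif.pattern.upper()):
        if c != "N":
            pwm[_BASE_INDEX[c], j] = 1.0
    return pwm


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N/unknown, never matches
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scan_one_strand(codes: np.ndarray, motif: ConsensusMotif,
                     min_score: float) -> list[tuple[int, float]]:
    L = motif.length
    if codes.size < L:
        return []
    cons = _encode(motif.pattern)
    info = motif.informative
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    match = (windows[:, info] == cons[info][None, :])
    scores = match.mean(axis=1)
    hits = np.flatnonzero(scores >= min_score - 1e-12)
    return [(int(i), float(scores[i])) for i in hits]


def scan_sequence(seq: str, motif: ConsensusMotif, min_score: float = 0.90,
                  both_strands: bool = True) -> list[MotifHit]:
    """All windows of ``seq`` (and, optionally, its reverse complement)
    matching the consensus at >= ``min_score`` of informative positions.
    Overlapping hits are all reported; letters at N positions never matter.
    Coordinates are 1-based on the given sequence; '-' strand hits are mapped
    back to forward coordinates and report the forward-strand letters.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid letters: {sorted(bad)}")
    codes = _encode(seq)
    n, L = len(seq), motif.length
    hits = [MotifHit(motif.name, "+", i + 1, i + L, score, seq[i:i + L])
            for i, score in _scan_one_strand(codes, motif, min_score)]
    if both_strands:
        rc_codes = _encode(reverse_complement(seq))
        for i, score in _scan_one_strand(rc_codes, motif, min_score):
            start_fw = n - i - L  # 0-based forward start
            hits.append(MotifHit(motif.name, "-", start_fw + 1, start_fw + L,
                                 score, seq[start_fw:start_fw + L]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    chromosome: str
    start_bp: int  # genomic, 1-based inclusive
    end_bp: int
    strand: str
    seq: str  # promoter-oriented (reverse-complemented for '-' genes)


def extract_upstream(gene: GeneModel, genome: Union[str, Path, Fasta],
                     length: int = 2000) -> UpstreamRegion:
    """Sequence upstream of the TSS, reading toward the gene.

    '+' genes: genomic [tss - length, tss - 1] as-is; '-' genes: reverse
    complement of [tss + 1, tss + length]. Truncated at chromosome ends with
    a warning.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    if gene.chromosome not in fasta:
        raise KeyError(f"chromosome {gene.chromosome!r} not in the genome FASTA")
    chrom_len = len(fasta[gene.chromosome])
    tss = gene.tss_bp
    if gene.strand == "+":
        start, end = tss - length, tss - 1
    else:
        start, end = tss + 1, tss + length
    t_start, t_end = max(1, start), min(chrom_len, end)
    if (t_start, t_end) != (start, end):
        warnings.warn(f"gene {gene.gene_id}: upstream window truncated to "
                      f"{t_start}-{t_end} at a chromosome end")
    if t_start > t_end:
        return UpstreamRegion(gene.gene_id, gene.chromosome, tss, tss,
                              gene.strand, "")
    seq = fasta[gene.chromosome][t_start - 1:t_end].seq.upper()
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return UpstreamRegion(gene.gene_id, gene.chromosome, t_start, t_end,
                          gene.strand, seq)


def scan_gene_set(genes: Sequence[GeneModel], genome: Union[str, Path, Fasta],
                  motifs: Iterable[ConsensusMotif] = (CHORE_A, CHORE_B),
                  upstream: int = 2000, min_score: float = 0.90
                  ) -> pd.DataFrame:
    """Scan each gene's upstream region; hits carry genome coordinates.

    Returned strand is the genome strand of the matched motif (a '+' hit in a
    '-' gene's promoter-oriented sequence lies on the genome's '-' strand).
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    rows = []
    for gene in genes:
        region = extract_upstream(gene, fasta, length=upstream)
        for motif in motifs:
            for hit in scan_sequence(region.seq, motif, min_score=min_score):
                if gene.strand == "+":
                    g_start = region.start_bp + hit.start - 1
                    g_end = region.start_bp + hit.end - 1
                    g_strand = hit.strand
                    fwd = hit.matched_seq
                else:
                    g_start = region.end_bp - hit.end + 1
                    g_end = region.end_bp - hit.start + 1
                    g_strand = "-" if hit.strand == "+" else "+"
                    fwd = reverse_complement(hit.matched_seq)
                rows.append((gene.gene_id, motif.name, gene.chromosome,
                             g_start, g_end, g_strand, hit.score, fwd))
    return pd.DataFrame(rows, columns=["gene_id", "motif", "chromosome",
                                       "start_bp", "end_bp", "strand",
                                       "score", "matched_seq"])


def hits_to_bed(hits: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a hit table (0-based half-open, score scaled to 0-1000)."""
    return pd.DataFrame({
        "chrom": hits["chromosome"], "start": hits["start_bp"] - 1,
        "end": hits["end_bp"], "name": hits["gene_id"] + ":" + hits["motif"],
        "score": (hits["score"] * 1000).round().astype(int),
        "strand": hits["strand"]})
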