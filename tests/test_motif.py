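import math

import numpy as np
import pytest

from ailqtl import (CHORE_A, CHORE_B, ConsensusMotif, GeneModel,
                    extract_upstream, pwm_from_consensus, scan_gene_set,
                    scan_sequence)
from ailqtl.motif import reverse_complement

CHORE_B_CONSENSUS = "CACACC" + "AAAAA" + "CACGCG"  # N positions filled with A


def _write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return str(path)


class TestPwm:
    def test_unit_weights_on_consensus_bases(self):
        pwm = pwm_from_consensus(ConsensusMotif("x", "CA"))
        assert pwm[:, 0].tolist() == [0, 1, 0, 0]
        assert pwm[:, 1].tolist() == [1, 0, 0, 0]

    def test_n_column_all_zero(self):
        pwm = pwm_from_consensus(ConsensusMotif("x", "N"))
        assert pwm.sum() == 0

    def test_chore_b_has_twelve_informative_columns(self):
        assert CHORE_B.length == 17
        assert CHORE_B.n_informative == 12
        assert pwm_from_consensus(CHORE_B).sum() == 12

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            ConsensusMotif("x", "CAQ")


class TestScanSequence:
    def test_exact_consensus_scores_one(self):
        (hit,) = scan_sequence(CHORE_B_CONSENSUS, CHORE_B, both_strands=False)
        assert hit.score == 1.0 and (hit.start, hit.end) == (1, 17)

    def test_one_informative_mismatch_passes_90pct(self):
        # the published promoter hit deviates at a single informative base
        seq = "CACACT" + "AAAAA" + "CACGCG"
        (hit,) = scan_sequence(seq, CHORE_B, both_strands=False)
        assert hit.score == pytest.approx(11 / 12)
        assert hit.score >= 0.90

    def test_two_informative_mismatches_fail(self):
        seq = "CACACT" + "AAAAA" + "CACGCT"
        assert scan_sequence(seq, CHORE_B, both_strands=False) == []

    def test_score_ignores_letters_at_n_positions(self):
        for filler in ("AAAAA", "GGGGG", "ACGTN"):
            seq = "CACACC" + filler + "CACGCG"
            (hit,) = scan_sequence(seq, CHORE_B, both_strands=False)
            assert hit.score == 1.0

    def test_strand_symmetry(self):
        """A + hit on a sequence appears as a - hit on its reverse complement
        at mirrored coordinates with the same score."""
        rng = np.random.default_rng(0)
        pad = "".join(rng.choice(list("ACGT"), size=30))
        seq = pad + CHORE_B_CONSENSUS + pad
        fwd = [h for h in scan_sequence(seq, CHORE_B) if h.strand == "+"]
        rc = [h for h in scan_sequence(reverse_complement(seq), CHORE_B)
              if h.strand == "-"]
        assert len(fwd) == len(rc) == 1
        n = len(seq)
        assert rc[0].start == n - fwd[0].end + 1
        assert rc[0].end == n - fwd[0].start + 1
        assert rc[0].score == fwd[0].score

    def test_sequence_shorter_than_motif(self):
        assert scan_sequence("CACGT", CHORE_B) == []

    def test_overlapping_hits_all_reported(self):
        seq = CHORE_B_CONSENSUS + CHORE_B_CONSENSUS
        hits = [h for h in scan_sequence(seq, CHORE_B, both_strands=False)]
        assert len(hits) == 2


class TestExtractUpstream:
    def test_plus_strand_window(self, tmp_path):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=5000))
        fasta = _write_fasta(tmp_path / "g.fa", {"chr1": seq})
        gene = GeneModel("g", "g", "chr1", 3000, 3500, "+")
        region = extract_upstream(gene, fasta, length=2000)
        assert (region.start_bp, region.end_bp) == (1000, 2999)
        assert region.seq == seq[999:2999]

    def test_minus_strand_reverse_complement(self, tmp_path):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=6000))
        fasta = _write_fasta(tmp_path / "g.fa", {"chr1": seq})
        gene = GeneModel("g", "g", "chr1", 2500, 3000, "-")
        region = extract_upstream(gene, fasta, length=2000)
        assert (region.start_bp, region.end_bp) == (3001, 5000)
        assert region.seq == reverse_complement(seq[3000:5000])

    def test_truncation_at_chromosome_start_warns(self, tmp_path):
        seq = "".join(np.random.default_rng(3).choice(list("ACGT"), size=500))
        fasta = _write_fasta(tmp_path / "g.fa", {"chr1": seq})
        gene = GeneModel("g", "g", "chr1", 100, 300, "+")
        with pytest.warns(UserWarning, match="truncated"):
            region = extract_upstream(gene, fasta, length=2000)
        assert (region.start_bp, region.end_bp) == (1, 99)

    def test_missing_chromosome_rejected(self, tmp_path):
        fasta = _write_fasta(tmp_path / "g.fa", {"chr1": "ACGT" * 100})
        gene = GeneModel("g", "g", "chrX", 100, 300, "+")
        with pytest.raises(KeyError):
            extract_upstream(gene, fasta)


class TestScanGeneSet:
    def test_planted_motif_recovered_with_genome_coordinates(self, tmp_path):
        rng = np.random.default_rng(4)
        seq = list("".join(rng.choice(list("ACGT"), size=10_000)))
        # plant an exact consensus 500 bp upstream of a + gene's TSS
        tss = 6000
        insert_at = tss - 500  # 1-based genomic start of the motif
        seq[insert_at - 1:insert_at - 1 + 17] = CHORE_B_CONSENSUS
        fasta = _write_fasta(tmp_path / "g.fa", {"chr15": "".join(seq)})
        genes = [GeneModel("hit_gene", "hit_gene", "chr15", tss, tss + 800, "+"),
                 GeneModel("null_gene", "null_gene", "chr15", 9000, 9500, "+")]
        hits = scan_gene_set(genes, fasta, motifs=[CHORE_B])
        perfect = hits[hits["score"] == 1.0]
        assert set(perfect["gene_id"]) == {"hit_gene"}
        row = perfect.iloc[0]
        assert (row["start_bp"], row["end_bp"]) == (insert_at, insert_at + 16)
        assert row["matched_seq"] == CHORE_B_CONSENSUS

    def test_minus_strand_gene_reports_genome_reverse_hit(self, tmp_path):
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), size=8000)))
        tss = 3000  # '-' gene: upstream is [3001, 5000] on the genome
        insert_at = 4000
        # plant the reverse complement so the promoter-oriented scan sees '+'
        seq[insert_at - 1:insert_at + 16] = reverse_complement(CHORE_B_CONSENSUS)
        fasta = _write_fasta(tmp_path / "g.fa", {"chr15": "".join(seq)})
        gene = GeneModel("g", "g", "chr15", 2000, tss, "-")
        hits = scan_gene_set([gene], fasta, motifs=[CHORE_B])
        perfect = hits[hits["score"] == 1.0]
        assert len(perfect) == 1
        row = perfect.iloc[0]
        assert (row["start_bp"], row["end_bp"]) == (insert_at, insert_at + 16)
        assert row["strand"] == "-"

    def test_random_sequence_hit_rate_matches_closed_form(self, tmp_path):
        """Hits on random DNA follow the <=1-mismatch binomial probability."""
        rng = np.random.default_rng(6)
        n_genes, up = 60, 2000
        chrom = "".join(rng.choice(list("ACGT"), size=(n_genes + 1) * 3000))
        fasta = _write_fasta(tmp_path / "g.fa", {"chr1": chrom})
        genes = [GeneModel(f"g{i}", f"g{i}", "chr1", 3000 * (i + 1),
                           3000 * (i + 1) + 100, "+")
                 for i in range(n_genes)]
        hits = scan_gene_set(genes, fasta, motifs=[CHORE_B], upstream=up)
        k = CHORE_B.n_informative
        p_hit = (0.25 ** k) * (1 + k * 3)  # P(0 or 1 mismatch in 12 positions)
        n_windows = n_genes * 2 * (up - CHORE_B.length + 1)
        expected = n_windows * p_hit
        tol = 4 * math.sqrt(expected) + 2  # binomial error with slack
        assert abs(len(hits) - expected) <= tol

    def test_empty_gene_list(self, tmp_path):
        fasta = _write_fasta(tmp_path / "g.fa", {"chr1": "ACGT" * 1000})
        assert scan_gene_set([], fasta).empty
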