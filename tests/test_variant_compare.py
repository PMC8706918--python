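import numpy as np
import pytest
from Bio import Align

from mitocompare.genome_io import CircularSequence, FeatureAnnotation, GenomeBundle
from mitocompare.synthetic_data import generate_mitogenome, mutate_genome
from mitocompare.variant_compare import (MITO_TABLE, AlignParams, PairwiseAlignment,
                                         align_pair, call_variants, classify_effect,
                                         pairwise_matrix, read_aligned_fasta_pair)

from conftest import random_sequence


def _cs(label: str, s: str) -> CircularSequence:
    return CircularSequence(label, s, True)


class TestAlignPair:
    def test_identity(self):
        s = "ACGTACGTACGTAAACGT"
        aln = align_pair(_cs("a", s), _cs("b", s))
        assert aln.rows == (s, s)

    def test_single_deletion(self):
        aln = align_pair(_cs("a", "ACGTACGT"), _cs("b", "ACGACGT"))
        assert aln.rows[0].replace("-", "") == "ACGTACGT"
        assert aln.rows[1].count("-") == 1

    def test_matches_biopython_global_score_on_small_pairs(self):
        # independent oracle: unbanded global affine aligner
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -6   # first gapped base
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(30, 120))
            a = random_sequence(rng, n, at_rich=False)
            b = list(a)
            for _ in range(int(rng.integers(1, 5))):
                i = int(rng.integers(0, len(b)))
                op = rng.integers(0, 3)
                if op == 0:
                    b[i] = "ACGT"[rng.integers(0, 4)]
                elif op == 1 and len(b) > 10:
                    del b[i]
                else:
                    b.insert(i, "ACGT"[rng.integers(0, 4)])
            bseq = "".join(b)
            ours = align_pair(_cs("a", a), _cs("b", bseq))
            assert ours.score == aligner.score(a, bseq)

    def test_rows_ungap_to_inputs(self):
        base, _ = generate_mitogenome(length=3000, control_region_length=400, seed=2)
        mut, _ = mutate_genome(base, n_snps=4, indel_spec=[(3, "del")], seed=3)
        aln = align_pair(base.sequence, mut.sequence)
        assert aln.rows[0].replace("-", "") == base.sequence.residues
        assert aln.rows[1].replace("-", "") == mut.sequence.residues

    def test_external_alignment_validated(self, tmp_path):
        p = tmp_path / "aln.fa"
        p.write_text(">a\nAC-GT\n>b\nACCGT\n")
        aln = read_aligned_fasta_pair(p, _cs("a", "ACGT"), _cs("b", "ACCGT"))
        assert aln.rows == ("AC-GT", "ACCGT")
        with pytest.raises(ValueError, match="mismatch"):
            read_aligned_fasta_pair(p, _cs("a", "ACTT"), _cs("b", "ACCGT"))


class TestCallVariants:
    def test_single_snp(self):
        vs = call_variants(PairwiseAlignment(("a", "b"), ("ACGT", "ACCT")))
        assert len(vs.snps) == 1 and not vs.indel_regions
        s = vs.snps[0]
        assert (s.pos_a, s.base_a, s.base_b) == (3, "G", "C")

    def test_single_indel_region(self):
        vs = call_variants(PairwiseAlignment(("a", "b"), ("AC--GTT", "ACTTGTT")))
        assert not vs.snps
        (r,) = vs.indel_regions
        assert (r.col_start, r.col_end, r.length, r.inserted_in) == (3, 4, 2, "b")

    def test_mixed_row_gap_run_merges_by_default(self):
        aln = PairwiseAlignment(("a", "b"), ("A--CCG", "ATT--G"))
        vs = call_variants(aln)
        assert not vs.snps
        (r,) = vs.indel_regions
        assert (r.col_start, r.col_end, r.length, r.inserted_in) == (2, 5, 4, "mixed")

    def test_mixed_row_gap_run_splits_with_flag(self):
        aln = PairwiseAlignment(("a", "b"), ("A--CCG", "ATT--G"))
        vs = call_variants(aln, split_by_row=True)
        assert [(r.col_start, r.col_end, r.length) for r in vs.indel_regions] == \
               [(2, 3, 2), (4, 5, 2)]

    def test_n_columns_never_called(self):
        vs = call_variants(PairwiseAlignment(("a", "b"), ("ANGT", "ACGT")))
        assert not vs.snps

    def test_symmetry(self):
        base, _ = generate_mitogenome(length=4000, control_region_length=500, seed=5)
        mut, _ = mutate_genome(base, n_snps=7, indel_spec=[(2, "ins"), (3, "del")], seed=6)
        ab = call_variants(align_pair(base.sequence, mut.sequence))
        ba = call_variants(align_pair(mut.sequence, base.sequence))
        assert len(ab.snps) == len(ba.snps)
        assert len(ab.indel_regions) == len(ba.indel_regions)
        assert ab.total_indel_bp == ba.total_indel_bp

    def test_gap_column_conservation(self):
        base, _ = generate_mitogenome(length=4000, control_region_length=500, seed=9)
        mut, _ = mutate_genome(base, n_snps=3, indel_spec=[(4, "ins"), (1, "del")], seed=10)
        aln = align_pair(base.sequence, mut.sequence)
        vs = call_variants(aln)
        n_gap_cols = sum(1 for x, y in zip(*aln.rows) if x == "-" or y == "-")
        assert vs.total_indel_bp == n_gap_cols

    def test_planted_truth_recovered_exactly(self):
        base, _ = generate_mitogenome(seed=3)
        mut, truth = mutate_genome(
            base, n_snps=21, indel_spec=[(1, "del"), (2, "ins"), (2, "del"), (4, "ins")],
            seed=4)
        vs = call_variants(align_pair(base.sequence, mut.sequence), base)
        assert len(vs.snps) == 21
        assert len(vs.indel_regions) == 4
        assert vs.total_indel_bp == 9
        got = {(s.pos_a, s.base_a, s.base_b) for s in vs.snps}
        assert got == {tuple(s) for s in truth.planted_snps}

    def test_longest_control_region_indel(self):
        base, _ = generate_mitogenome(seed=3)
        cr = next(f for f in base.features if f.kind == "control_region")
        mut, truth = mutate_genome(base, n_snps=0, indel_spec=[(42, "del")], seed=9)
        vs = call_variants(align_pair(base.sequence, mut.sequence), base)
        (r,) = vs.indel_regions
        assert r.length == 42
        pos = truth.planted_indels[0][0]
        assert cr.start <= pos <= cr.end


class TestClassifyEffect:
    def _bundle(self, cds: str, strand: str = "+") -> GenomeBundle:
        pad = "GCTAGCTAGC"
        seq = pad + (cds if strand == "+" else _rc(cds)) + pad
        return GenomeBundle(
            CircularSequence("g", seq, True),
            [FeatureAnnotation("p", "PCG", "PCG1", 11, 10 + len(cds), strand)])

    def test_third_position_leucine_synonymous(self):
        b = self._bundle("ATGTTACCC")  # codons ATG TTA CCC
        assert classify_effect(16, "A", "G", b) == "synonymous"  # TTA->TTG both Leu

    def test_stop_gain_is_nonsynonymous(self):
        b = self._bundle("ATGAAACCC")
        assert classify_effect(14, "A", "T", b) == "nonsynonymous"  # AAA->TAA stop

    def test_noncoding_position(self):
        b = self._bundle("ATGAAACCC")
        assert classify_effect(2, "C", "T", b) == "noncoding"

    def test_minus_strand_codon(self):
        b = self._bundle("ATGTTACCC", strand="-")
        # genome carries the reverse complement; the gene still reads ATG TTA CCC
        pos = 10 + len("ATGTTACCC") - 5  # genome position of the TTA third base
        ref = b.sequence.residues[pos - 1]
        alt = {"T": "C", "C": "T", "A": "G", "G": "A"}[ref]
        effect = classify_effect(pos, ref, alt, b)
        assert effect in {"synonymous", "nonsynonymous"}

    def test_broken_frame_returns_na(self):
        seq = "GCTAGCTAGC" + "ATGAAACC" + "GCTAGCTAGC"  # 8 bp, not a codon multiple
        b = GenomeBundle(CircularSequence("g", seq, True),
                         [FeatureAnnotation("p", "PCG", "PCG1", 11, 18, "+")])
        assert classify_effect(12, "T", "C", b) == "NA"

    def test_agrees_with_full_gene_translation(self):
        # oracle: translate the whole mutated gene and compare proteins
        rng = np.random.default_rng(12)
        codons = [c for c in MITO_TABLE.forward_table if "U" not in c]
        for _ in range(30):
            cds = "ATG" + "".join(rng.choice(codons) for _ in range(20))
            b = self._bundle(cds)
            off = int(rng.integers(0, len(cds)))
            ref = cds[off]
            alt = rng.choice([x for x in "ACGT" if x != ref])
            mutated = cds[:off] + alt + cds[off + 1 :]
            prot = lambda s: "".join(
                MITO_TABLE.forward_table.get(s[i:i+3], "*") for i in range(0, len(s), 3))
            expected = "synonymous" if prot(cds) == prot(mutated) else "nonsynonymous"
            assert classify_effect(11 + off, ref, alt, b) == expected

    def test_reference_base_mismatch_raises(self):
        b = self._bundle("ATGTTACCC")
        with pytest.raises(ValueError, match="mismatch"):
            classify_effect(11, "C", "G", b)


def _rc(s: str) -> str:
    from mitocompare.genome_io import reverse_complement
    return reverse_complement(s)


def test_pairwise_matrix_symmetric_counts():
    base, _ = generate_mitogenome(length=5000, control_region_length=600, seed=21)
    m1, _ = mutate_genome(base, n_snps=5, indel_spec=[(2, "del")], seed=22)
    m2, _ = mutate_genome(base, n_snps=3, indel_spec=[(1, "ins")], seed=23)
    from dataclasses import replace
    bundles = [base,
               GenomeBundle(replace(m1.sequence, seq_id="g2")),
               GenomeBundle(replace(m2.sequence, seq_id="g3"))]
    mat = pairwise_matrix(bundles)
    assert len(mat) == 3
    vs = mat[(base.sequence.seq_id, "g2")]
    assert len(vs.snps) == 5 and vs.total_indel_bp == 2
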