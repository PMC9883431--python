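import numpy as np
import pytest

import zegselect as z
from zegselect.locus_model import AlleleKind, AlleleSpec, canonical_indel
from zegselect.readproc import (
    DemuxError,
    ReadRecord,
    ReadTooShortError,
    UmiScheme,
    _as_plain_ref,
    revcomp,
    umi_consensus,
)
from zegselect.synthetic_data import random_allele


def _read(seq1, seq2="ACGT", id="r"):
    return ReadRecord(id=id, seq1=seq1, qual1="I" * len(seq1), seq2=seq2, qual2="I" * len(seq2))


class TestDemultiplex:
    BARCODES = {"s1": "AAAAAAAA", "s2": "TTTTTTTT", "s3": "ACGTACGT"}

    def test_exact_and_near_barcodes_assigned(self):
        reads = [_read("AAAAAAAA" + "C" * 10), _read("AAAAAAAT" + "C" * 10)]
        assigned, unassigned = z.demultiplex(reads, self.BARCODES, max_mismatch=1)
        assert len(assigned["s1"]) == 2 and not unassigned
        assert all(r.sample == "s1" for r in assigned["s1"])

    def test_distant_read_unassigned(self):
        reads = [_read("AAATTTAA" + "C" * 10)]  # >=2 mismatches from every barcode
        assigned, unassigned = z.demultiplex(reads, self.BARCODES, max_mismatch=1)
        assert len(unassigned) == 1
        assert sum(len(v) for v in assigned.values()) == 0

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(0)
        reads = [
            _read("".join(rng.choice(list("ACGT"), 8)) + "C" * 5, id=f"r{i}")
            for i in range(50)
        ]
        assigned, unassigned = z.demultiplex(reads, self.BARCODES, max_mismatch=1)
        assert sum(len(v) for v in assigned.values()) + len(unassigned) == 50

    def test_ambiguous_barcode_table_refused(self):
        # Hamming distance 2 == 2*max_mismatch: a read can tie between them
        bad = {"a": "AAAAAAAA", "b": "AAAAAATT"}
        with pytest.raises(DemuxError, match="distance"):
            z.demultiplex([_read("A" * 8 + "C")], bad, max_mismatch=1)

    def test_unequal_lengths_refused(self):
        with pytest.raises(DemuxError):
            z.demultiplex([_read("A" * 9)], {"a": "AAAA", "b": "TTTTT"})


class TestExtractUmi:
    def test_eight_bp_scheme_trims_prefix(self):
        read = _read("ACGTACGT" + "G" * 142)
        umi, trimmed = z.extract_umi(read, UmiScheme(umi_len=8))
        assert umi == "ACGTACGT"
        assert len(trimmed.seq1) == 142 and len(trimmed.qual1) == 142

    def test_barcode_then_umi_layout(self):
        read = _read("AAAACCCC" + "ACGTACGT" + "G" * 20)
        umi, trimmed = z.extract_umi(read, UmiScheme(umi_len=8, barcode_len=8))
        assert umi == "ACGTACGT" and trimmed.seq1 == "G" * 20

    def test_too_short_read_rejected(self):
        with pytest.raises(ReadTooShortError):
            z.extract_umi(_read("ACGTAC"), UmiScheme(umi_len=8))

    def test_simulator_round_trip_recovers_umi(self, lqts, rng):
        """Every error-free simulated read yields back its generating UMI."""
        params = z.SimulationParams(seq_error_rate=0.0, read_depth=200, seed=2)
        spectrum = z.default_spectrum(lqts, params)
        cells = {"WT": 10, spectrum.alleles[1].key: 11}
        reads, truth = z.generate_reads(
            cells, lqts, params, "s", "ACACACAC", spectrum, rng
        )
        scheme = UmiScheme(umi_len=8, barcode_len=8)
        truth_umis = {t.umi for t in truth}
        for read in reads:
            umi, _ = z.extract_umi(read, scheme)
            assert umi in truth_umis


class TestMergePairs:
    # aperiodic 120-bp insert so the true overlap is unambiguous
    AMPLICON = "".join(
        np.random.default_rng(77).choice(list("ACGT"), 120)
    )

    def test_error_free_pair_reconstructs_amplicon(self):
        r1 = self.AMPLICON[:80]
        r2 = revcomp(self.AMPLICON)[:80]
        merged = z.merge_pairs(r1, "I" * 80, r2, "I" * 80)
        assert merged == self.AMPLICON

    def test_disjoint_sequences_fail(self):
        assert z.merge_pairs("A" * 30, "I" * 30, "C" * 30, "I" * 30) is None

    def test_conflict_resolved_by_quality_then_tie_to_n(self):
        r1 = self.AMPLICON[:80]
        r2_seq = list(revcomp(self.AMPLICON)[:80])
        # corrupt an overlap base on mate 2: rc index 59 is amplicon position
        # 60, covered by both mates (overlap spans positions 40..79)
        r2_seq[59] = "A" if r2_seq[59] != "A" else "C"
        r2 = "".join(r2_seq)
        hi, lo = "I" * 80, "!" * 80
        merged_hi1 = z.merge_pairs(r1, hi, r2, lo)
        assert merged_hi1 == self.AMPLICON  # mate 1 wins on quality
        merged_tie = z.merge_pairs(r1, hi, r2, hi)
        assert merged_tie.count("N") == 1 and merged_tie != self.AMPLICON


class TestUmiConsensus:
    def test_unanimous_and_majority(self):
        assert umi_consensus("u", ["AAAT", "AAAT", "AAAT"]).sequence == "AAAT"
        assert umi_consensus("u", ["AAAT", "AAAT", "AACT"]).sequence == "AAAT"

    def test_two_way_tie_becomes_n(self):
        cons = umi_consensus("u", ["AAAT", "AACT"])
        assert cons.sequence == "AANT"
        assert cons.family_size == 2

    def test_singleton_passthrough(self):
        cons = umi_consensus("u", ["ACGTT"])
        assert cons.sequence == "ACGTT" and cons.family_size == 1

    def test_length_discordant_family_projected_onto_longest(self):
        base = "ACGGTTACGATCCGGATTACCGGA"
        short = base[:10] + base[11:]  # one deletion
        cons = umi_consensus("u", [base, base, short])
        assert cons.sequence == base

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            umi_consensus("u", [])

    def test_consensus_suppresses_sequencing_error(self, rng):
        """Family-of-5 majority vote pushes 1% per-base error below 0.1%."""
        true = "ACGGTTACGATCCGGATTACCGGAAGTCCGAT" * 4  # 128 bp
        bases = np.array(list("ACGT"))
        n_fam, err_in = 400, 0.01
        wrong = total = 0
        for _ in range(n_fam):
            members = []
            for _ in range(5):
                arr = np.array(list(true))
                hits = rng.random(arr.size) < err_in
                arr[hits] = bases[rng.integers(0, 4, hits.sum())]
                members.append("".join(arr))
            cons = umi_consensus("u", members).sequence
            wrong += sum(a != b for a, b in zip(cons, true))
            total += len(true)
        assert wrong / total < 0.001


def _brute_force_affine(seq, ref, match=1.0, mismatch=-2.0, open_=-5.0, ext=-1.0):
    """Gotoh affine-gap global alignment score, independent O(nm) oracle."""
    n, m = len(ref), len(seq)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in query (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in ref (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == seq[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignGlobal:
    def test_identity_alignment_scores_length(self):
        ref = _as_plain_ref("ACGTTGCAGGTCCATG")
        aln = z.align_global("ACGTTGCAGGTCCATG", ref)
        assert aln.score == 16
        assert not aln.indels
        assert all(c == b for c, b in zip(aln.cols, ref.sequence))

    def test_homopolymer_deletion_lands_leftmost(self):
        ref_seq = "ACGTCAAAAGTCCATGGATC"
        read = "ACGTCAAAGTCCATGGATC"  # one A missing from the run at 5-8
        aln = z.align_global(read, _as_plain_ref(ref_seq))
        assert len(aln.indels) == 1
        d = aln.indels[0]
        assert (d.start, d.deleted_len, d.inserted_seq) == (5, 1, "")
        assert aln.score == _brute_force_affine(read, ref_seq)

    def test_single_substitution_is_one_mismatch_column(self):
        ref_seq = "ACGTCATTGGTCCATGGATC"
        read = ref_seq[:7] + "C" + ref_seq[8:]
        aln = z.align_global(read, _as_plain_ref(ref_seq))
        assert not aln.indels
        assert aln.mismatch_positions(ref_seq) == [7]

    @pytest.mark.parametrize("trial", range(30))
    def test_score_matches_exhaustive_dp_oracle(self, trial):
        """Optimal score equals an independent Gotoh DP on short strings."""
        rng = np.random.default_rng(100 + trial)
        ref_seq = "".join(rng.choice(list("ACGT"), rng.integers(12, 30)))
        read = list(ref_seq)
        # random small edits
        for _ in range(rng.integers(0, 3)):
            op = rng.integers(3)
            pos = int(rng.integers(1, len(read)))
            if op == 0:
                read[pos] = "ACGT"[rng.integers(4)]
            elif op == 1 and len(read) > 5:
                del read[pos]
            else:
                read.insert(pos, "ACGT"[rng.integers(4)])
        read = "".join(read)
        aln = z.align_global(read, _as_plain_ref(ref_seq))
        assert aln.score == pytest.approx(_brute_force_affine(read, ref_seq))


class TestClassifyRead:
    def test_error_free_wildtype(self, lqts):
        call = z.classify_read(z.align_global(lqts.sequence, lqts), lqts)
        assert call.category is AlleleKind.WT and call.allele_key == "WT"

    def test_full_hdr_amplicon(self, lqts):
        allele = AlleleSpec(kind=AlleleKind.HDR, incorporation=(True,) * 4)
        seq = z.build_allele_sequence(lqts, allele)
        call = z.classify_read(z.align_global(seq, lqts), lqts)
        assert call.category is AlleleKind.HDR
        assert call.incorporation == (True, True, True, True)
        assert call.allele_key == "HDR[1111]"

    def test_cut_spanning_deletion_round_trips(self, lqts):
        d = canonical_indel(lqts.sequence, lqts.cut_index - 1, deleted_len=3)
        allele = AlleleSpec(kind=AlleleKind.INDEL, indel=d)
        seq = z.build_allele_sequence(lqts, allele)
        call = z.classify_read(z.align_global(seq, lqts), lqts)
        assert call.category is AlleleKind.INDEL
        assert call.allele_key == allele.key

    def test_partial_tract_without_ki_is_hdr_with_ki_false(self, lqts):
        allele = AlleleSpec(
            kind=AlleleKind.HDR, incorporation=(True, False, False, False)
        )
        seq = z.build_allele_sequence(lqts, allele)
        call = z.classify_read(z.align_global(seq, lqts), lqts)
        assert call.category is AlleleKind.HDR
        assert call.incorporation[lqts.ki_marker_index] is False

    def test_indel_outside_window_ignored(self, lqts):
        d = canonical_indel(lqts.sequence, 30, deleted_len=2)  # near fwd primer
        seq = z.build_allele_sequence(lqts, AlleleSpec(kind=AlleleKind.INDEL, indel=d))
        call = z.classify_read(z.align_global(seq, lqts), lqts, window=20)
        assert call.category is not AlleleKind.INDEL

    def test_many_stray_mismatches_become_other_sub(self, lqts):
        chars = list(lqts.sequence)
        for pos in (60, 75, 90):
            chars[pos] = "A" if chars[pos] != "A" else "C"
        call = z.classify_read(z.align_global("".join(chars), lqts), lqts)
        assert call.category is AlleleKind.OTHER_SUB

    @pytest.mark.parametrize("locus_name", ["toyLQTS", "toyBrS"])
    def test_oracle_equivalence_on_random_alleles(self, locus_name):
        """classify∘align recovers the generating allele key, error-free."""
        ref = z.load_locus(locus_name)
        rng = np.random.default_rng(7)
        for _ in range(150):
            allele = random_allele(ref, rng)
            seq = z.build_allele_sequence(ref, allele)
            call = z.classify_read(z.align_global(seq, ref), ref)
            assert call.allele_key == allele.key
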