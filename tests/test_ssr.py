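"""Microsatellite detection: MISA threshold semantics, canonical motif
classes, compound merging, and equivalence with a naive scanning oracle."""

import numpy as np
import pytest

import corekit as ck
from corekit.ssr import _find_simple_runs

# deterministic non-repetitive flanks (no 1-6 bp tandem reaches a threshold)
LEFT = "GATCCTAGCAGTCAGGCTTG"
RIGHT = "CTGAACGTCGTACTGGATCC"

NO_MERGE = -(10**9)  # max_interruption that disables compound merging


class TestThresholds:
    def test_mono_run_at_threshold(self):
        recs = ck.find_ssrs("A" * 10)
        assert len(recs) == 1
        r = recs[0]
        assert (r.motif, r.repeat_count, r.start, r.end, r.kind) == ("A", 10, 1, 10, "simple")

    def test_mono_run_below_threshold(self):
        assert ck.find_ssrs("A" * 9) == []

    def test_di_run_at_threshold_in_flanks(self):
        seq = LEFT + "AC" * 6 + RIGHT
        recs = ck.find_ssrs(seq)
        assert len(recs) == 1
        r = recs[0]
        assert r.motif == "AC" and r.repeat_count == 6
        assert r.start == len(LEFT) + 1 and r.end == len(LEFT) + 12

    def test_below_threshold_insert_does_not_change_output(self):
        base = LEFT + "A" * 10 + RIGHT
        # (AG)5 stays below the dinucleotide threshold; the spacer keeps the
        # junctions from extending any run
        with_insert = LEFT + "AG" * 5 + "CTGAC" + "A" * 10 + RIGHT
        base_recs = [(r.motif, r.repeat_count) for r in ck.find_ssrs(base)]
        ins_recs = [(r.motif, r.repeat_count) for r in ck.find_ssrs(with_insert)]
        assert base_recs == ins_recs == [("A", 10)]

    def test_perfect_run_covers_whole_sequence(self):
        seq = "AGT" * 7
        (r,) = ck.find_ssrs(seq)
        assert r.repeat_count * len(r.motif) == len(seq)


class TestCompound:
    def test_two_runs_merge_when_gap_within_interruption(self):
        seq = "AT" * 6 + "GG" + "GA" * 7
        (r,) = ck.find_ssrs(seq, max_interruption=2)
        assert r.kind == "compound"
        assert r.start == 1 and r.end == len(seq)
        assert r.member_motifs == (("AT", 6), ("GA", 7))

    def test_no_merge_when_gap_exceeds_interruption(self):
        seq = "AT" * 6 + "GG" + "GA" * 7
        recs = ck.find_ssrs(seq, max_interruption=1)
        assert [r.kind for r in recs] == ["simple", "simple"]
        assert [r.motif for r in recs] == ["AT", "GA"]

    def test_records_sorted_and_non_overlapping(self):
        seq = LEFT + "A" * 12 + LEFT + "CT" * 8 + RIGHT + "TAG" * 6 + RIGHT
        recs = ck.find_ssrs(seq, max_interruption=0)
        starts = [r.start for r in recs]
        assert starts == sorted(starts)
        for a, b in zip(recs, recs[1:]):
            assert b.start > a.end


class TestAmbiguityAndErrors:
    def test_single_n_breaks_a_run(self):
        assert ck.find_ssrs("A" * 5 + "N" + "A" * 5) == []
        recs = ck.find_ssrs("A" * 10 + "N" + "A" * 10, max_interruption=NO_MERGE)
        assert [(r.motif, r.repeat_count) for r in recs] == [("A", 10), ("A", 10)]

    def test_n_runs_are_never_ssrs(self):
        assert ck.find_ssrs("N" * 30) == []

    def test_non_iupac_character_is_error(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            ck.find_ssrs("ACGTX" * 5)


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("T", "A"),          # reverse complement class A/T
            ("CT", "AG"),        # AG/CT class
            ("ATAT", "AT"),      # period reduction
            ("GA", "AG"),        # rotation
            ("AAG", "AAG"),
            ("CTT", "AAG"),      # revcomp of AAG
            ("ACGACG", "ACG"),
        ],
    )
    def test_examples(self, motif, expected):
        assert ck.canonical_motif(motif) == expected

    def test_rotation_and_strand_invariance(self):
        rng = np.random.default_rng(5)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            k = int(rng.integers(1, 7))
            motif = "".join(rng.choice(list("ACGT"), k))
            canon = ck.canonical_motif(motif)
            rot = motif[1:] + motif[:1]
            rc = motif.translate(comp)[::-1]
            assert ck.canonical_motif(rot) == canon
            assert ck.canonical_motif(rc) == canon


class TestSummary:
    def test_counts_partition(self):
        seq = "AT" * 6 + "GG" + "GA" * 7
        recs = ck.find_ssrs(seq, sequence_id="u1", max_interruption=2)
        recs += ck.find_ssrs("A" * 10, sequence_id="u2")
        s = ck.summarize_ssrs(recs, n_sequences=4)
        assert s.n_loci == s.n_simple + s.n_compound == 2
        assert s.n_sequences_with_ssr == 2 and s.n_sequences_multi_ssr == 0
        assert s.frequency_percent == 50.0

    def test_empty_records(self):
        s = ck.summarize_ssrs([], n_sequences=3)
        assert s.n_loci == 0 and s.frequency_percent == 0.0

    def test_zero_sequences_is_error(self):
        with pytest.raises(ValueError):
            ck.summarize_ssrs([], n_sequences=0)


def naive_runs(seq, thresholds):
    """Independent O(n*k) scan: every maximal primitive perfect run.

    A run is maximal when the self-similarity seq[i] == seq[i+k] does not
    extend one character to the left (one run per self-similar region, the
    MISA consume rule).
    """
    out = set()
    n = len(seq)
    for k, thr in enumerate(thresholds, start=1):
        for s0 in range(n - k + 1):
            motif = seq[s0 : s0 + k]
            if len(motif) < k or len(set(motif) - set("ACGT")):
                continue
            # primitive motif only
            if any(k % p == 0 and motif == motif[:p] * (k // p) for p in range(1, k)):
                continue
            c = 1
            while seq[s0 + c * k : s0 + (c + 1) * k] == motif:
                c += 1
            if c < thr:
                continue
            if s0 > 0 and s0 - 1 + k < n and seq[s0 - 1] == seq[s0 - 1 + k] != "N":
                continue  # the self-similar region starts earlier
            out.add((s0 + 1, s0 + c * k, motif, c))
    return out


def test_matches_naive_oracle_on_random_sequences():
    rng = np.random.default_rng(42)
    thresholds = (10, 6, 5, 5, 5, 5)
    motifs = ["A", "AG", "AT", "AAG", "ACGT", "AATGC", "ACGTAC"]
    for rep in range(30):
        parts = []
        for _ in range(6):
            parts.append("".join(rng.choice(list("ACGTN"), int(rng.integers(20, 80)),
                                            p=[0.24, 0.24, 0.24, 0.24, 0.04])))
            if rng.random() < 0.8:
                m = motifs[int(rng.integers(len(motifs)))]
                parts.append(m * int(rng.integers(3, 14)))
        seq = "".join(parts)
        got = {
            (r.start, r.end, r.motif, r.repeat_count)
            for r in ck.find_ssrs(seq, max_interruption=NO_MERGE)
        }
        assert got == naive_runs(seq, thresholds), f"mismatch on replicate {rep}"


def test_fasta_scan_and_determinism(tmp_path):
    fa = tmp_path / "u.fa"
    fa.write_text(f">u1\n{'A' * 12}\n>u2\n{LEFT}{'CT' * 8}{RIGHT}\n>u3\n{LEFT}\n")
    recs1, n1 = ck.find_ssrs_fasta(fa)
    recs2, n2 = ck.find_ssrs_fasta(fa)
    assert n1 == n2 == 3
    assert recs1 == recs2
    assert [(r.sequence_id, r.motif) for r in recs1] == [("u1", "A"), ("u2", "CT")]
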