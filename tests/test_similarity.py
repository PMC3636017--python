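"""Unit and property tests for the k-mer-seeded banded aligner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from interphyte.similarity import (
    MappingPolicy,
    SeedIndex,
    _banded_dp,
    _to_array,
    align_identity,
    best_hit,
    map_reads,
    revcomp,
)

from oracles import full_dp

DNA = st.text(alphabet="ACGT", min_size=8, max_size=60)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate_seq(rng, seq, d):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < d:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestSeedIndex:
    def test_posting_count_is_length_minus_k_plus_one(self):
        idx = SeedIndex({"r": "ACGTACGT"}, k=4)
        assert len(idx) == 5

    def test_k_below_four_rejected(self):
        with pytest.raises(ValueError):
            SeedIndex({"r": "ACGTACGT"}, k=3)

    def test_k_longer_than_shortest_reference_rejected(self):
        with pytest.raises(ValueError):
            SeedIndex({"r": "ACGTA"}, k=6)

    def test_postings_match_enumeration_oracle(self, rng):
        refs = {f"r{i}": random_seq(rng, int(rng.integers(20, 60))) for i in range(5)}
        k = 5
        idx = SeedIndex(refs, k)
        expected = {}
        for rid, seq in refs.items():
            for off in range(len(seq) - k + 1):
                expected.setdefault(seq[off : off + k], []).append((rid, off))
        assert {km: sorted(v) for km, v in idx.postings.items()} == {
            km: sorted(v) for km, v in expected.items()
        }

    def test_every_reference_self_hits_at_full_identity(self, rng):
        refs = {f"r{i}": random_seq(rng, 120) for i in range(6)}
        idx = SeedIndex(refs, 11)
        for rid, seq in refs.items():
            hit = best_hit(seq, idx, MappingPolicy())
            assert hit is not None
            assert hit.percent_identity == 100.0


class TestAlignIdentity:
    def test_identical_sequences(self):
        h = align_identity("A" * 100, "A" * 100)
        assert h.percent_identity == 100.0
        assert h.alignment_length == 100

    def test_single_mismatch_gives_99_percent(self):
        a = "ACGT" * 25
        b = a[:50] + ("G" if a[50] != "G" else "C") + a[51:]
        h = align_identity(a, b)
        assert h.percent_identity == pytest.approx(99.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_identity("", "ACGT")

    @pytest.mark.parametrize("mode", ["global", "glocal", "local"])
    def test_matches_full_dp_oracle(self, mode, rng):
        """Banded result equals the unbanded optimum when divergence fits the band."""
        pol = MappingPolicy()
        for _ in range(60):
            n = int(rng.integers(15, 70))
            q = random_seq(rng, n)
            s = mutate_seq(rng, q, 0.08)
            if rng.random() < 0.4 and len(s) > 20:
                cut = int(rng.integers(0, len(s)))
                s = s[:cut] + s[cut + 1 :]
            res = _banded_dp(_to_array(q), _to_array(s), pol, mode)
            assert (res.score, res.matches, res.columns) == full_dp(q, s, pol, mode)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=DNA, b=DNA)
    def test_identity_bounds_and_symmetry(self, a, b):
        h1 = align_identity(a, b)
        h2 = align_identity(b, a)
        assert 0 <= h1.percent_identity <= 100
        assert h1.alignment_length >= 1
        assert h1.score == h2.score
        assert h1.percent_identity == pytest.approx(h2.percent_identity)


class TestBestHit:
    def test_exact_query_recovers_reference(self, rng):
        refs = {f"r{i}": random_seq(rng, 150) for i in range(8)}
        idx = SeedIndex(refs, 11)
        hit = best_hit(refs["r3"], idx)
        assert hit.subject_id == "r3"
        assert hit.percent_identity == 100.0

    def test_equal_score_ties_break_to_smallest_subject_id(self):
        seq = "ACGTTGCAACGTACGTGGCCATAT" * 4
        refs = {"b_ref": seq, "a_ref": seq}
        idx = SeedIndex(refs, 11)
        hit = best_hit(seq, idx)
        assert hit.subject_id == "a_ref"

    def test_reverse_complement_query_found_on_minus_strand(self, rng):
        refs = {f"r{i}": random_seq(rng, 200) for i in range(4)}
        idx = SeedIndex(refs, 11)
        hit = best_hit(revcomp(refs["r2"]), idx)
        assert hit.subject_id == "r2"
        assert hit.strand == "-"
        assert hit.percent_identity == 100.0

    def test_recovers_true_source_for_error_free_queries(self, rng):
        """Error-free full-length queries find their source transcript."""
        refs = {f"r{i:03d}": random_seq(rng, int(rng.integers(150, 400))) for i in range(40)}
        idx = SeedIndex(refs, 11)
        correct = sum(
            1 for rid, seq in refs.items() if best_hit(seq, idx).subject_id == rid
        )
        assert correct >= 0.99 * len(refs)

    def test_insignificant_hit_returns_none(self, rng):
        refs = {"r0": random_seq(rng, 300)}
        idx = SeedIndex(refs, 11)
        assert best_hit(random_seq(rng, 60), idx, MappingPolicy(min_score=40)) is None

    def test_repeated_runs_identical(self, rng):
        refs = {f"r{i}": random_seq(rng, 200) for i in range(6)}
        idx = SeedIndex(refs, 11)
        q = mutate_seq(rng, refs["r1"], 0.05)
        h1 = best_hit(q, idx)
        h2 = best_hit(q, SeedIndex(refs, 11))
        assert (h1.subject_id, h1.score, h1.percent_identity) == (
            h2.subject_id,
            h2.score,
            h2.percent_identity,
        )


class TestMapReads:
    def test_error_free_reads_map_to_their_transcript(self, rng):
        refs = {"t1": random_seq(rng, 500), "t2": random_seq(rng, 500)}
        reads = {
            f"rd{i}": refs["t1"][p : p + 80]
            for i, p in enumerate(rng.integers(0, 420, size=20))
        }
        asn, counts = map_reads(reads, refs)
        assert counts["t1"] == 20
        assert counts["t2"] == 0
        assert all(h.subject_id == "t1" for h in asn.values())

    def test_read_with_40_percent_alignable_is_unmapped(self, rng):
        """The length-fraction 0.5 rule rejects a read only 40 % alignable."""
        ref = {"t": random_seq(rng, 400)}
        # 40 bases from the reference + 60 unrelated bases
        read = ref["t"][100:140] + random_seq(rng, 60)
        asn, counts = map_reads({"rd": read}, ref)
        assert asn["rd"] is None
        assert counts["t"] == 0

    def test_counts_match_exhaustive_all_pairs_aligner(self, rng):
        """Assignments equal a brute-force every-read-vs-every-transcript scan."""
        refs = {f"t{i}": random_seq(rng, 300) for i in range(5)}
        pol = MappingPolicy(min_score=15)
        reads = {}
        for i in range(30):
            src = f"t{int(rng.integers(0, 5))}"
            p = int(rng.integers(0, 220))
            reads[f"rd{i:02d}"] = mutate_seq(rng, refs[src][p : p + 80], 0.02)
        asn, counts = map_reads(reads, refs, pol)
        for rid, seq in reads.items():
            best = None
            for tid in sorted(refs):
                h = align_identity(seq, refs[tid], pol, mode="local",
                                   subject_id=tid, query_id=rid)
                key = (-h.score, -h.percent_identity, -h.alignment_length, tid)
                if h.score >= pol.min_score and (best is None or key < best[0]):
                    best = (key, h)
            expected = None
            if best is not None:
                h = best[1]
                if (
                    h.query_span / len(seq) >= pol.length_fraction
                    and h.percent_identity / 100 >= pol.min_similarity
                ):
                    expected = h.subject_id
            got = asn[rid].subject_id if asn[rid] else None
            assert got == expected, rid
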