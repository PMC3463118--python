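"""Index construction, persistence, and lookup."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splitmap.index import (
    AMBIGUOUS,
    Index,
    IndexCorruptionError,
    IndexFormatError,
    IndexParams,
    build_index,
    encode_kmer,
    read_index,
    write_index,
)

from _oracles import naive_kmer_index
from conftest import random_dna


class TestEncodeKmer:
    @pytest.mark.parametrize(
        "kmer,expected",
        [
            ("AAAA", 0),
            ("ACGT", 27),  # 0*64 + 1*16 + 2*4 + 3
            ("acgt", 27),  # case-insensitive
            ("TTTT", 255),
            ("ACNT", AMBIGUOUS),
        ],
    )
    def test_examples(self, kmer, expected):
        assert encode_kmer(kmer, 4) == expected

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            encode_kmer("ACG", 4)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=15))
    def test_roundtrip_against_base4_arithmetic(self, kmer):
        key = encode_kmer(kmer)
        digits = []
        v = key
        for _ in range(len(kmer)):
            digits.append("ACGT"[v & 3])
            v >>= 2
        assert "".join(reversed(digits)) == kmer


class TestBuildIndex:
    def test_eight_base_example(self, tiny_index):
        assert list(tiny_index.lookup(encode_kmer("ACGT"))) == [0, 4]
        assert list(tiny_index.lookup(encode_kmer("CGTA"))) == [1]
        assert len(tiny_index.roa) == 5

    def test_maxhits_exclusion(self):
        idx = build_index({"r": "ACGTACGT"}, IndexParams(k=4, skip=1, max_hits=1))
        assert list(idx.lookup(encode_kmer("ACGT"))) == []
        assert list(idx.lookup(encode_kmer("CGTA"))) == [1]

    def test_maxhits_sampling(self):
        idx = build_index(
            {"r": "ACGTACGT"}, IndexParams(k=4, skip=1, max_hits=1, sampling=True, rng_seed=9)
        )
        hits = list(idx.lookup(encode_kmer("ACGT")))
        assert len(hits) == 1 and hits[0] in (0, 4)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            build_index({}, IndexParams(k=4, skip=1))
        with pytest.raises(ValueError):
            build_index({"r": ""}, IndexParams(k=4, skip=1))

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            IndexParams(k=16)
        with pytest.raises(ValueError):
            IndexParams(k=8, skip=9)
        with pytest.raises(ValueError):
            IndexParams(max_hits=0)

    def test_ambiguous_bases_never_indexed(self):
        idx = build_index({"r": "ACGTNACGT"}, IndexParams(k=4, skip=1, max_hits=10))
        # windows overlapping the N are absent; ACGT occurs at 0 and 5
        assert list(idx.lookup(encode_kmer("ACGT"))) == [0, 5]
        # only offsets 0 and 5 give N-free windows
        assert len(idx.roa) == 2

    def test_seeds_never_span_sequence_boundary(self):
        idx = build_index([("a", "ACGTAC"), ("b", "GTACGT")], IndexParams(k=4, skip=1, max_hits=50))
        # the boundary-crossing window "ACGT" at concat offset 4..8 must not exist;
        # ACGT occurs within a at 0 and within b at 8 (concat offset 6+2)
        assert list(idx.lookup(encode_kmer("ACGT"))) == [0, 8]

    def test_completeness_against_naive_scan(self, rng):
        """With max_hits=inf and skip=1 every exact k-mer occurrence is
        retrievable (checked against a plain dict scan of the sequence)."""
        seq = random_dna(rng, 10_000)
        k = 8
        idx = build_index({"c": seq}, IndexParams(k=k, skip=1, max_hits=10**9))
        naive = naive_kmer_index(seq, k)
        assert len(idx.keys) == len(naive)
        for kmer, positions in naive.items():
            assert list(idx.lookup(encode_kmer(kmer))) == positions

    def test_skip_grid(self, rng):
        seq = random_dna(rng, 3_000)
        k, skip = 8, 3
        idx = build_index({"c": seq}, IndexParams(k=k, skip=skip, max_hits=10**9))
        naive = naive_kmer_index(seq, k, skip=skip)
        total = sum(len(v) for v in naive.values())
        assert len(idx.roa) == total
        offs = np.sort(idx.roa)
        assert np.all(offs % skip == 0)

    def test_sampling_is_ordered_subset(self, rng):
        seq = "".join(rng.choice(["AC", "AG"], 400))  # very repetitive 2-mers
        k, mh = 4, 5
        full = build_index({"r": seq}, IndexParams(k=k, skip=1, max_hits=10**9))
        samp = build_index(
            {"r": seq}, IndexParams(k=k, skip=1, max_hits=mh, sampling=True, rng_seed=3)
        )
        for key in full.keys:
            f = list(full.lookup(int(key)))
            s = list(samp.lookup(int(key)))
            if len(f) > mh:
                assert len(s) == mh
            else:
                assert s == f
            assert set(s) <= set(f)
            assert s == sorted(s)

    def test_roa_partition_invariants(self, rng):
        seq = random_dna(rng, 5_000)
        idx = build_index({"c": seq}, IndexParams(k=9, skip=1, max_hits=650))
        assert len(idx.key_starts) == len(idx.keys) + 1
        assert idx.key_starts[0] == 0 and idx.key_starts[-1] == len(idx.roa)
        assert np.all(np.diff(idx.key_starts) >= 1)
        for i in range(0, len(idx.keys), 97):
            block = idx.roa[idx.key_starts[i] : idx.key_starts[i + 1]]
            assert np.all(np.diff(block) > 0)
            assert block.max() <= idx.total_length - idx.params.k


class TestPersistence:
    def test_round_trip_identity(self, tiny_index, tmp_path):
        p = tmp_path / "x.ssix"
        write_index(tiny_index, p)
        loaded = read_index(p)
        assert loaded == tiny_index

    def test_round_trip_preserves_params(self, tmp_path, rng):
        seq = random_dna(rng, 2_000)
        idx = build_index({"c": seq}, IndexParams(k=11, skip=2, max_hits=99, sampling=True, rng_seed=5))
        p = tmp_path / "y.ssix"
        write_index(idx, p)
        loaded = read_index(p)
        assert loaded.params.k == 11
        assert loaded.params == idx.params
        assert loaded == idx

    def test_round_trip_with_ambiguous_bases(self, tmp_path):
        idx = build_index({"r": "ACGTNNACGTAC"}, IndexParams(k=4, skip=1, max_hits=10))
        p = tmp_path / "n.ssix"
        write_index(idx, p)
        assert read_index(p) == idx

    def test_bad_magic_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.ssix"
        p.write_bytes(b"NOPE" + b"\0" * 100)
        with pytest.raises(IndexFormatError):
            read_index(p)

    def test_truncated_file_raises_corruption_error(self, tiny_index, tmp_path):
        p = tmp_path / "t.ssix"
        write_index(tiny_index, p)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) - 9])
        with pytest.raises(IndexCorruptionError):
            read_index(p)

    def test_build_determinism_byte_identical(self, tmp_path, rng):
        seq = random_dna(rng, 4_000)
        params = IndexParams(k=8, skip=1, max_hits=3, sampling=True, rng_seed=77)
        p1, p2 = tmp_path / "a.ssix", tmp_path / "b.ssix"
        write_index(build_index({"c": seq}, params), p1)
        write_index(build_index({"c": seq}, params), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestLookup:
    def test_absent_kmer_empty(self, tiny_index):
        assert list(tiny_index.lookup(encode_kmer("AAAA"))) == []

    def test_ambiguous_lookup_raises(self, tiny_index):
        with pytest.raises(ValueError):
            tiny_index.lookup(AMBIGUOUS)

    def test_lookup_on_fully_excluded_table(self):
        # every k-mer of a pure repeat exceeds max_hits: the key table is
        # empty and lookups (single and batched) return nothing
        idx = build_index({"r": "ACGT" * 1000}, IndexParams(k=4, skip=1, max_hits=5))
        assert len(idx.keys) == 0
        assert list(idx.lookup(encode_kmer("ACGT"))) == []
        starts, counts = idx.lookup_batch(np.array([0, 27, 255]))
        assert counts.sum() == 0

    def test_coordinate_helpers(self):
        idx = build_index([("a", "ACGTAC"), ("b", "GGTACGTT")], IndexParams(k=4, skip=1))
        assert idx.seq_index_of(0) == 0
        assert idx.seq_index_of(5) == 0
        assert idx.seq_index_of(6) == 1
        assert idx.to_local(8) == ("b", 2)
        assert idx.seq_bounds(1) == (6, 14)
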