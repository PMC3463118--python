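"""SV/CGR simulation, read sampling, and breakpoint verification."""
import numpy as np
import pytest

from splitmap._util import revcomp_str
from splitmap.sv_sim import (
    BreakpointTruth,
    CGRSpec,
    ReadSimParams,
    RepeatFamilySpec,
    SVEvent,
    apply_cgr,
    apply_sv_events,
    impress_errors,
    make_synthetic_reference,
    read_truth,
    sample_reads,
    simulate_sv_events,
    verify_breakpoints,
    write_truth,
)


class TestSyntheticReference:
    def test_reproducible_from_seed(self):
        a = make_synthetic_reference(2, [5_000, 3_000], rng_seed=4)
        b = make_synthetic_reference(2, [5_000, 3_000], rng_seed=4)
        assert a.sequences == b.sequences

    def test_requested_lengths(self):
        ref = make_synthetic_reference(2, [5_000, 3_000], rng_seed=4)
        assert len(ref.sequences["chr1"]) == 5_000
        assert len(ref.sequences["chr2"]) == 3_000

    def test_planted_family_identity_band(self):
        """Pairwise identity of planted repeats sits in the configured band
        (checked by direct global alignment of the copies)."""
        from splitmap.chaining import AGSParams
        from splitmap.dp_align import banded_affine_fill

        fam = RepeatFamilySpec(n_copies=6, length=200, divergence=0.03)
        ref = make_synthetic_reference(1, [100_000], rng_seed=9, repeat_family=fam)
        assert len(ref.repeat_loci) == 6
        copies = [
            ref.sequences[name][s : s + ln] for name, s, ln in ref.repeat_loci
        ]
        ags = AGSParams(match=1, mismatch=0, gap_open=0, gap_extend=0)
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                matches, _ = banded_affine_fill(copies[i], copies[j], ags, 200)
                ident = matches / 200
                # each copy diverges ~3% from the consensus; pairwise ~94%
                assert 0.85 <= ident <= 1.0


class TestApplySVEvents:
    REF = None

    @pytest.fixture()
    def reference(self):
        return make_synthetic_reference(2, [30_000, 20_000], rng_seed=17).sequences

    def test_deletion_contig_arithmetic(self, reference):
        ev = SVEvent("deletion", "chr1", 5_000, 300)
        contigs, truth = apply_sv_events(reference, [ev], flank=500)
        (name, seq), = contigs.items()
        assert len(seq) == 1000
        assert truth[0].contig_offset == 500
        assert truth[0].left == ("chr1", 5_000, "+")
        assert truth[0].right == ("chr1", 5_300, "+")

    def test_inversion_contig_arithmetic(self, reference):
        ev = SVEvent("inversion", "chr1", 5_000, 300)
        contigs, truth = apply_sv_events(reference, [ev], flank=500)
        (name, seq), = contigs.items()
        assert len(seq) == 1300
        assert [t.contig_offset for t in truth] == [500, 800]
        assert truth[0].right == ("chr1", 5_300, "-")
        # the inverted middle is the reverse complement of the source
        assert seq[500:800] == revcomp_str(reference["chr1"][5_000:5_300])

    def test_tandem_duplication_small(self, reference):
        ev = SVEvent("tandem_duplication", "chr1", 5_000, 200)
        contigs, truth = apply_sv_events(reference, [ev], flank=500)
        (name, seq), = contigs.items()
        assert len(seq) == 2 * 500 + 2 * 200
        assert truth[0].left == ("chr1", 5_200, "+")
        assert truth[0].right == ("chr1", 5_000, "+")

    def test_insertion_two_reference_sides(self, reference):
        ev = SVEvent("insertion", "chr1", 5_000, 300, donor_ref="chr2", donor_start=7_000)
        contigs, truth = apply_sv_events(reference, [ev], flank=500)
        assert len(truth) == 2
        assert truth[0].left[0] == "chr1" and truth[0].right[0] == "chr2"
        assert truth[1].left == ("chr2", 7_300, "+")

    def test_large_event_left_breakpoint_only(self, reference):
        ev = SVEvent("inversion", "chr1", 5_000, 5_000)
        contigs, truth = apply_sv_events(reference, [ev], flank=500)
        (name, seq), = contigs.items()
        assert len(seq) == 1000 and len(truth) == 1

    def test_overlapping_events_rejected(self, reference):
        evs = [
            SVEvent("deletion", "chr1", 5_000, 300),
            SVEvent("inversion", "chr1", 5_100, 300),
        ]
        with pytest.raises(ValueError):
            apply_sv_events(reference, evs, flank=500)

    def test_simulated_events_nonoverlapping_and_sized(self, reference):
        events = simulate_sv_events(reference, n_per_type=5, length_range=(100, 2_000), rng_seed=3)
        assert len(events) == 20
        for e in events:
            if e.type != "insertion":
                assert 100 <= e.length <= 2_000
        # applying must not raise (non-overlap invariant)
        apply_sv_events(reference, events, flank=500)


class TestCGR:
    @pytest.fixture()
    def reference(self):
        return make_synthetic_reference(1, [120_000], rng_seed=23).sequences

    def test_length_conservation(self, reference):
        spec = CGRSpec(region_length=20_000, rng_seed=5)
        contigs, truth = apply_cgr(reference, spec)
        (seq,) = contigs.values()
        # contig length == sum of retained fragment lengths; bounded by the
        # region plus duplications minus deletions
        assert 0 < len(seq) < 20_000 * 1.3

    def test_junction_count_matches_adjacency(self, reference):
        spec = CGRSpec(region_length=10_000, rng_seed=6)
        contigs, truth = apply_cgr(reference, spec)
        offsets = [t.contig_offset for t in truth]
        assert offsets == sorted(offsets)
        assert len(set(offsets)) == len(offsets)

    def test_deleted_fraction_within_binomial_bounds(self, reference):
        # statistical check on the deletion fraction via direct simulation
        n, p = 33, 0.30  # ~10 kb / 300 bp mean fragments
        dels = []
        for seed in range(40):
            spec = CGRSpec(region_length=10_000, rng_seed=seed, frac_duplicated=0.0)
            contigs, _ = apply_cgr(reference, spec)
            (seq,) = contigs.values()
            dels.append(1 - len(seq) / 10_000)
        mean = float(np.mean(dels))
        sigma = np.sqrt(p * (1 - p) / n / len(dels))
        assert abs(mean - p) < 6 * sigma + 0.02

    def test_two_locus_spec(self, reference):
        spec = CGRSpec(region_length=20_000, num_loci=2, rng_seed=8)
        contigs, truth = apply_cgr(reference, spec)
        assert truth  # junctions exist

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CGRSpec(frac_deleted=0.7, frac_duplicated=0.5)
        with pytest.raises(ValueError):
            CGRSpec(num_loci=3)


class TestSampleReads:
    def test_read_count(self):
        contigs = {"c": "ACGT" * 500}  # 2000 bp
        reads = sample_reads(contigs, ReadSimParams(read_length=100, coverage=3, error_rate=0, rng_seed=1))
        assert len(reads) == round(3 * 2000 / 100)

    def test_zero_error_reads_are_exact_substrings(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3_000))
        reads = sample_reads({"c": seq}, ReadSimParams(read_length=200, coverage=2, error_rate=0, rng_seed=3))
        for r in reads:
            w = seq[r.start : r.start + 200]
            assert r.sequence == (w if r.strand == "+" else revcomp_str(w))

    def test_substitution_rate_within_binomial_bounds(self):
        rng = np.random.default_rng(4)
        n = 1_000_000
        seq = "A" * n
        out = impress_errors(seq, 0.02, 0.1, rng)
        subs = sum(1 for c in out if c != "A")
        # substitutions ~= err*(1-indel_frac)*n; insertions add non-A too
        # (1/4 of inserted bases are A) -> expected extra ~ 0.02*0.1*0.5*0.75
        exp_sub = 0.02 * 0.9 * n
        sigma = np.sqrt(0.02 * 0.9 * n)
        assert abs(subs - exp_sub) < 6 * sigma + 0.02 * 0.1 * n

    def test_length_change_reflects_indels(self):
        rng = np.random.default_rng(5)
        out = impress_errors("A" * 100_000, 0.04, 1.0, rng)
        # pure indels, ins/del equiprobable: length roughly conserved
        assert abs(len(out) - 100_000) < 1_000

    def test_reproducible(self):
        contigs = {"c": "ACGTACGTAC" * 100}
        p = ReadSimParams(read_length=50, coverage=2, error_rate=0.05, rng_seed=11)
        r1 = sample_reads(contigs, p)
        r2 = sample_reads(contigs, p)
        assert [(a.name, a.sequence) for a in r1] == [(b.name, b.sequence) for b in r2]


class TestTruthIO:
    def test_roundtrip(self, tmp_path):
        truth = [
            BreakpointTruth("c1", 500, ("chr1", 100, "+"), ("chr2", 900, "-")),
            BreakpointTruth("c1", 800, ("chr2", 900, "-"), ("chr1", 400, "+")),
        ]
        p = tmp_path / "t.tsv"
        write_truth(p, truth)
        assert read_truth(p) == truth


def _sam_with_pair(tmp_path, left_end, right_start, right_strand="+"):
    """A SAM file with one query split into two alignments around offset 250."""
    header = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"
    seq = "A" * 500
    if right_strand == "+":
        rec2 = f"c1|0|+|0\t0\tchr1\t{right_start + 1}\t255\t250S250M\t*\t0\t0\t{seq}\t*\tAS:i:250"
    else:
        # minus-strand second piece: reference end at right_start
        rec2 = f"c1|0|+|0\t16\tchr1\t{right_start - 250 + 1}\t255\t250M250S\t*\t0\t0\t{seq}\t*\tAS:i:250"
    text = (
        header
        + f"c1|0|+|0\t0\tchr1\t{left_end - 250 + 1}\t255\t250M250S\t*\t0\t0\t{seq}\t*\tAS:i:250\n"
        + rec2
        + "\n"
    )
    p = tmp_path / "v.sam"
    p.write_text(text)
    return p


class TestVerifyBreakpoints:
    def truth(self, right_pos=40_000, right_strand="+"):
        return [BreakpointTruth("c1", 250, ("chr1", 10_250, "+"), ("chr1", right_pos, right_strand))]

    def test_exact_split_verified(self, tmp_path):
        sam = _sam_with_pair(tmp_path, 10_250, 40_000)
        rep = verify_breakpoints(sam, self.truth())
        assert rep.frac_junctions == 1.0 and rep.frac_queries == 1.0

    def test_off_by_five_verified(self, tmp_path):
        sam = _sam_with_pair(tmp_path, 10_250, 40_005)
        rep = verify_breakpoints(sam, self.truth())
        assert rep.frac_junctions == 1.0

    def test_off_by_six_not_verified(self, tmp_path):
        sam = _sam_with_pair(tmp_path, 10_250, 40_006)
        rep = verify_breakpoints(sam, self.truth())
        assert rep.frac_junctions == 0.0

    def test_strand_must_match(self, tmp_path):
        sam = _sam_with_pair(tmp_path, 10_250, 40_000, right_strand="-")
        assert verify_breakpoints(sam, self.truth()).frac_junctions == 0.0
        # the same pair against inverted truth verifies
        assert (
            verify_breakpoints(sam, self.truth(right_pos=40_000, right_strand="-")).frac_junctions
            == 1.0
        )

    def test_unknown_contig_raises(self, tmp_path):
        sam = _sam_with_pair(tmp_path, 10_250, 40_000)
        bad_truth = [BreakpointTruth("other", 1, ("chr1", 1, "+"), ("chr1", 2, "+"))]
        with pytest.raises(ValueError):
            verify_breakpoints(sam, bad_truth)
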