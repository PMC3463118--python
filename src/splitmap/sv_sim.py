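"""Structural-variant and complex-rearrangement simulation plus breakpoint
verification.

The generator produces everything the aligner needs end-to-end with no
external data: random (optionally repeat-seeded) reference genomes,
breakpoint-spanning contigs for simple SV events (deletion, tandem
duplication, inversion, insertion from a distant locus), chromothripsis-style
shattered contigs, and uniformly sampled error-bearing reads.  Every junction
a contig carries is recorded as ground truth, and
:func:`verify_breakpoints` scores a SAM file against that truth with the
within-N-bases criterion used for split-read breakpoint detection.

Contig construction for an event of length L with flank F:
  deletion              F + F                      (one novel junction)
  tandem duplication    F + L + L + F  (L <= F)    (one novel junction)
  inversion             F + L + F      (L <= F)    (two novel junctions)
  insertion             F + L + F      (L <= F)    (two novel junctions)
Events longer than the flank get a contig for the left breakpoint only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._util import revcomp_str

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Reference generation


@dataclass
class RepeatFamilySpec:
    """A planted family of interspersed, highly similar elements (an
    Alu-like short interspersed repeat)."""

    n_copies: int = 25
    length: int = 300
    divergence: float = 0.01  # per-copy substitution rate from the consensus


@dataclass
class SyntheticReference:
    sequences: dict  # name -> str
    repeat_loci: list = field(default_factory=list)  # (name, start, length)
    repeat_consensus: str | None = None


def _random_seq(rng, length: int, gc_bias: float = 0.5) -> str:
    p_gc = gc_bias / 2
    p_at = (1 - gc_bias) / 2
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return BASES[codes].tobytes().decode("ascii")


def _mutate_substitutions(seq: str, rate: float, rng) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = rng.binomial(len(arr), rate)
    if n_mut:
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        for p in pos:
            choices = BASES[BASES != arr[p]]
            arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def make_synthetic_reference(
    num_seqs: int = 1,
    lengths=(1_000_000,),
    gc_bias: float = 0.5,
    rng_seed: int = 0,
    repeat_family: RepeatFamilySpec | None = None,
) -> SyntheticReference:
    """Generate i.i.d. random sequences, reproducible from ``rng_seed``.

    When ``repeat_family`` is given, that many copies of a random consensus
    element, each independently diverged by the family's substitution rate,
    are planted at non-overlapping positions across the sequences.
    """
    rng = np.random.default_rng(rng_seed)
    seqs = {}
    for i in range(num_seqs):
        seqs[f"chr{i + 1}"] = _random_seq(rng, int(lengths[i]), gc_bias)
    loci = []
    consensus = None
    if repeat_family is not None:
        consensus = _random_seq(rng, repeat_family.length, gc_bias)
        names = list(seqs)
        weights = np.array([len(seqs[n]) for n in names], dtype=float)
        weights /= weights.sum()
        taken: dict[str, list] = {n: [] for n in names}
        placed = 0
        while placed < repeat_family.n_copies:
            name = names[int(rng.choice(len(names), p=weights))]
            L = len(seqs[name])
            pos = int(rng.integers(0, L - repeat_family.length))
            if any(pos < e + 1000 and pos + repeat_family.length > s - 1000 for s, e in taken[name]):
                continue
            copy = _mutate_substitutions(consensus, repeat_family.divergence, rng)
            seqs[name] = seqs[name][:pos] + copy + seqs[name][pos + repeat_family.length :]
            taken[name].append((pos, pos + repeat_family.length))
            loci.append((name, pos, repeat_family.length))
            placed += 1
    return SyntheticReference(sequences=seqs, repeat_loci=loci, repeat_consensus=consensus)


# ---------------------------------------------------------------------------
# Simple SV events


SV_TYPES = ("deletion", "tandem_duplication", "inversion", "insertion")


@dataclass
class SVEvent:
    type: str
    ref_name: str
    start: int
    length: int
    donor_ref: str | None = None  # insertions only
    donor_start: int | None = None


@dataclass
class BreakpointTruth:
    """One novel junction on a simulated contig.

    Each side is (ref_name, boundary_pos, strand): approaching the junction
    along the contig you leave the reference at ``left`` and re-enter it at
    ``right``; boundary positions use half-open coordinates ('+' side
    boundaries are interval ends/starts, '-' sides the mirrored ones).
    """

    contig_name: str
    contig_offset: int
    left: tuple
    right: tuple


def simulate_sv_events(
    reference: dict,
    n_per_type: int = 25,
    length_range=(100, 10_000),
    flank: int = 500,
    rng_seed: int = 0,
    min_distance: int = 100_000,
    donor_loci=None,
) -> list[SVEvent]:
    """Place non-overlapping SV events of each type at random positions.

    Lengths are log-uniform over ``length_range``.  Insertion donors are
    drawn from ``donor_loci`` [(name, start, length), ...] when given,
    otherwise from a random locus at least ``min_distance`` away (or on a
    different sequence).
    """
    rng = np.random.default_rng(rng_seed)
    names = list(reference)
    occupied: dict[str, list] = {n: [] for n in names}

    def reserve(name, lo, hi) -> bool:
        if lo < 0 or hi > len(reference[name]):
            return False
        for s, e in occupied[name]:
            if lo < e and hi > s:
                return False
        occupied[name].append((lo, hi))
        return True

    events = []
    lo_l, hi_l = length_range
    for etype in SV_TYPES:
        made = 0
        attempts = 0
        while made < n_per_type and attempts < 10_000:
            attempts += 1
            name = names[int(rng.integers(len(names)))]
            if etype == "insertion" and donor_loci:
                dref, dstart, dlen = donor_loci[int(rng.integers(len(donor_loci)))]
                length = int(dlen)
            else:
                length = int(round(math.exp(rng.uniform(math.log(lo_l), math.log(hi_l)))))
                length = max(lo_l, min(hi_l, length))
                dref = dstart = None
            L = len(reference[name])
            start = int(rng.integers(flank, max(flank + 1, L - length - flank)))
            span = length if etype != "insertion" else 0
            if not reserve(name, start - flank, start + span + flank):
                continue
            if etype == "insertion" and dref is None:
                for _ in range(100):
                    dref = names[int(rng.integers(len(names)))]
                    dstart = int(rng.integers(0, len(reference[dref]) - length))
                    far = dref != name or abs(dstart - start) >= min_distance
                    if far:
                        break
                else:
                    continue
            events.append(SVEvent(etype, name, start, length, dref, dstart))
            made += 1
    return events


def apply_sv_events(reference: dict, events, flank: int = 500):
    """Build one breakpoint-spanning contig per event plus junction truth.

    Returns (contigs: dict name->seq, truth: list of BreakpointTruth).
    Events of length <= ``flank`` span the whole event; longer events get a
    left-breakpoint-only contig.  Overlapping events raise ValueError.
    """
    seen: dict[str, list] = {}
    for ev in events:
        span = ev.length if ev.type != "insertion" else 0
        iv = (ev.start - flank, ev.start + span + flank)
        for s, e in seen.get(ev.ref_name, []):
            if iv[0] < e and iv[1] > s:
                raise ValueError("events overlap on the reference")
        seen.setdefault(ev.ref_name, []).append(iv)

    contigs = {}
    truth = []
    for i, ev in enumerate(events):
        name = f"{ev.type}_{i}"
        seq = reference[ev.ref_name]
        s, L = ev.start, ev.length
        small = L <= flank
        if ev.type == "deletion":
            contig = seq[s - flank : s] + seq[s + L : s + L + flank]
            juncs = [(flank, (ev.ref_name, s, "+"), (ev.ref_name, s + L, "+"))]
        elif ev.type == "tandem_duplication":
            if small:
                contig = seq[s - flank : s] + seq[s : s + L] * 2 + seq[s + L : s + L + flank]
                juncs = [(flank + L, (ev.ref_name, s + L, "+"), (ev.ref_name, s, "+"))]
            else:
                contig = seq[s + L - flank : s + L] + seq[s : s + flank]
                juncs = [(flank, (ev.ref_name, s + L, "+"), (ev.ref_name, s, "+"))]
        elif ev.type == "inversion":
            inv = revcomp_str(seq[s : s + L])
            if small:
                contig = seq[s - flank : s] + inv + seq[s + L : s + L + flank]
                juncs = [
                    (flank, (ev.ref_name, s, "+"), (ev.ref_name, s + L, "-")),
                    (flank + L, (ev.ref_name, s, "-"), (ev.ref_name, s + L, "+")),
                ]
            else:
                contig = seq[s - flank : s] + inv[:flank]
                juncs = [(flank, (ev.ref_name, s, "+"), (ev.ref_name, s + L, "-"))]
        elif ev.type == "insertion":
            donor = reference[ev.donor_ref][ev.donor_start : ev.donor_start + L]
            if small:
                contig = seq[s - flank : s] + donor + seq[s : s + flank]
                juncs = [
                    (flank, (ev.ref_name, s, "+"), (ev.donor_ref, ev.donor_start, "+")),
                    (flank + L, (ev.donor_ref, ev.donor_start + L, "+"), (ev.ref_name, s, "+")),
                ]
            else:
                contig = seq[s - flank : s] + donor[:flank]
                juncs = [(flank, (ev.ref_name, s, "+"), (ev.donor_ref, ev.donor_start, "+"))]
        else:
            raise ValueError(f"unknown event type {ev.type}")
        contigs[name] = contig
        for off, left, right in juncs:
            truth.append(BreakpointTruth(name, off, left, right))
    return contigs, truth


# ---------------------------------------------------------------------------
# Chromothripsis-style complex rearrangement


@dataclass
class CGRSpec:
    """Chromosome-shattering simulation: a region is cut into fragments
    (exponential lengths with the given mean, floored at the minimum), a
    fraction of fragments is deleted, duplicated and inverted, and the
    survivors are shuffled and ligated into one contig."""

    region_length: int = 30_000
    mean_frag_len: int = 300
    min_frag_len: int = 50
    frac_deleted: float = 0.30
    frac_duplicated: float = 0.10
    frac_inverted: float = 0.50
    num_loci: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        for v in (self.frac_deleted, self.frac_duplicated, self.frac_inverted):
            if not (0 <= v <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.frac_deleted + self.frac_duplicated > 1:
            raise ValueError("deleted + duplicated fractions exceed 1")
        if self.num_loci not in (1, 2):
            raise ValueError("num_loci must be 1 or 2")


def apply_cgr(reference: dict, spec: CGRSpec, contig_name: str = "cgr_0"):
    """Shatter one or two reference regions and ligate the pieces.

    Returns (contigs: {contig_name: seq}, truth).  Every junction between
    fragments that are not reference-adjacent (same strand, abutting
    original positions, in order) is recorded as a novel junction.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = list(reference)
    per_locus = spec.region_length // spec.num_loci
    pieces = []  # (ref_name, start, end, strand)
    for _ in range(spec.num_loci):
        name = names[int(rng.integers(len(names)))]
        L = len(reference[name])
        if L < per_locus:
            raise ValueError("reference sequence shorter than CGR region")
        region_start = int(rng.integers(0, L - per_locus + 1))
        pos = region_start
        end = region_start + per_locus
        while pos < end:
            frag = spec.min_frag_len + int(rng.exponential(max(spec.mean_frag_len - spec.min_frag_len, 1)))
            frag = min(frag, end - pos)
            pieces.append([name, pos, pos + frag, "+"])
            pos += frag

    n = len(pieces)
    order = rng.permutation(n)
    n_del = int(round(spec.frac_deleted * n))
    n_dup = int(round(spec.frac_duplicated * n))
    deleted = set(order[:n_del])
    duplicated = set(order[n_del : n_del + n_dup])
    retained = []
    for i, p in enumerate(pieces):
        if i in deleted:
            continue
        retained.append(list(p))
        if i in duplicated:
            retained.append(list(p))
    for p in retained:
        if rng.random() < spec.frac_inverted:
            p[3] = "-"
    perm = rng.permutation(len(retained))
    shuffled = [retained[i] for i in perm]

    parts = []
    for name, s, e, strand in shuffled:
        frag = reference[name][s:e]
        parts.append(frag if strand == "+" else revcomp_str(frag))
    contig = "".join(parts)

    truth = []
    offset = 0
    for a, b in zip(shuffled[:-1], shuffled[1:]):
        offset += a[2] - a[1]
        ref_adjacent = a[0] == b[0] and a[3] == b[3] == "+" and a[2] == b[1]
        if ref_adjacent:
            continue
        left = (a[0], a[2], "+") if a[3] == "+" else (a[0], a[1], "-")
        right = (b[0], b[1], "+") if b[3] == "+" else (b[0], b[2], "-")
        truth.append(BreakpointTruth(contig_name, offset, left, right))
    return {contig_name: contig}, truth


# ---------------------------------------------------------------------------
# Read sampling and error profiles


@dataclass
class ReadSimParams:
    """read_length / coverage: uniform sampling depth over each contig.
    error_rate: per-base error probability; an error is a 1-bp indel with
    probability ``indel_frac`` (insertion/deletion equiprobable), otherwise
    a random substitution."""

    read_length: int = 500
    coverage: float = 5.0
    error_rate: float = 0.02
    indel_frac: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.indel_frac <= 1):
            raise ValueError("indel_frac must be in [0, 1]")


@dataclass
class SimRead:
    name: str
    sequence: str
    contig: str
    start: int  # 0-based offset of the error-free source window
    strand: str

    @property
    def quality(self) -> str:
        return "I" * len(self.sequence)


def impress_errors(seq: str, error_rate: float, indel_frac: float, rng) -> str:
    """Apply the wgsim-style error model to a sequence."""
    out = []
    for ch in seq:
        if rng.random() >= error_rate:
            out.append(ch)
            continue
        if rng.random() < indel_frac:
            if rng.random() < 0.5:
                continue  # 1-bp deletion
            out.append(ch)
            out.append("ACGT"[int(rng.integers(4))])  # 1-bp insertion
        else:
            others = "ACGT".replace(ch.upper(), "") or "ACGT"
            out.append(others[int(rng.integers(len(others)))])
    return "".join(out)


def sample_reads(contigs: dict, params: ReadSimParams) -> list[SimRead]:
    """Sample reads uniformly from both strands of each contig to the target
    coverage, then impress errors; reproducible from ``params.rng_seed``."""
    rng = np.random.default_rng(params.rng_seed)
    reads = []
    for cname, seq in contigs.items():
        L = len(seq)
        if params.read_length > L:
            raise ValueError(f"read length exceeds contig {cname} length")
        n_reads = int(round(params.coverage * L / params.read_length))
        for i in range(n_reads):
            start = int(rng.integers(0, L - params.read_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            window = seq[start : start + params.read_length]
            if strand == "-":
                window = revcomp_str(window)
            errored = impress_errors(window, params.error_rate, params.indel_frac, rng)
            reads.append(SimRead(f"{cname}|{start}|{strand}|{i}", errored, cname, start, strand))
    return reads


# ---------------------------------------------------------------------------
# Truth table IO

TRUTH_HEADER = "#contig\toffset\tleft_ref\tleft_pos\tleft_strand\tright_ref\tright_pos\tright_strand"


def write_truth(path, truth):
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for t in truth:
            fh.write(
                f"{t.contig_name}\t{t.contig_offset}\t{t.left[0]}\t{t.left[1]}\t{t.left[2]}"
                f"\t{t.right[0]}\t{t.right[1]}\t{t.right[2]}\n"
            )


def read_truth(path) -> list[BreakpointTruth]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, off, lr, lp, ls, rr, rp, rs = line.rstrip("\n").split("\t")
            out.append(BreakpointTruth(c, int(off), (lr, int(lp), ls), (rr, int(rp), rs)))
    return out


# ---------------------------------------------------------------------------
# Breakpoint verification


@dataclass
class VerificationReport:
    n_queries: int
    n_queries_verifying: int
    junction_hits: dict  # (contig, offset) -> bool

    @property
    def frac_queries(self) -> float:
        return self.n_queries_verifying / self.n_queries if self.n_queries else 0.0

    @property
    def n_junctions(self) -> int:
        return len(self.junction_hits)

    @property
    def n_junctions_verified(self) -> int:
        return sum(self.junction_hits.values())

    @property
    def frac_junctions(self) -> float:
        return self.n_junctions_verified / self.n_junctions if self.junction_hits else 0.0


def _record_sides(rec) -> dict:
    """Extract strand-aware interval data from a pysam record."""
    strand = "-" if rec.is_reverse else "+"
    qlen = rec.infer_read_length() or len(rec.query_sequence or "")
    qs, qe = rec.query_alignment_start, rec.query_alignment_end
    if rec.is_reverse:
        fq_start, fq_end = qlen - qe, qlen - qs
    else:
        fq_start, fq_end = qs, qe
    return {
        "fq_start": fq_start,
        "fq_end": fq_end,
        "ref": rec.reference_name,
        "r_start": rec.reference_start,
        "r_end": rec.reference_end,
        "strand": strand,
        "secondary": rec.is_secondary,
    }


def _flip(side):
    ref, pos, strand = side
    return ref, pos, "-" if strand == "+" else "+"


def _sides_match(obs, tru, tol) -> bool:
    return obs[0] == tru[0] and obs[2] == tru[2] and abs(obs[1] - tru[1]) <= tol


def verify_breakpoints(
    sam_path,
    truth,
    tolerance: int = 5,
    include_secondary: bool = False,
    query_gap_slack: int = 20,
) -> VerificationReport:
    """Score a SAM file against simulated junction truth.

    A query verifies a junction when two of its alignments (primaries, plus
    secondaries when ``include_secondary``) are adjacent on the query
    (their query intervals within ``query_gap_slack`` bases of abutting)
    and their facing reference boundaries match the junction's two sides
    within ``tolerance`` bases (inclusive) with matching strands, in either
    read orientation.  Reports the fraction of queries verifying at least
    one junction and the fraction of distinct truth junctions verified by
    at least one query.
    """
    by_contig: dict[str, list] = {}
    for t in truth:
        by_contig.setdefault(t.contig_name, []).append(t)
    junction_hits = {(t.contig_name, t.contig_offset): False for t in truth}

    per_query: dict[str, list] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                per_query.setdefault(rec.query_name, [])
                continue
            per_query.setdefault(rec.query_name, []).append(_record_sides(rec))

    n_verifying = 0
    for qname, alns in per_query.items():
        contig = qname.split("|")[0]
        if contig not in by_contig:
            raise ValueError(f"query {qname} does not map to any truth contig")
        cand = [a for a in alns if include_secondary or not a["secondary"]]
        cand.sort(key=lambda a: (a["fq_start"], a["fq_end"]))
        verified_any = False
        for ai in range(len(cand)):
            for bi in range(len(cand)):
                a, b = cand[ai], cand[bi]
                if bi == ai or b["fq_start"] < a["fq_start"]:
                    continue
                if abs(b["fq_start"] - a["fq_end"]) > query_gap_slack:
                    continue
                left = (a["ref"], a["r_end"] if a["strand"] == "+" else a["r_start"], a["strand"])
                right = (b["ref"], b["r_start"] if b["strand"] == "+" else b["r_end"], b["strand"])
                for t in by_contig[contig]:
                    direct = _sides_match(left, t.left, tolerance) and _sides_match(right, t.right, tolerance)
                    flipped = _sides_match(left, _flip(t.right), tolerance) and _sides_match(
                        right, _flip(t.left), tolerance
                    )
                    if direct or flipped:
                        junction_hits[(t.contig_name, t.contig_offset)] = True
                        verified_any = True
        if verified_any:
            n_verifying += 1
    return VerificationReport(len(per_query), n_verifying, junction_hits)
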