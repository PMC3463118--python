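"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive (enumeration, full unrestricted DP,
plain dict scans) and shares no code path with the package implementation
it checks.
"""
from __future__ import annotations

import math

NEG = float("-inf")


# ---------------------------------------------------------------------------
# Seeding: concatenate-and-sort seed collation


def seeds_by_concat_sort(index, query: str):
    """All (diagonal, qo, ro) seed matches via per-position lookups and one
    global sort (the approach the heap merge replaces)."""
    from splitmap.index import AMBIGUOUS, encode_kmer

    k = index.params.k
    out = []
    for qo in range(len(query) - k + 1):
        key = encode_kmer(query[qo : qo + k])
        if key == AMBIGUOUS:
            continue
        for ro in index.lookup(key):
            out.append((int(ro) - qo, qo, int(ro)))
    out.sort()
    return out


def naive_kmer_index(seq: str, k: int, skip: int = 1):
    """Plain dict of kmer -> ascending offsets (non-ambiguous only)."""
    table: dict[str, list] = {}
    for p in range(0, len(seq) - k + 1, skip):
        kmer = seq[p : p + k].upper()
        if any(c not in "ACGT" for c in kmer):
            continue
        table.setdefault(kmer, []).append(p)
    return table


# ---------------------------------------------------------------------------
# Chaining: exhaustive chain enumeration


def best_chain_brute_force(fragments, ags):
    """Maximum estimated chain score by enumerating every chain (ordered
    fragment sequence consistent with the edge rule); the scoring rule is
    restated here from first principles."""
    frags = sorted(fragments, key=lambda f: (f.q_start, f.r_start, f.q_end))
    n = len(frags)
    best = NEG

    def edge(f1, f2):
        if f2.q_start < f1.q_start or f2.r_start < f1.r_start:
            return NEG
        if f2.q_end <= f1.q_end or f2.r_end <= f1.r_end:
            return NEG
        trim = max(0, f1.q_end - f2.q_start, f1.r_end - f2.r_start)
        if trim >= f2.q_end - f2.q_start:
            return NEG
        d = abs(f2.diagonal - f1.diagonal)
        indel = 0 if d == 0 else ags.gap_open + ags.gap_extend * d
        mid = min(max(0, f2.q_start - f1.q_end), max(0, f2.r_start - f1.r_end))
        return indel + ags.mismatch * mid - ags.match * trim

    def extend(last_idx, score):
        nonlocal best
        best = max(best, score)
        for j in range(last_idx + 1, n):
            e = edge(frags[last_idx], frags[j])
            if e == NEG:
                continue
            extend(j, score + ags.match * frags[j].length + e)

    for i in range(n):
        extend(i, ags.match * frags[i].length)
    return best


# ---------------------------------------------------------------------------
# DP: plain-python unrestricted affine DP


def global_affine_oracle(q: str, r: str, ags):
    """Unbanded global affine-gap alignment score, textbook O(nm) DP."""
    n, m = len(q), len(r)
    g1 = ags.gap_open + ags.gap_extend
    ge = ags.gap_extend
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        F[0][j] = g1 + ge * (j - 1)
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        E[i][0] = g1 + ge * (i - 1)
        H[i][0] = E[i][0]
        qa = q[i - 1].upper()
        for j in range(1, m + 1):
            ra = r[j - 1].upper()
            s = ags.match if (qa == ra and qa in "ACGT") else ags.mismatch
            E[i][j] = max(H[i - 1][j] + g1, E[i - 1][j] + ge)
            F[i][j] = max(H[i][j - 1] + g1, F[i][j - 1] + ge)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]


def extension_oracle(q: str, r: str, ags):
    """Best extension score anchored at (0, 0): full DP keeping the global
    best cell, no band, no dropoff."""
    n, m = len(q), len(r)
    g1 = ags.gap_open + ags.gap_extend
    ge = ags.gap_extend
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    best = 0.0
    for j in range(1, m + 1):
        F[0][j] = g1 + ge * (j - 1)
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        E[i][0] = g1 + ge * (i - 1)
        H[i][0] = E[i][0]
        qa = q[i - 1].upper()
        for j in range(1, m + 1):
            ra = r[j - 1].upper()
            s = ags.match if (qa == ra and qa in "ACGT") else ags.mismatch
            E[i][j] = max(H[i - 1][j] + g1, E[i - 1][j] + ge)
            F[i][j] = max(H[i][j - 1] + g1, F[i][j - 1] + ge)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
        best = max(best, max(H[i]))
    return best


def rescore_alignment_text(q: str, r: str, ags, cigar) -> float:
    """Recompute an AGS score from aligned sequence text and a cigar."""
    qi = ri = 0
    score = 0.0
    for op, ln in cigar:
        if op == "M":
            for x in range(ln):
                qa, ra = q[qi + x].upper(), r[ri + x].upper()
                score += ags.match if (qa == ra and qa in "ACGT") else ags.mismatch
            qi += ln
            ri += ln
        elif op == "I":
            score += ags.gap_open + ags.gap_extend * ln
            qi += ln
        elif op == "D":
            score += ags.gap_open + ags.gap_extend * ln
            ri += ln
        elif op == "S":
            qi += ln
    return score


# ---------------------------------------------------------------------------
# OQC: exhaustive ordered-subset enumeration


def oqc_brute_force(alignments, params):
    """Best coverage score over every ordered alignment subset.

    Reimplements the objective directly: first alignment contributes its
    score; each appended alignment contributes its score minus overlap
    credit (prorated at the weaker per-base rate) minus bp * GDP.
    """

    def gdp(a, b):
        if a.ref_name != b.ref_name:
            return params.max_gdp
        gap = max(b.r_start - a.r_end, a.r_start - b.r_end, 0)
        return min(params.max_gdp, math.log10(max(1, gap)))

    alns = sorted(alignments, key=lambda a: (a.fq_start, a.fq_end, a.ref_name, a.r_start, a.strand))
    n = len(alns)
    best = NEG

    def extend(last, score):
        nonlocal best
        best = max(best, score)
        a = alns[last]
        for j in range(last + 1, n):
            b = alns[j]
            if b.fq_end <= a.fq_end:
                continue
            ov = max(0, min(a.fq_end, b.fq_end) - max(a.fq_start, b.fq_start))
            credit = 0.0
            if ov:
                credit = ov * min(
                    a.score / (a.fq_end - a.fq_start), b.score / (b.fq_end - b.fq_start)
                )
            extend(j, score + b.score - credit - params.bp * gdp(a, b))

    for i in range(n):
        extend(i, float(alns[i].score))
    return best if n else 0.0
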