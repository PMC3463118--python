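"""Optimal Query Coverage (OQC) and Filter By Similarity (FBS).

OQC selects, from all completed alignments of a query, the subset that
maximises the sum of overlap-adjusted alignment scores minus a penalty for
every split.  The split penalty is the user's breakpoint penalty (BP)
multiplied by a genomic distance penalty (GDP): log10 of the reference
distance between the two alignments, capped at max_gdp, with alignments on
different reference sequences always charged the cap.  The winning subset
(the Optimal Coverage Set) becomes the query's primary alignments; the
search is the same edge-free max-path DAG relaxation used for fragment
chaining, over alignments presorted by query start.  Opposite-strand and
cross-sequence pairs are chainable — an inversion or translocation junction
joins exactly such alignments.

FBS then promotes non-primary alignments that closely mirror a primary
(reciprocal query-interval overlap and score both above user fractions) to
secondary alignments; everything else is discarded from output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .dp_align import Alignment

NEG_INF = float("-inf")


@dataclass(frozen=True)
class OQCParams:
    """bp: breakpoint penalty per split (score units, multiplied by the
    GDP).  max_gdp: cap on the genomic-distance factor.  enabled: when
    False the aligner reports all alignments instead."""

    bp: float = 5.0
    max_gdp: float = 5.0
    enabled: bool = True

    def __post_init__(self):
        if self.bp < 0 or self.max_gdp < 0:
            raise ValueError("bp and max_gdp must be >= 0")


@dataclass(frozen=True)
class FBSParams:
    """min_overlap_frac: minimum reciprocal query-interval overlap with a
    primary.  min_score_frac: minimum score as a fraction of that
    primary's."""

    min_overlap_frac: float = 0.9
    min_score_frac: float = 0.9
    enabled: bool = True

    def __post_init__(self):
        for v in (self.min_overlap_frac, self.min_score_frac):
            if not (0 < v <= 1):
                raise ValueError("FBS fractions must be in (0, 1]")


@dataclass
class CoverageResult:
    primaries: list = field(default_factory=list)
    secondaries: list = field(default_factory=list)
    coverage_score: float = 0.0


def genomic_distance_penalty(a1: Alignment, a2: Alignment, params: OQCParams) -> float:
    """GDP factor between two alignments: log10 of the base-pair distance
    between their nearest reference endpoints (0 when they touch or
    overlap), capped at max_gdp; different sequences always incur the cap."""
    if a1.ref_name != a2.ref_name:
        return params.max_gdp
    gap = max(a2.r_start - a1.r_end, a1.r_start - a2.r_end, 0)
    return min(params.max_gdp, math.log10(max(1, gap)))


def overlap_adjusted_gain(prev: Alignment, nxt: Alignment) -> float:
    """Score gained by appending ``nxt`` after ``prev`` along the query.

    Where the two overlap on the query, credit for the overlap is prorated
    at the per-base rate of the weaker alignment, so each query base is
    scored at most once.  Containment is disallowed.
    """
    if nxt.fq_start < prev.fq_start:
        raise ValueError("alignments must be appended in query order")
    if nxt.fq_end <= prev.fq_end:
        raise ValueError("next alignment is contained in prev on the query")
    ov = max(0, min(prev.fq_end, nxt.fq_end) - max(prev.fq_start, nxt.fq_start))
    if ov == 0:
        return float(nxt.score)
    per_prev = prev.score / (prev.fq_end - prev.fq_start)
    per_next = nxt.score / (nxt.fq_end - nxt.fq_start)
    return float(nxt.score) - ov * min(per_prev, per_next)


def _sort_key(a: Alignment):
    return (a.fq_start, a.fq_end, a.ref_name, a.r_start, a.strand)


def optimal_query_coverage(alignments, params: OQCParams) -> CoverageResult:
    """Find the Optimal Coverage Set by max-path DAG relaxation.

    The objective of a chain a_1..a_t is
    score(a_1) + sum_i [overlap_adjusted_gain(a_{i-1}, a_i)
                        - bp * GDP(a_{i-1}, a_i)].
    Primaries are flagged in place; non-primaries are left untouched for
    FBS.  Empty input yields an empty result.
    """
    alns = sorted(alignments, key=_sort_key)
    if not alns:
        return CoverageResult()
    n = len(alns)
    best = [float(a.score) for a in alns]
    back = [-1] * n
    for j in range(1, n):
        aj = alns[j]
        for i in range(j):
            ai = alns[i]
            if aj.fq_end <= ai.fq_end:
                continue
            g = overlap_adjusted_gain(ai, aj) - params.bp * genomic_distance_penalty(ai, aj, params)
            cand = best[i] + g
            if cand > best[j]:
                best[j] = cand
                back[j] = i
    end = max(range(n), key=lambda j: (best[j], -j))
    chain = []
    j = end
    while j != -1:
        chain.append(alns[j])
        j = back[j]
    chain.reverse()
    for a in alns:
        a.is_primary = False
    for a in chain:
        a.is_primary = True
    return CoverageResult(primaries=chain, coverage_score=float(best[end]))


def coverage_score(alignments, max_gdp: float = 5.0) -> float:
    """The Coverage Score of a set of alignments: their best non-overlapping
    summed score (the OQC objective with no breakpoint penalty)."""
    if not alignments:
        return 0.0
    res = optimal_query_coverage(list(alignments), OQCParams(bp=0.0, max_gdp=max_gdp))
    return res.coverage_score


def filter_by_similarity(cov: CoverageResult, all_alignments, params: FBSParams):
    """Tag non-primary alignments that closely mirror a primary as
    secondaries: reciprocal query overlap >= min_overlap_frac and score >=
    min_score_frac of the matched primary.  Returns the secondaries, each
    with ``similar_to`` set to its best-matching primary."""
    secondaries = []
    for a in all_alignments:
        if a.is_primary:
            continue
        a.is_secondary = False
        a.similar_to = None
        best_key = None
        for p in cov.primaries:
            ov = max(0, min(a.fq_end, p.fq_end) - max(a.fq_start, p.fq_start))
            if ov == 0:
                continue
            len_a = a.fq_end - a.fq_start
            len_p = p.fq_end - p.fq_start
            if ov / len_p < params.min_overlap_frac or ov / len_a < params.min_overlap_frac:
                continue
            if a.score < params.min_score_frac * p.score:
                continue
            key = (ov, p.score)
            if best_key is None or key > best_key:
                best_key = key
                a.similar_to = p
        if a.similar_to is not None:
            a.is_secondary = True
            secondaries.append(a)
    cov.secondaries = secondaries
    return secondaries


def report_all_mode(alignments):
    """Identity pass-through used when OQC is disabled: every alignment is
    reported, with only the single best-scoring one flagged primary (ties
    broken by reference name then position)."""
    alns = list(alignments)
    if not alns:
        return alns
    best = min(alns, key=lambda a: (-a.score, a.ref_name, a.r_start))
    for a in alns:
        a.is_primary = a is best
        a.is_secondary = a is not best
    return alns
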