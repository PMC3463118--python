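"""Fragment chaining: max-path DAG over fragments within a reference region.

Fragments are grouped into reference regions, then the chain with the
maximum estimated affine-gap score is found by relaxing edges over
qStart-sorted fragments without materialising them (O(n^2) time, O(n)
space).  Fragment bases are scored as matches; a difference between the
diagonals of consecutive fragments is scored as a single indel of that
length; bases counted in an earlier fragment are trimmed from the later
fragment's reward.  Chaining repeats on fragments that fall in query
intervals not yet covered by a chain, and chains whose seeds cover fewer
than ``min_match`` non-overlapping query bases are discarded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seeding import Fragment

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AGSParams:
    """Affine-gap scoring parameters; a gap of length L costs
    gap_open + gap_extend * L."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class ChainParams:
    """min_match: minimum seed-covered (non-overlapping) query bases for a
    potential alignment to survive.  max_region_gap: reference distance that
    separates fragment groups; None means 10x the query length, capped at
    50 kb, chosen per query."""

    min_match: int = 25
    max_region_gap: int | None = None

    REGION_GAP_FACTOR = 10
    REGION_GAP_CAP = 50_000

    def __post_init__(self):
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")
        if self.max_region_gap is not None and self.max_region_gap <= 0:
            raise ValueError("max_region_gap must be positive")

    def region_gap_for(self, query_length: int) -> int:
        if self.max_region_gap is not None:
            return self.max_region_gap
        return min(self.REGION_GAP_FACTOR * query_length, self.REGION_GAP_CAP)


@dataclass
class PotentialAlignment:
    """A chained fragment set awaiting DP completion."""

    fragments: list  # ascending q_start and r_start
    estimated_score: float
    seed_bases: int
    strand: str
    region_id: int


def partition_regions(fragments, max_region_gap: int, ref_offsets=None) -> list[list[Fragment]]:
    """Group single-strand fragments into reference regions.

    Fragments are sorted by r_start; a new group starts when the reference
    gap to the previous fragment exceeds ``max_region_gap`` or a sequence
    boundary (given by ``ref_offsets``) is crossed.
    """
    frags = sorted(fragments, key=lambda f: (f.r_start, f.q_start))
    groups: list[list[Fragment]] = []
    prev = None
    for f in frags:
        new = prev is None or f.r_start - prev.r_end > max_region_gap
        if not new and ref_offsets is not None and len(ref_offsets) > 1:
            si_prev = int(np.searchsorted(ref_offsets, prev.r_start, side="right")) - 1
            si = int(np.searchsorted(ref_offsets, f.r_start, side="right")) - 1
            new = si != si_prev
        if new:
            groups.append([])
        groups[-1].append(f)
        prev = f
    return groups


def chain_score_edge(f1: Fragment, f2: Fragment, ags: AGSParams) -> float:
    """Estimated cost/benefit of ``f2`` succeeding ``f1`` in a chain.

    Returns the indel term for the diagonal difference minus the match
    reward trimmed for bases of ``f2`` that overlap ``f1`` on query or
    reference (each matching base is counted once).  -inf when the edge is
    disallowed: ``f2`` must start at or after ``f1`` on both axes and
    contribute novel coverage on both.
    """
    if f2.q_start < f1.q_start or f2.r_start < f1.r_start:
        return NEG_INF
    if f2.q_end <= f1.q_end or f2.r_end <= f1.r_end:
        return NEG_INF
    q_ov = max(0, f1.q_end - f2.q_start)
    r_ov = max(0, f1.r_end - f2.r_start)
    trim = max(q_ov, r_ov)
    if trim >= f2.length:
        return NEG_INF
    d = abs(f2.diagonal - f1.diagonal)
    indel = 0 if d == 0 else ags.gap_open + ags.gap_extend * d
    # the unmatched middle the DP fill will have to cross is at best a run
    # of substitutions; estimating it as such keeps same-diagonal fragments
    # that are far apart on both axes from chaining "for free"
    middle = min(max(0, f2.q_start - f1.q_end), max(0, f2.r_start - f1.r_end))
    return indel + ags.mismatch * middle - ags.match * trim


def chain_fragments(group, ags: AGSParams):
    """Maximum-estimated-score chain over a fragment group.

    Nodes (fragments sorted by q_start) carry reward match*length; edges are
    scored by :func:`chain_score_edge` and relaxed in one O(n^2) pass.  Ties
    prefer the predecessor with the smaller reference gap, then the smaller
    q_start.  Returns (fragments, estimated_score).
    """
    if not group:
        raise ValueError("cannot chain an empty group")
    frags = sorted(group, key=lambda f: (f.q_start, f.r_start, f.q_end))
    n = len(frags)
    best = [ags.match * f.length for f in frags]
    back = [-1] * n
    # tie-break key of the chosen predecessor: (ref gap, q_start)
    pref = [None] * n
    for j in range(n):
        fj = frags[j]
        for i in range(j):
            fi = frags[i]
            e = chain_score_edge(fi, fj, ags)
            if e == NEG_INF:
                continue
            cand = best[i] + ags.match * fj.length + e
            key = (fj.r_start - fi.r_end, fi.q_start)
            if cand > best[j] or (cand == best[j] and pref[j] is not None and key < pref[j]):
                best[j] = cand
                back[j] = i
                pref[j] = key
    end = max(range(n), key=lambda j: (best[j], -j))
    chain = []
    j = end
    while j != -1:
        chain.append(frags[j])
        j = back[j]
    chain.reverse()
    return chain, float(best[end])


def seed_union_bases(fragments) -> int:
    """Measure of the union of the fragments' query intervals."""
    ivs = sorted((f.q_start, f.q_end) for f in fragments)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def iterate_uncovered(group, ags: AGSParams, region_id: int = 0) -> list[PotentialAlignment]:
    """Chain repeatedly over query portions not covered by earlier chains.

    Each round chains the remaining fragments that do not overlap on the
    query with any potential alignment already produced from this region.
    Output is ordered by estimated score, descending.
    """
    remaining = list(group)
    covered: list[tuple[int, int]] = []  # query extents of produced chains
    out: list[PotentialAlignment] = []
    while remaining:
        chain, score = chain_fragments(remaining, ags)
        strand = chain[0].strand
        out.append(
            PotentialAlignment(
                fragments=chain,
                estimated_score=score,
                seed_bases=seed_union_bases(chain),
                strand=strand,
                region_id=region_id,
            )
        )
        covered.append((min(f.q_start for f in chain), max(f.q_end for f in chain)))
        chain_ids = {id(f) for f in chain}
        remaining = [
            f
            for f in remaining
            if id(f) not in chain_ids
            and not any(f.q_start < e and f.q_end > s for s, e in covered)
        ]
    out.sort(key=lambda pa: -pa.estimated_score)
    return out


def filter_minmatch(pa: PotentialAlignment, min_match: int) -> bool:
    """Keep a potential alignment iff its seeds cover >= min_match
    non-overlapping query bases (boundary inclusive)."""
    return pa.seed_bases >= min_match
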