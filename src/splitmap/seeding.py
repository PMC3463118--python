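"""Seed collection and fragment formation.

Every query position contributes one k-mer; its presorted reference hit list
comes straight out of the index.  Because each list is ascending in reference
offset (hence in diagonal, for a fixed query offset), a QL-way merge with a
binary heap produces the full seed stream globally sorted by
(diagonal, query offset) while keeping at most one live entry per query
position.  Same-diagonal seeds whose query spans overlap or abut are then
coalesced into maximal exact-match fragments.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._util import encode_seq, revcomp_codes
from .index import Index, window_keys


class SeedMatch(NamedTuple):
    qo: int  # query offset of seed start (0-based)
    ro: int  # reference offset of seed start (concatenated space)
    diagonal: int  # ro - qo


@dataclass
class Fragment:
    """Maximal run of exactly matching bases on one diagonal.

    Query and reference spans are 0-based half-open and equal in length.
    """

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    diagonal: int
    seed_count: int
    strand: str = "+"

    def __post_init__(self):
        if self.q_end - self.q_start != self.r_end - self.r_start:
            raise ValueError("fragment spans must have equal length")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def query_hit_lists(index: Index, query) -> list[tuple[int, np.ndarray]]:
    """(query offset, ascending reference hits) for each non-ambiguous k-mer."""
    codes = encode_seq(query)
    k = index.params.k
    keys, valid = window_keys(codes, k)
    if len(keys) == 0:
        return []
    starts, counts = index.lookup_batch(keys)
    out = []
    for qo in np.nonzero(valid & (counts > 0))[0]:
        s = starts[qo]
        out.append((int(qo), index.roa[s : s + counts[qo]]))
    return out


def collect_seed_matches(index: Index, query, stats: dict | None = None) -> list[SeedMatch]:
    """All seed matches of ``query`` sorted by (diagonal, query offset).

    Implemented as a heap merge of the per-position presorted hit lists (at
    most one live heap entry per query position), not a concatenate-and-sort.
    ``stats``, if given, receives ``n_seeds`` and ``peak_heap``.
    """
    lists = query_hit_lists(index, query)
    heap = []
    for li, (qo, hits) in enumerate(lists):
        heap.append((int(hits[0]) - qo, qo, li, 0))
    heapq.heapify(heap)
    peak = len(heap)
    out = []
    while heap:
        diag, qo, li, pi = heapq.heappop(heap)
        out.append(SeedMatch(qo, diag + qo, diag))
        hits = lists[li][1]
        pi += 1
        if pi < len(hits):
            heapq.heappush(heap, (int(hits[pi]) - qo, qo, li, pi))
    if stats is not None:
        stats["n_seeds"] = len(out)
        stats["peak_heap"] = peak
    return out


def build_fragments(sorted_seeds, k: int, strand: str = "+") -> list[Fragment]:
    """Coalesce (diagonal, qo)-sorted seeds into maximal exact fragments.

    Seeds on one diagonal merge while the next seed starts at or before the
    current fragment end (``next.qo <= prev.qo + k``); contiguous coverage of
    the merged span by exact k-mer matches makes every fragment an exact
    match run by construction.
    """
    frags: list[Fragment] = []
    prev_key = None
    cur = None  # [diag, q_start, last_qo, n_seeds]
    for seed in sorted_seeds:
        key = (seed.diagonal, seed.qo)
        if prev_key is not None and key < prev_key:
            raise ValueError("seeds must be sorted by (diagonal, qo)")
        prev_key = key
        if cur is not None and seed.diagonal == cur[0] and seed.qo <= cur[2] + k:
            cur[2] = max(cur[2], seed.qo)
            cur[3] += 1
        else:
            if cur is not None:
                frags.append(_close(cur, k, strand))
            cur = [seed.diagonal, seed.qo, seed.qo, 1]
    if cur is not None:
        frags.append(_close(cur, k, strand))
    return frags


def _close(cur, k, strand) -> Fragment:
    diag, q_start, last_qo, n = cur
    q_end = last_qo + k
    return Fragment(q_start, q_end, q_start + diag, q_end + diag, diag, n, strand)


def fragment_is_exact(frag: Fragment, index: Index, query_codes: np.ndarray) -> bool:
    """Direct base-by-base check of the fragment exact-match invariant."""
    q = query_codes[frag.q_start : frag.q_end]
    r = index.ref_codes[frag.r_start : frag.r_end]
    return bool(np.all((q == r) & (q < 4)))


def seed_query_both_strands(index: Index, query, stats: dict | None = None):
    """Fragments for the query and its reverse complement.

    Returns ``{"+": fragments, "-": fragments}``; minus-strand fragments use
    reverse-complemented-query coordinates (SAM convention: the query is
    reported reverse-complemented against the forward reference).
    """
    codes = encode_seq(query)
    k = index.params.k
    result = {}
    for strand, c in (("+", codes), ("-", revcomp_codes(codes))):
        st: dict = {}
        seeds = collect_seed_matches(index, c, st)
        result[strand] = build_fragments(seeds, k, strand)
        if stats is not None:
            stats[f"n_seeds{strand}"] = st.get("n_seeds", 0)
    return result
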