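"""Affine-gap dynamic programming: banded global fills between fragments,
X-dropoff extensions at alignment ends, and the exact full Smith-Waterman
local aligner used as the accuracy benchmark throughout the test-suite.

Conventions shared by every kernel here (and by the chaining estimates):
a gap of length L costs gap_open + gap_extend * L; traceback ties prefer a
match/mismatch over a deletion over an insertion, giving deterministic
CIGARs.  Scores are exact integers.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import (
    cigar_query_len,
    cigar_ref_len,
    encode_seq,
    merge_cigar,
)
from .chaining import AGSParams, PotentialAlignment

log = logging.getLogger(__name__)

NEG = -(2**40)  # effectively -inf for int64 DP cells

# fills larger than this on either axis are abandoned (the chain that
# produced them is biologically implausible at our scales)
MAX_FILL_DIM = 20_000


class AlignmentDropped(Exception):
    """A potential alignment could not be completed."""


@dataclass(frozen=True)
class DPParams:
    """band_width: half-width of the DP band for inter-fragment fills.
    x_drop: stop extending when the running score falls more than this below
    the best score seen.  extension_band_factor: band multiplier applied
    during extensions, whose endpoints are unknown."""

    band_width: int = 15
    x_drop: int = 25
    extension_band_factor: int = 2

    def __post_init__(self):
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")
        if self.x_drop <= 0:
            raise ValueError("x_drop must be positive")


@dataclass
class Alignment:
    """A completed local alignment.

    ``q_start``/``q_end`` are 0-based half-open on the *aligned orientation*
    of the query (the reverse complement for minus-strand alignments, as in
    SAM); ``fq_start``/``fq_end`` give the same interval on the forward
    query.  ``r_start``/``r_end`` are per-sequence reference coordinates.
    ``cigar`` covers only the aligned span (soft clips are added on SAM
    output).
    """

    query_name: str
    strand: str
    ref_name: str
    r_start: int
    r_end: int
    q_start: int
    q_end: int
    query_length: int
    cigar: list
    score: int
    is_primary: bool = False
    is_secondary: bool = False
    similar_to: "Alignment | None" = field(default=None, repr=False, compare=False)

    @property
    def fq_start(self) -> int:
        return self.q_start if self.strand == "+" else self.query_length - self.q_end

    @property
    def fq_end(self) -> int:
        return self.q_end if self.strand == "+" else self.query_length - self.q_start

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    def validate(self):
        if cigar_query_len(self.cigar) != self.q_span:
            raise AssertionError("CIGAR query length mismatch")
        if cigar_ref_len(self.cigar) != self.r_end - self.r_start:
            raise AssertionError("CIGAR reference length mismatch")


# ---------------------------------------------------------------------------
# Banded global fill


def banded_affine_fill(query_seg, ref_seg, ags: AGSParams, band_width: int):
    """Optimal global affine-gap alignment of two segments within a band.

    The band covers diagonals j - i in [min(0, m-n) - band_width,
    max(0, m-n) + band_width], which always contains both corners, so a
    complete path exists for any band_width >= 1.  With band_width >=
    max(len1, len2) the result equals unbanded global alignment.  Returns
    (score, cigar).
    """
    q = encode_seq(query_seg)
    r = encode_seq(ref_seg)
    n, m = len(q), len(r)
    if n == 0 or m == 0:
        raise ValueError("both segments must be nonempty")
    g1 = ags.gap_open + ags.gap_extend
    ge = ags.gap_extend
    lo = min(0, m - n) - band_width
    hi = max(0, m - n) + band_width

    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    j0 = min(m, hi)
    if j0 >= 1:
        js = np.arange(1, j0 + 1)
        F[0, 1 : j0 + 1] = g1 + ge * (js - 1)
        H[0, 1 : j0 + 1] = F[0, 1 : j0 + 1]
    i0 = min(n, -lo)
    if i0 >= 1:
        iis = np.arange(1, i0 + 1)
        E[1 : i0 + 1, 0] = g1 + ge * (iis - 1)
        H[1 : i0 + 1, 0] = E[1 : i0 + 1, 0]

    for i in range(1, n + 1):
        jlo = max(1, i + lo)
        jhi = min(m, i + hi)
        if jlo > jhi:
            continue
        qc = q[i - 1]
        rs = r[jlo - 1 : jhi]
        sub = np.where((rs == qc) & (qc < 4) & (rs < 4), ags.match, ags.mismatch)
        diag = H[i - 1, jlo - 1 : jhi] + sub
        E[i, jlo : jhi + 1] = np.maximum(
            H[i - 1, jlo : jhi + 1] + g1, E[i - 1, jlo : jhi + 1] + ge
        )
        h0 = np.maximum(diag, E[i, jlo : jhi + 1])
        # F depends on H cells of this row to the left; a single running
        # maximum suffices because re-opening a gap out of a gap never beats
        # the direct single gap (gap_open <= 0)
        hl = np.empty(jhi - jlo + 1, dtype=np.int64)
        hl[0] = H[i, jlo - 1]
        hl[1:] = h0[:-1]
        t = hl - ge * np.arange(jlo - 1, jhi, dtype=np.int64)
        c = np.maximum.accumulate(t)
        F[i, jlo : jhi + 1] = g1 + ge * (np.arange(jlo, jhi + 1, dtype=np.int64) - 1) + c
        H[i, jlo : jhi + 1] = np.maximum(h0, F[i, jlo : jhi + 1])

    score = int(H[n, m])
    if score <= NEG // 2:  # pragma: no cover - band always contains a path
        raise AlignmentDropped("band excluded every complete path")
    cigar = _traceback_global(H, E, F, q, r, ags)
    return score, cigar


def _traceback_global(H, E, F, q, r, ags):
    g1 = ags.gap_open + ags.gap_extend
    ge = ags.gap_extend
    i, j = len(q), len(r)
    ops = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                s = ags.match if (q[i - 1] == r[j - 1] and q[i - 1] < 4 and r[j - 1] < 4) else ags.mismatch
                if H[i, j] == H[i - 1, j - 1] + s:
                    ops.append(("M", 1))
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif i > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover
                raise AssertionError("traceback failed")
        elif state == "F":
            ops.append(("D", 1))
            if H[i, j - 1] + g1 == F[i, j]:
                state = "H"
            j -= 1
        else:  # E
            ops.append(("I", 1))
            if H[i - 1, j] + g1 == E[i, j]:
                state = "H"
            i -= 1
    ops.reverse()
    return merge_cigar(ops)


# ---------------------------------------------------------------------------
# X-dropoff extension


def _extend(qseg: np.ndarray, rseg: np.ndarray, ags: AGSParams, band: int, x: int):
    """Banded extension anchored at (0, 0), free to end anywhere.

    Rows are query positions; a row is abandoned (and the extension stops)
    when its best cell falls more than ``x`` below the best score seen.
    Returns (best_score, q_extent, r_extent, cigar).
    """
    n, mlen = len(qseg), len(rseg)
    g1 = ags.gap_open + ags.gap_extend
    ge = ags.gap_extend
    W = 2 * band + 1
    barr = np.arange(W, dtype=np.int64)

    # row 0
    j_row0 = barr - band
    h_row = np.full(W, NEG, dtype=np.int64)
    in0 = (j_row0 >= 1) & (j_row0 <= mlen)
    h_row[in0] = g1 + ge * (j_row0[in0] - 1)
    origin = band  # b index of j=0 in row 0
    h_row[origin] = 0
    f_row = h_row.copy()
    f_row[origin] = NEG
    e_row = np.full(W, NEG, dtype=np.int64)

    rows_H = [h_row]
    rows_E = [e_row]
    rows_F = [f_row]

    best, bi, bb = 0, 0, origin
    n_rows = 0
    for i in range(1, n + 1):
        jarr = i - band + barr
        if jarr[0] > mlen:
            break
        in_seq = (jarr >= 0) & (jarr <= mlen)
        prevH, prevE = rows_H[-1], rows_E[-1]
        qc = int(qseg[i - 1])
        jc = np.clip(jarr - 1, 0, max(mlen - 1, 0))
        rvals = rseg[jc] if mlen > 0 else np.zeros(W, dtype=np.uint8)
        sub = np.where((rvals == qc) & (qc < 4) & (rvals < 4), ags.match, ags.mismatch)
        vdiag = (jarr >= 1) & (jarr <= mlen)
        diag = np.where(vdiag, prevH + sub, NEG)
        prevH_up = np.concatenate([prevH[1:], [NEG]])
        prevE_up = np.concatenate([prevE[1:], [NEG]])
        e_row = np.where(in_seq, np.maximum(prevH_up + g1, prevE_up + ge), NEG)
        h0 = np.maximum(diag, e_row)
        t = h0 - ge * barr
        c = np.concatenate([[NEG], np.maximum.accumulate(t)[:-1]])
        f_row = np.where(in_seq, g1 + ge * (barr - 1) + c, NEG)
        h_row = np.maximum(h0, f_row)
        h_row[~in_seq] = NEG
        rows_H.append(h_row)
        rows_E.append(e_row)
        rows_F.append(f_row)
        n_rows = i
        rowmax = int(h_row.max())
        if rowmax > best:
            best = rowmax
            bi = i
            bb = int(np.argmax(h_row))
        if rowmax < best - x:
            break

    bj = bi - band + bb if bi > 0 else 0
    if bi == 0:
        return 0, 0, 0, []

    def cell(rows, i, j):
        b = j - i + band
        if b < 0 or b >= W or i < 0 or i > n_rows:
            return NEG
        return int(rows[i][b])

    i, j = bi, bj
    ops = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                qv, rv = int(qseg[i - 1]), int(rseg[j - 1])
                s = ags.match if (qv == rv and qv < 4 and rv < 4) else ags.mismatch
                if cell(rows_H, i, j) == cell(rows_H, i - 1, j - 1) + s:
                    ops.append(("M", 1))
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and cell(rows_H, i, j) == cell(rows_F, i, j):
                state = "F"
            elif i > 0 and cell(rows_H, i, j) == cell(rows_E, i, j):
                state = "E"
            else:  # pragma: no cover
                raise AssertionError("extension traceback failed")
        elif state == "F":
            ops.append(("D", 1))
            if cell(rows_H, i, j - 1) + g1 == cell(rows_F, i, j):
                state = "H"
            j -= 1
        else:
            ops.append(("I", 1))
            if cell(rows_H, i - 1, j) + g1 == cell(rows_E, i, j):
                state = "H"
            i -= 1
    ops.reverse()
    return best, bi, bj, merge_cigar(ops)


def xdrop_extend(query, ref, anchor_q: int, anchor_r: int, direction: str, ags: AGSParams, dp: DPParams, ref_limit: tuple[int, int] | None = None):
    """X-dropoff extension from an anchor abutting a fragment end.

    ``direction`` is "forward" (extend towards larger offsets) or
    "backward".  ``ref_limit`` bounds the usable reference window
    (concatenated coordinates); extensions never cross it.  Returns
    (best_score, q_extent, r_extent, cigar) with the cigar in left-to-right
    orientation.
    """
    q = encode_seq(query)
    r = encode_seq(ref)
    lo, hi = ref_limit if ref_limit is not None else (0, len(r))
    band = dp.band_width * dp.extension_band_factor
    if direction == "forward":
        qseg = q[anchor_q:]
        rseg = r[anchor_r:hi]
    elif direction == "backward":
        qseg = q[:anchor_q][::-1]
        rseg = r[lo:anchor_r][::-1]
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    score, qe, re_, cigar = _extend(np.ascontiguousarray(qseg), np.ascontiguousarray(rseg), ags, band, dp.x_drop)
    if direction == "backward":
        cigar = list(reversed(cigar))
    return score, qe, re_, cigar


# ---------------------------------------------------------------------------
# Completion of a potential alignment


def complete_alignment(
    pa: PotentialAlignment,
    index,
    query_codes: np.ndarray,
    query_name: str,
    ags: AGSParams,
    dp: DPParams,
) -> Alignment:
    """Concatenate backward extension + fragments + inter-fragment fills +
    forward extension into one alignment with an exact AGS score.

    ``query_codes`` must already be in the orientation of ``pa.strand``
    (reverse-complemented for minus-strand chains).  Raises
    :class:`AlignmentDropped` when a fill is infeasible.
    """
    frags = pa.fragments
    # physically trim overlaps off later fragments (they sit on a diagonal,
    # so query and reference trim together)
    trimmed = [frags[0]]
    for f in frags[1:]:
        prev = trimmed[-1]
        t = max(prev.q_end - f.q_start, prev.r_end - f.r_start, 0)
        if t >= f.length:
            raise AlignmentDropped("chained fragment fully consumed by overlap trim")
        if t:
            f = dataclasses.replace(
                f, q_start=f.q_start + t, r_start=f.r_start + t
            )
        trimmed.append(f)
    frags = trimmed

    si = index.seq_index_of(frags[0].r_start)
    seq_lo, seq_hi = index.seq_bounds(si)
    if index.seq_index_of(frags[-1].r_end - 1) != si:
        raise AlignmentDropped("chain crosses a reference sequence boundary")

    ref = index.ref_codes
    score = 0
    cigar: list = []

    # backward extension
    bscore, bq, br, bcig = xdrop_extend(
        query_codes, ref, frags[0].q_start, frags[0].r_start, "backward", ags, dp, (seq_lo, seq_hi)
    )
    score += bscore
    cigar.extend(bcig)
    q_start = frags[0].q_start - bq
    r_start = frags[0].r_start - br

    for idx, f in enumerate(frags):
        if idx > 0:
            prev = frags[idx - 1]
            qgap = f.q_start - prev.q_end
            rgap = f.r_start - prev.r_end
            if qgap > MAX_FILL_DIM or rgap > MAX_FILL_DIM:
                raise AlignmentDropped("inter-fragment gap too large to fill")
            if qgap > 0 and rgap > 0:
                s, cig = banded_affine_fill(
                    query_codes[prev.q_end : f.q_start],
                    ref[prev.r_end : f.r_start],
                    ags,
                    max(dp.band_width, abs(qgap - rgap) + 1),
                )
                score += s
                cigar.extend(cig)
            elif qgap > 0:
                score += ags.gap_open + ags.gap_extend * qgap
                cigar.append(("I", qgap))
            elif rgap > 0:
                score += ags.gap_open + ags.gap_extend * rgap
                cigar.append(("D", rgap))
        cigar.append(("M", f.length))
        score += ags.match * f.length

    # forward extension
    last = frags[-1]
    fscore, fq, fr, fcig = xdrop_extend(
        query_codes, ref, last.q_end, last.r_end, "forward", ags, dp, (seq_lo, seq_hi)
    )
    score += fscore
    cigar.extend(fcig)
    q_end = last.q_end + fq
    r_end = last.r_end + fr

    aln = Alignment(
        query_name=query_name,
        strand=pa.strand,
        ref_name=index.ref_names[si],
        r_start=r_start - seq_lo,
        r_end=r_end - seq_lo,
        q_start=q_start,
        q_end=q_end,
        query_length=len(query_codes),
        cigar=merge_cigar(cigar),
        score=int(score),
        )
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# Full Smith-Waterman oracle


def full_sw_oracle(query, ref, ags: AGSParams):
    """Exact unbanded local affine-gap alignment (quadratic DP, no
    heuristics).  Returns (score, (q_start, q_end), (r_start, r_end),
    cigar); an all-negative comparison yields score 0 and empty spans.
    """
    q = encode_seq(query)
    r = encode_seq(ref)
    n, m = len(q), len(r)
    if n == 0 or m == 0:
        raise ValueError("sequences must be nonempty")
    g1 = ags.gap_open + ags.gap_extend
    ge = ags.gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    jarr = np.arange(1, m + 1, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        rs = r
        sub = np.where((rs == qc) & (qc < 4) & (rs < 4), ags.match, ags.mismatch)
        diag = H[i - 1, :m] + sub
        E[i, 1:] = np.maximum(H[i - 1, 1:] + g1, E[i - 1, 1:] + ge)
        h0 = np.maximum(np.maximum(diag, E[i, 1:]), 0)
        hl = np.empty(m, dtype=np.int64)
        hl[0] = H[i, 0]
        hl[1:] = h0[:-1]
        t = hl - ge * (jarr - 1)
        c = np.maximum.accumulate(t)
        F[i, 1:] = g1 + ge * (jarr - 1) + c
        H[i, 1:] = np.maximum(h0, F[i, 1:])
        rowmax = int(H[i].max())
        if rowmax > best:
            best = rowmax
            bi = i
            bj = int(np.argmax(H[i]))
    if best == 0:
        return 0, (0, 0), (0, 0), []
    # traceback
    i, j = bi, bj
    ops = []
    state = "H"
    while H[i, j] != 0 or state != "H":
        if state == "H":
            if H[i, j] == 0:
                break
            s = ags.match if (q[i - 1] == r[j - 1] and q[i - 1] < 4 and r[j - 1] < 4) else ags.mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ops.append(("M", 1))
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover
                raise AssertionError("oracle traceback failed")
        elif state == "F":
            ops.append(("D", 1))
            if H[i, j - 1] + g1 == F[i, j]:
                state = "H"
            j -= 1
        else:
            ops.append(("I", 1))
            if H[i - 1, j] + g1 == E[i, j]:
                state = "H"
            i -= 1
    ops.reverse()
    return best, (i, bi), (j, bj), merge_cigar(ops)
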