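"""Shared helpers: base encoding, reverse complement, CIGAR arithmetic."""
from __future__ import annotations

import numpy as np

# 2-bit base codes; anything outside ACGT (case-insensitive) maps to the
# ambiguity code 4 and is never indexed, seeded, or scored as a match.
A, C, G, T, AMBIG_CODE = 0, 1, 2, 3, 4

_ENCODE_LUT = np.full(256, AMBIG_CODE, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
    _ENCODE_LUT[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT_LUT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq) -> np.ndarray:
    """Encode a DNA string (or bytes) as uint8 codes 0..4."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_LUT[codes[::-1]]


_RC_TABLE = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp_str(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# CIGAR helpers. A cigar is a list of (op, length) pairs with op one of
# 'M', 'I', 'D', 'S' ('I' consumes query, 'D' consumes reference).


def merge_cigar(ops):
    """Coalesce adjacent runs of the same operation; drop zero-length runs."""
    out = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def cigar_to_string(cigar) -> str:
    return "".join(f"{ln}{op}" for op, ln in cigar)


def cigar_from_string(s: str):
    out = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def cigar_query_len(cigar) -> int:
    return sum(ln for op, ln in cigar if op in "MIS=X")


def cigar_ref_len(cigar) -> int:
    return sum(ln for op, ln in cigar if op in "MD=X")


def rescore_cigar(q_codes: np.ndarray, r_codes: np.ndarray, ags, cigar) -> int:
    """Recompute the affine-gap score of an alignment from its CIGAR.

    ``q_codes``/``r_codes`` start at the aligned portion (soft clips in the
    cigar are skipped over on the query).  A gap of length L costs
    gap_open + gap_extend * L.
    """
    qi = ri = 0
    score = 0
    for op, ln in cigar:
        if op in ("M", "=", "X"):
            qs = q_codes[qi : qi + ln]
            rs = r_codes[ri : ri + ln]
            n_match = int(np.count_nonzero((qs == rs) & (qs < AMBIG_CODE)))
            score += ags.match * n_match + ags.mismatch * (ln - n_match)
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
        else:  # pragma: no cover - unknown op
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return score
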