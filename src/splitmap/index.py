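"""k-mer hash index over a 2-bit-packed reference.

The index records, for every k-mer key present in the reference, the sorted
list of reference start offsets (the Reference Offset Array, ROA).  Keys are
the 2-bit encoding of the k-mer (A=0, C=1, G=2, T=3, first base in the most
significant position), so lexicographic key order matches sequence order.
Multi-sequence references are concatenated into a single offset space with
per-sequence boundaries recorded; no seed spans a boundary.  Only the forward
strand is indexed; reverse-strand matches are found by aligning the
reverse-complemented query.

k-mers occurring more often than ``max_hits`` are either dropped entirely or,
when sampling is enabled, down-sampled uniformly without replacement to
exactly ``max_hits`` ascending offsets (reproducible from ``rng_seed``).

The on-disk key table is stored compressed: only keys with at least one
retained hit are kept, in ascending order, and looked up by binary search.
A dense 4^k table would need several gigabytes at k=15 for no correctness
benefit at the scales this package targets.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from ._util import AMBIG_CODE, encode_seq

AMBIGUOUS = -1
"""Sentinel hash key for k-mers containing a non-ACGT character."""

MAGIC = b"SSIX"
FORMAT_VERSION = 1


class IndexFormatError(ValueError):
    """Raised for bad magic bytes or an unsupported format version."""


class IndexCorruptionError(ValueError):
    """Raised when an index file is truncated or internally inconsistent."""


@dataclass(frozen=True)
class IndexParams:
    """Parameters controlling index construction.

    k: seed length in bases (<=15 so keys fit in 2k<=30 bits).
    skip: distance between successive indexed seed start positions (1..k).
    max_hits: maximum retained reference hits per k-mer.
    sampling: when True, over-represented k-mers are down-sampled to
        max_hits instead of being excluded.
    rng_seed: seed driving the down-sampling draws.
    """

    k: int = 15
    skip: int = 1
    max_hits: int = 650
    sampling: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not (1 <= self.k <= 15):
            raise ValueError("k must be in [1, 15]")
        if not (1 <= self.skip <= self.k):
            raise ValueError("skip must satisfy 1 <= skip <= k")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


def encode_kmer(seq, k: int | None = None) -> int:
    """Encode a k-base string as an integer key in [0, 4^k).

    Returns :data:`AMBIGUOUS` if any base is not one of ACGT (either case).
    Raises ValueError if ``k`` is given and the length does not match.
    """
    codes = encode_seq(seq)
    if k is not None and len(codes) != k:
        raise ValueError(f"expected a {k}-base k-mer, got length {len(codes)}")
    if np.any(codes >= AMBIG_CODE):
        return AMBIGUOUS
    key = 0
    for c in codes:
        key = (key << 2) | int(c)
    return key


def window_keys(codes: np.ndarray, k: int):
    """Vectorised keys of all k-windows of a code array.

    Returns (keys, valid): int64 keys for start positions 0..len-k and a
    boolean mask that is False where the window contains an ambiguous base.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    keys = np.zeros(n, dtype=np.int64)
    clean = np.minimum(codes, 3).astype(np.int64)
    for j in range(k):
        keys = (keys << 2) | clean[j : j + n]
    bad = (codes >= AMBIG_CODE).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return keys, valid


@dataclass
class Index:
    """Built index: packed reference plus the key table and ROA."""

    params: IndexParams
    ref_names: list[str]
    ref_lengths: np.ndarray  # int64, per-sequence lengths
    ref_offsets: np.ndarray  # int64, start of each sequence in concat space
    ref_codes: np.ndarray  # uint8 codes 0..4 of the concatenated reference
    ambig_positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    keys: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    key_starts: np.ndarray = field(default_factory=lambda: np.empty(1, np.int64))
    roa: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def total_length(self) -> int:
        return int(len(self.ref_codes))

    # -- coordinate helpers -------------------------------------------------
    def seq_index_of(self, offset: int) -> int:
        """Index of the sequence containing concatenated offset."""
        return int(np.searchsorted(self.ref_offsets, offset, side="right")) - 1

    def seq_bounds(self, seq_index: int) -> tuple[int, int]:
        lo = int(self.ref_offsets[seq_index])
        return lo, lo + int(self.ref_lengths[seq_index])

    def to_local(self, offset: int) -> tuple[str, int]:
        i = self.seq_index_of(offset)
        return self.ref_names[i], offset - int(self.ref_offsets[i])

    def ref_slice(self, start: int, end: int) -> np.ndarray:
        return self.ref_codes[start:end]

    # -- lookup -------------------------------------------------------------
    def lookup(self, key: int) -> np.ndarray:
        """Sorted reference offsets stored for ``key`` (possibly empty)."""
        if key == AMBIGUOUS:
            raise ValueError("cannot look up an ambiguous k-mer")
        i = int(np.searchsorted(self.keys, key))
        if i >= len(self.keys) or self.keys[i] != key:
            return np.empty(0, dtype=np.int64)
        return self.roa[self.key_starts[i] : self.key_starts[i + 1]]

    def lookup_batch(self, query_keys: np.ndarray):
        """For an array of keys return (starts, counts) into ``self.roa``.

        Keys absent from the table get count 0.
        """
        if len(self.keys) == 0:
            z = np.zeros(len(query_keys), dtype=np.int64)
            return z, z.copy()
        idx = np.minimum(np.searchsorted(self.keys, query_keys), len(self.keys) - 1)
        present = self.keys[idx] == query_keys
        starts = np.where(present, self.key_starts[idx], 0)
        counts = np.where(present, self.key_starts[idx + 1] - self.key_starts[idx], 0)
        return starts.astype(np.int64), counts.astype(np.int64)

    def __eq__(self, other):  # field-for-field, numpy-aware
        if not isinstance(other, Index):
            return NotImplemented
        return (
            self.params == other.params
            and self.ref_names == other.ref_names
            and np.array_equal(self.ref_lengths, other.ref_lengths)
            and np.array_equal(self.ref_offsets, other.ref_offsets)
            and np.array_equal(self.ref_codes, other.ref_codes)
            and np.array_equal(self.ambig_positions, other.ambig_positions)
            and np.array_equal(self.keys, other.keys)
            and np.array_equal(self.key_starts, other.key_starts)
            and np.array_equal(self.roa, other.roa)
        )


def build_index(reference, params: IndexParams | None = None) -> Index:
    """Build the hash index of a reference.

    ``reference`` is a mapping name->sequence or an iterable of (name, seq)
    pairs; sequences may be strings or uint8 code arrays.
    """
    if params is None:
        params = IndexParams()
    if hasattr(reference, "items"):
        items = list(reference.items())
    else:
        items = list(reference)
    if not items or all(len(s) == 0 for _, s in items):
        raise ValueError("reference must contain at least one non-empty sequence")

    names = []
    code_parts = []
    lengths = []
    for name, seq in items:
        names.append(str(name))
        codes = encode_seq(seq)
        code_parts.append(codes)
        lengths.append(len(codes))
    ref_codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.uint8)
    lengths = np.asarray(lengths, dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1])).astype(np.int64)

    k, skip = params.k, params.skip
    pos_parts = []
    key_parts = []
    for codes, off in zip(code_parts, offsets):
        keys, valid = window_keys(codes, k)
        if len(keys) == 0:
            continue
        grid = np.arange(0, len(keys), skip)
        ok = grid[valid[grid]]
        pos_parts.append(ok + off)
        key_parts.append(keys[ok])
    if pos_parts:
        positions = np.concatenate(pos_parts)
        pos_keys = np.concatenate(key_parts)
    else:
        positions = np.empty(0, np.int64)
        pos_keys = np.empty(0, np.int64)

    # stable sort by key keeps offsets ascending within each key
    order = np.argsort(pos_keys, kind="stable")
    roa = positions[order]
    sorted_keys = pos_keys[order]
    uniq, counts = np.unique(sorted_keys, return_counts=True)
    starts = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)

    over = counts > params.max_hits
    if np.any(over):
        if params.sampling:
            rng = np.random.default_rng(params.rng_seed)
            keep_keys, blocks = [], []
            for i in range(len(uniq)):
                block = roa[starts[i] : starts[i + 1]]
                if over[i]:
                    pick = rng.choice(len(block), size=params.max_hits, replace=False)
                    block = block[np.sort(pick)]
                keep_keys.append(uniq[i])
                blocks.append(block)
            uniq = np.asarray(keep_keys, dtype=np.int64)
            roa = np.concatenate(blocks) if blocks else np.empty(0, np.int64)
            counts = np.asarray([len(b) for b in blocks], dtype=np.int64)
        else:
            keep = ~over
            blocks = [roa[starts[i] : starts[i + 1]] for i in np.nonzero(keep)[0]]
            uniq = uniq[keep]
            counts = counts[keep]
            roa = np.concatenate(blocks) if blocks else np.empty(0, np.int64)
        starts = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)

    ambig_pos = np.nonzero(ref_codes >= AMBIG_CODE)[0]
    return Index(
        params=params,
        ref_names=names,
        ref_lengths=lengths,
        ref_offsets=offsets,
        ref_codes=ref_codes,
        ambig_positions=ambig_pos.astype(np.int64),
        keys=uniq.astype(np.int64),
        key_starts=starts,
        roa=roa.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Persistence: a single self-describing little-endian binary file.


def _pack_2bit(codes: np.ndarray) -> np.ndarray:
    clean = np.minimum(codes, 3).astype(np.uint8)
    pad = (-len(clean)) % 4
    if pad:
        clean = np.concatenate([clean, np.zeros(pad, np.uint8)])
    quads = clean.reshape(-1, 4)
    return (quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)).astype(np.uint8)


def _unpack_2bit(packed: np.ndarray, n: int) -> np.ndarray:
    out = np.empty(len(packed) * 4, dtype=np.uint8)
    out[0::4] = packed & 3
    out[1::4] = (packed >> 2) & 3
    out[2::4] = (packed >> 4) & 3
    out[3::4] = (packed >> 6) & 3
    return out[:n]


def _write_arr(f, arr: np.ndarray, dtype: str):
    data = np.ascontiguousarray(arr.astype(dtype)).tobytes()
    f.write(struct.pack("<q", len(arr)))
    f.write(data)


def _read_exact(f, n: int) -> bytes:
    data = f.read(n)
    if len(data) != n:
        raise IndexCorruptionError("index file is truncated")
    return data


def _read_arr(f, dtype: str) -> np.ndarray:
    (n,) = struct.unpack("<q", _read_exact(f, 8))
    if n < 0:
        raise IndexCorruptionError("negative array length in index file")
    item = np.dtype(dtype).itemsize
    return np.frombuffer(_read_exact(f, n * item), dtype=dtype).copy()


def write_index(index: Index, path) -> None:
    p = index.params
    ambig_pos = np.nonzero(index.ref_codes >= AMBIG_CODE)[0].astype(np.int64)
    with open(path, "wb") as f:
        f.write(MAGIC)
        f.write(struct.pack("<I", FORMAT_VERSION))
        f.write(struct.pack("<5q", p.k, p.skip, p.max_hits, int(p.sampling), p.rng_seed))
        f.write(struct.pack("<q", len(index.ref_names)))
        for name in index.ref_names:
            nb = name.encode("utf-8")
            f.write(struct.pack("<q", len(nb)))
            f.write(nb)
        _write_arr(f, index.ref_lengths, "<i8")
        f.write(struct.pack("<q", index.total_length))
        _write_arr(f, _pack_2bit(index.ref_codes), "<u1")
        _write_arr(f, ambig_pos, "<i8")
        _write_arr(f, index.keys, "<i8")
        _write_arr(f, index.key_starts, "<i8")
        _write_arr(f, index.roa, "<i8")


def read_index(path) -> Index:
    with open(path, "rb") as f:
        magic = _read_exact(f, 4)
        if magic != MAGIC:
            raise IndexFormatError(f"bad magic bytes {magic!r}; not an index file")
        (version,) = struct.unpack("<I", _read_exact(f, 4))
        if version != FORMAT_VERSION:
            raise IndexFormatError(f"unsupported index format version {version}")
        k, skip, max_hits, sampling, rng_seed = struct.unpack("<5q", _read_exact(f, 40))
        params = IndexParams(k=k, skip=skip, max_hits=max_hits, sampling=bool(sampling), rng_seed=rng_seed)
        (n_seq,) = struct.unpack("<q", _read_exact(f, 8))
        names = []
        for _ in range(n_seq):
            (nb,) = struct.unpack("<q", _read_exact(f, 8))
            names.append(_read_exact(f, nb).decode("utf-8"))
        lengths = _read_arr(f, "<i8")
        (total,) = struct.unpack("<q", _read_exact(f, 8))
        packed = _read_arr(f, "<u1")
        codes = _unpack_2bit(packed, total)
        ambig_pos = _read_arr(f, "<i8")
        codes[ambig_pos] = AMBIG_CODE
        keys = _read_arr(f, "<i8")
        key_starts = _read_arr(f, "<i8")
        roa = _read_arr(f, "<i8")
        if f.read(1):
            raise IndexCorruptionError("trailing bytes after index payload")
    if len(key_starts) != len(keys) + 1 or (len(keys) and key_starts[-1] != len(roa)):
        raise IndexCorruptionError("key table does not partition the ROA")
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1])).astype(np.int64) if n_seq else np.empty(0, np.int64)
    return Index(
        params=params,
        ref_names=names,
        ref_lengths=lengths,
        ref_offsets=offsets,
        ref_codes=codes,
        ambig_positions=ambig_pos,
        keys=keys,
        key_starts=key_starts,
        roa=roa,
    )
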