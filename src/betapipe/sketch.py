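"""Canonical-k-mer bottom-s MinHash sketching and the Mash distance.

A genome (assembled, or represented only by low-coverage reads) is reduced
to the ``s`` smallest 64-bit hash values over its canonical k-mers — a
bottom-s MinHash sketch. Comparing two sketches estimates the Jaccard index
``j`` of the underlying k-mer sets, and the Mash distance

    D = -ln(2j / (1 + j)) / k

converts that estimate into a per-base mutation-distance proxy. For read
input, k-mers observed fewer than ``m`` times are ignored (default m = 2),
which suppresses the large population of singleton k-mers created by
sequencing errors; assemblies default to m = 1 because their single-copy
k-mers are real.

Defaults follow the parameters used for low-coverage plant panels:
k = 21, s = 10000, m = 2.

Hashing: k-mers are 2-bit packed (A=0, C=1, G=2, T=3; canonical = the
lexicographically smaller of a window and its reverse complement, which
coincides with the numerically smaller packed code) and passed through a
splitmix64 finalizer seeded with 42. The hash identity is recorded in each
sketch's ``hash_tag``; sketches with different tags are never comparable.
"""

from __future__ import annotations

import base64
import gzip
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .simdata import ReadSet, encode_seq

__all__ = [
    "Sketch",
    "DEFAULT_K",
    "DEFAULT_S",
    "DEFAULT_M_READS",
    "HASH_TAG",
    "canonical_kmers",
    "canonical_kmer_codes",
    "hash_kmers",
    "build_sketch",
    "jaccard",
    "mash_distance",
    "save_sketches",
    "load_sketches",
]

DEFAULT_K = 21
DEFAULT_S = 10_000
DEFAULT_M_READS = 2
HASH_SEED = 42
HASH_TAG = f"splitmix64-{HASH_SEED}"

_U64 = np.uint64


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of 2-bit packed k-mer codes, vectorized.

    Complementing is bitwise NOT in every 2-bit lane; reversal swaps 2-bit
    groups, then nibbles, then bytes (in-place ops to limit temporaries).
    """
    m2 = _U64(0x3333333333333333)
    m4 = _U64(0x0F0F0F0F0F0F0F0F)
    x = np.bitwise_not(codes)
    t = x >> _U64(2)
    t &= m2
    x &= m2
    x <<= _U64(2)
    x |= t
    t = x >> _U64(4)
    t &= m4
    x &= m4
    x <<= _U64(4)
    x |= t
    x = x.byteswap()
    x >>= _U64(64 - 2 * k)
    return x


try:  # single-pass scan kernel; keeps allocations small and constant
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install here
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=False)
def _scan_kmers(enc, k, out_codes, out_pos):  # pragma: no cover - jit-compiled
    mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
    top = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    fwd = np.uint64(0)
    rc = np.uint64(0)
    run = 0
    m = 0
    for i in range(enc.size):
        b = enc[i]
        if b < 4:
            fwd = ((fwd << two) | np.uint64(b)) & mask
            rc = (rc >> two) | (np.uint64(3 - b) << top)
            run += 1
        else:
            run = 0
        if run >= k:
            out_codes[m] = fwd if fwd < rc else rc
            out_pos[m] = i - k + 1
            m += 1
    return m


_SCRATCH: dict[str, np.ndarray] = {}


def _scratch(name: str, size: int, dtype) -> np.ndarray:
    buf = _SCRATCH.get(name)
    if buf is None or buf.size < size:
        buf = np.empty(size, dtype=dtype)
        _SCRATCH[name] = buf
    return buf


def canonical_kmer_codes(
    encoded: np.ndarray, k: int, return_positions: bool = False
):
    """Canonical 2-bit packed codes of all valid k-windows of an encoded seq.

    ``encoded`` is a uint8 array with A,C,G,T as 0..3 and anything else
    (including record separators) >= 4; windows touching such symbols are
    skipped. With ``return_positions`` the window start offsets of the
    emitted codes are returned as a second array.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must fit in 62 bits (k <= 31)")
    n = encoded.size - k + 1
    empty = np.empty(0, dtype=_U64)
    if n <= 0:
        return (empty, np.empty(0, dtype=np.int64)) if return_positions else empty
    if _HAVE_NUMBA:
        out_codes = _scratch("codes", n, _U64)
        out_pos = _scratch("pos", n, np.int64)
        m = _scan_kmers(encoded, k, out_codes, out_pos)
        canon = out_codes[:m].copy()
        if return_positions:
            return canon, out_pos[:m].copy()
        return canon
    return _canonical_kmer_codes_numpy(encoded, k, return_positions)


def _canonical_kmer_codes_numpy(
    encoded: np.ndarray, k: int, return_positions: bool
):
    """Vectorized fallback used when the jit kernel is unavailable."""
    n = encoded.size - k + 1
    bad = np.concatenate(([0], np.cumsum((encoded >= 4).astype(np.int64))))
    ok = (bad[k:] - bad[:-k]) == 0
    clean = np.where(encoded < 4, encoded, 0).astype(_U64)
    # pack windows by doubling (O(log k) passes instead of k)
    pows: dict[int, np.ndarray] = {1: clean}
    p = 1
    while p * 2 <= k:
        c = pows[p]
        pows[p * 2] = (c[:-p] << _U64(2 * p)) | c[p:]
        p *= 2
    fwd = None
    covered = 0
    while p >= 1:
        if k & p:
            arr = pows[p]
            if fwd is None:
                fwd = arr[:n].copy()
            else:
                fwd <<= _U64(2 * p)
                fwd |= arr[covered : covered + n]
            covered += p
        p //= 2
    fwd = fwd[ok]
    if fwd.size == 0:
        canon = fwd
    else:
        rev = _revcomp_codes(fwd, k)
        canon = np.minimum(fwd, rev)
    if return_positions:
        return canon, np.nonzero(ok)[0]
    return canon


def canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield canonical k-mer strings for every valid window of ``seq``."""
    codes = canonical_kmer_codes(encode_seq(seq), k)
    shifts = [(k - 1 - j) * 2 for j in range(k)]
    for code in codes:
        c = int(code)
        yield "".join("ACGT"[(c >> s) & 3] for s in shifts)


def hash_kmers(codes: np.ndarray, seed: int = HASH_SEED) -> np.ndarray:
    """splitmix64 finalizer over packed k-mer codes (64-bit, seeded)."""
    with np.errstate(over="ignore"):
        z = codes.astype(_U64) ^ (_U64(seed) * _U64(0x9E3779B97F4A7C15))
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
        return z ^ (z >> _U64(31))


@dataclass(eq=False)
class Sketch:
    """Bottom-s MinHash sketch of one accession's canonical k-mer set."""

    name: str
    k: int
    s: int
    m: int
    hashes: np.ndarray  # sorted ascending, unique, <= s values
    hash_tag: str = HASH_TAG

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=_U64)
        if self.hashes.size > 1 and not (self.hashes[1:] > self.hashes[:-1]).all():
            raise ValueError("sketch hashes must be strictly increasing")
        if self.hashes.size > self.s:
            raise ValueError("sketch holds more hashes than its capacity s")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.name == other.name
            and (self.k, self.s, self.m, self.hash_tag)
            == (other.k, other.s, other.m, other.hash_tag)
            and self.hashes.size == other.hashes.size
            and bool(np.array_equal(self.hashes, other.hashes))
        )

    def __len__(self) -> int:
        return int(self.hashes.size)


def _gather_codes(source, k: int) -> np.ndarray:
    """Concatenate source sequences (separated by sentinels) and extract codes."""
    if isinstance(source, ReadSet):
        seqs: Sequence[str] = source.seqs
    elif isinstance(source, str):
        seqs = [source]
    else:
        seqs = list(source)
    if not seqs:
        raise ValueError("empty source: nothing to sketch")
    # join on a non-ACGT separator: one encode pass, windows never span reads
    return canonical_kmer_codes(encode_seq("\n".join(seqs)), k)


def build_sketch(
    source,
    name: str = "",
    k: int = DEFAULT_K,
    s: int = DEFAULT_S,
    m: int | None = None,
) -> Sketch:
    """Sketch a read set or assembled sequence(s).

    ``m`` (minimum k-mer copy number) defaults to 2 for read input and 1 for
    assembled sequences. Counting is exact: hash occurrence counts are
    tallied over the full input before the copy filter is applied.
    """
    if m is None:
        m = DEFAULT_M_READS if isinstance(source, ReadSet) else 1
    codes = _gather_codes(source, k)
    if codes.size == 0:
        raise ValueError("no valid k-mers in source")
    hashes = hash_kmers(codes)
    if m > 1:
        uniq, counts = np.unique(hashes, return_counts=True)
        qual = uniq[counts >= m]
    else:
        qual = np.unique(hashes)
    if qual.size == 0:
        raise ValueError(
            f"no k-mers pass the copy filter (m={m}); "
            "input may be too shallow (all k-mers are singletons)"
        )
    return Sketch(name=name, k=k, s=s, m=m, hashes=qual[:s])


def _check_compatible(a: Sketch, b: Sketch) -> None:
    for fname in ("k", "s", "hash_tag"):
        if getattr(a, fname) != getattr(b, fname):
            raise ValueError(
                f"sketches {a.name!r} and {b.name!r} differ in {fname}: "
                f"{getattr(a, fname)!r} vs {getattr(b, fname)!r}"
            )


def jaccard(a: Sketch, b: Sketch) -> tuple[float, int, int]:
    """Merged bottom-s Jaccard estimate: (j, shared, denom).

    X is the min(s, |union|) smallest values of the merged hash sets;
    shared counts members of X present in both sketches.
    """
    _check_compatible(a, b)
    union = np.union1d(a.hashes, b.hashes)
    x = union[: min(a.s, union.size)]
    shared = int(
        (
            np.isin(x, a.hashes, assume_unique=True)
            & np.isin(x, b.hashes, assume_unique=True)
        ).sum()
    )
    denom = int(x.size)
    if denom == 0:
        raise ValueError("cannot compare two empty sketches")
    return shared / denom, shared, denom


def mash_distance(j: float, k: int = DEFAULT_K) -> float:
    """Mash distance D = -ln(2j/(1+j))/k, capped to [0, 1]; j = 0 maps to 1."""
    if not (0.0 <= j <= 1.0):
        raise ValueError(f"jaccard estimate must be in [0, 1], got {j}")
    if j == 0.0:
        return 1.0
    return min(1.0, max(0.0, -math.log(2.0 * j / (1.0 + j)) / k))


# ---------------------------------------------------------------------------
# Sketch container I/O (JSON header + base64 hash block; gzip by extension)
# ---------------------------------------------------------------------------

_FORMAT = "betapipe-sketch-v1"


def _sketch_to_record(sk: Sketch) -> dict:
    return {
        "name": sk.name,
        "k": sk.k,
        "s": sk.s,
        "m": sk.m,
        "hash_tag": sk.hash_tag,
        "count": len(sk),
        "hashes": base64.b64encode(
            np.ascontiguousarray(sk.hashes).astype(">u8").tobytes()
        ).decode("ascii"),
    }


def _record_to_sketch(rec: dict, where: str) -> Sketch:
    for fname in ("name", "k", "s", "m", "hash_tag", "count", "hashes"):
        if fname not in rec:
            raise ValueError(f"{where}: sketch record missing field {fname!r}")
    hashes = np.frombuffer(base64.b64decode(rec["hashes"]), dtype=">u8").astype(_U64)
    if hashes.size != rec["count"]:
        raise ValueError(
            f"{where}: declared count {rec['count']} but {hashes.size} hashes stored"
        )
    return Sketch(
        name=rec["name"], k=rec["k"], s=rec["s"], m=rec["m"],
        hashes=hashes, hash_tag=rec["hash_tag"],
    )


def save_sketches(sketches: Iterable[Sketch], path: str) -> None:
    payload = {"format": _FORMAT, "sketches": [_sketch_to_record(s) for s in sketches]}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        json.dump(payload, fh)


def load_sketches(path: str) -> dict[str, Sketch]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        payload = json.load(fh)
    if payload.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} container")
    out: dict[str, Sketch] = {}
    for i, rec in enumerate(payload["sketches"]):
        sk = _record_to_sketch(rec, where=f"{path}[sketch {i}]")
        out[sk.name] = sk
    return out
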