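"""Low-level nucleotide utilities shared by the simulator and the annotator.

Sequences are handled as numpy ``uint8`` code arrays (A,C,G,T -> 0..3, any
other symbol -> 4) so that seeded ungapped extension and per-site mutation
are vectorized.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_LETTER = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: complement of codes 0..4 (N stays N)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _LETTER[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def extend_right(a: np.ndarray, b: np.ndarray, i: int, j: int, xdrop: int) -> int:
    """Ungapped X-drop extension of the diagonal starting at ``a[i]``/``b[j]``.

    Scores +1 per match, -1 per mismatch; extension stops once the running
    score falls ``xdrop`` below the best seen.  Returns the extension length
    ``L`` maximizing the score (the segment ``a[i:i+L]`` vs ``b[j:j+L]``).
    """
    n = min(len(a) - i, len(b) - j)
    if n <= 0:
        return 0
    m = a[i:i + n] == b[j:j + n]
    s = np.where(m, 1, -1).cumsum()
    best = np.maximum.accumulate(s)
    dropped = np.nonzero(best - s > xdrop)[0]
    stop = dropped[0] if dropped.size else n
    if stop == 0:
        return 0
    return int(np.argmax(s[:stop])) + 1


def extend_left(a: np.ndarray, b: np.ndarray, i: int, j: int, xdrop: int) -> int:
    """Mirror of :func:`extend_right`: extends the diagonal ending just
    before ``a[i]``/``b[j]`` leftwards and returns the extension length."""
    n = min(i, j)
    if n <= 0:
        return 0
    m = a[i - n:i][::-1] == b[j - n:j][::-1]
    s = np.where(m, 1, -1).cumsum()
    best = np.maximum.accumulate(s)
    dropped = np.nonzero(best - s > xdrop)[0]
    stop = dropped[0] if dropped.size else n
    if stop == 0:
        return 0
    return int(np.argmax(s[:stop])) + 1


def trim_to_match_run(a: np.ndarray, b: np.ndarray, start: int, end: int,
                      off: int, run: int) -> tuple[int, int]:
    """Trim segment ``a[start:end]`` vs ``b[start+off:end+off]`` so that both
    ends terminate in at least ``run`` consecutive matches.

    Returns the trimmed ``(start, end)``; ``(start, start)`` if no such run
    exists.  Used to pin detected repeat boundaries to solid sequence
    identity instead of isolated chance matches in the flanks.
    """
    if end - start < run:
        return start, start
    m = (a[start:end] == b[start + off:end + off]).astype(np.int32)
    if run <= 1:
        hit = np.nonzero(m)[0]
        if not hit.size:
            return start, start
        return start + int(hit[0]), start + int(hit[-1]) + 1
    w = np.convolve(m, np.ones(run, dtype=np.int32), mode="valid")
    full = np.nonzero(w == run)[0]
    if not full.size:
        return start, start
    return start + int(full[0]), start + int(full[-1]) + run


def segment_identity(a: np.ndarray, b: np.ndarray, start: int, end: int, off: int) -> float:
    if end <= start:
        return 0.0
    return float(np.mean(a[start:end] == b[start + off:end + off]))


def kmer_index(codes: np.ndarray, k: int) -> dict[int, list[int]]:
    """Exact k-mer index: packed integer k-mer -> sorted start positions.

    Windows containing non-ACGT symbols are skipped.  k is limited to 31 so
    the packed value fits an int64.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = len(codes) - k + 1
    if n <= 0:
        return {}
    c = codes.astype(np.int64)
    packed = np.zeros(n, dtype=np.int64)
    for t in range(k):
        packed = packed * 4 + c[t:t + n]
    valid = np.ones(n, dtype=bool)
    bad = np.nonzero(codes >= 4)[0]
    for p in bad:
        valid[max(0, p - k + 1):p + 1] = False
    index: dict[int, list[int]] = {}
    for pos in np.nonzero(valid)[0]:
        index.setdefault(int(packed[pos]), []).append(int(pos))
    return index


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mers of every window (int64; windows with non-ACGT are -1)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    packed = np.zeros(n, dtype=np.int64)
    for t in range(k):
        packed = packed * 4 + c[t:t + n]
    bad = np.nonzero(codes >= 4)[0]
    for p in bad:
        packed[max(0, p - k + 1):p + 1] = -1
    return packed
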