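"""Exact pairwise alignment (Needleman-Wunsch / Smith-Waterman with affine gaps).

This is the single aligner used across the pipeline: read-vs-template hit
emission in the simulator, pairwise identity for 97% clustering, and scoring
of located ANIb fragments. Scoring defaults are match +1, mismatch -1,
gap open -2, gap extend -1 (a gap of length k costs 2 + (k-1)).

Traceback is deterministic: on ties the diagonal move is preferred, then the
vertical (gap in the second sequence), then the horizontal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["Alignment", "align_pair", "pairwise_identity"]

_NEG = -(1 << 29)


@dataclass(frozen=True)
class Alignment:
    """Result of an optimal pairwise alignment.

    Coordinates are 0-based half-open on the input sequences; ``aln_length``
    counts alignment columns (including gap columns).
    """

    score: int
    identities: int
    aln_length: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def identity(self) -> float:
        """Fraction of identical columns over the alignment length."""
        return self.identities / self.aln_length if self.aln_length else 0.0


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
    _CODE[_c + 32] = _i


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_ext, local):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    X = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in b: consumes a ("up")
    Y = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in a: consumes b ("left")
    # predecessor state per cell: 0=M 1=X 2=Y 3=start
    pm = np.full((n + 1, m + 1), 3, np.uint8)
    px = np.full((n + 1, m + 1), 3, np.uint8)
    py = np.full((n + 1, m + 1), 3, np.uint8)

    M[0, 0] = 0
    if not local:
        for i in range(1, n + 1):
            X[i, 0] = -(gap_open + (i - 1) * gap_ext)
            px[i, 0] = 1 if i > 1 else 0
        for j in range(1, m + 1):
            Y[0, j] = -(gap_open + (j - 1) * gap_ext)
            py[0, j] = 2 if j > 1 else 0
    else:
        for i in range(n + 1):
            M[i, 0] = 0
        for j in range(m + 1):
            M[0, j] = 0

    best_s = 0 if local else _NEG
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 255) else mismatch
            # M: diagonal from best of the three states; ties prefer M, X, Y
            d = M[i - 1, j - 1]
            st = 0
            if X[i - 1, j - 1] > d:
                d = X[i - 1, j - 1]
                st = 1
            if Y[i - 1, j - 1] > d:
                d = Y[i - 1, j - 1]
                st = 2
            v = d + s
            if local and v < 0:
                v = 0
                st = 3
            if d > _NEG // 2:
                M[i, j] = v
                pm[i, j] = st
            # X (up): open from M/Y, extend X
            vx = _NEG
            sx = 3
            if M[i - 1, j] > _NEG // 2 and M[i - 1, j] - gap_open > vx:
                vx = M[i - 1, j] - gap_open
                sx = 0
            if X[i - 1, j] > _NEG // 2 and X[i - 1, j] - gap_ext > vx:
                vx = X[i - 1, j] - gap_ext
                sx = 1
            if Y[i - 1, j] > _NEG // 2 and Y[i - 1, j] - gap_open > vx:
                vx = Y[i - 1, j] - gap_open
                sx = 2
            X[i, j] = vx
            px[i, j] = sx
            # Y (left)
            vy = _NEG
            sy = 3
            if M[i, j - 1] > _NEG // 2 and M[i, j - 1] - gap_open > vy:
                vy = M[i, j - 1] - gap_open
                sy = 0
            if X[i, j - 1] > _NEG // 2 and X[i, j - 1] - gap_open > vy:
                vy = X[i, j - 1] - gap_open
                sy = 1
            if Y[i, j - 1] > _NEG // 2 and Y[i, j - 1] - gap_ext > vy:
                vy = Y[i, j - 1] - gap_ext
                sy = 2
            Y[i, j] = vy
            py[i, j] = sy
            if local and M[i, j] > best_s:
                best_s = M[i, j]
                best_i = i
                best_j = j

    if not local:
        best_i = n
        best_j = m
        best_s = M[n, m]
        state = 0
        if X[n, m] > best_s:
            best_s = X[n, m]
            state = 1
        if Y[n, m] > best_s:
            best_s = Y[n, m]
            state = 2
    else:
        state = 0

    # traceback
    i = best_i
    j = best_j
    ident = 0
    length = 0
    while i > 0 or j > 0:
        if state == 0:
            if local and M[i, j] == 0 and pm[i, j] == 3:
                break
            if i == 0 and j == 0:
                break
            prev = pm[i, j]
            if prev == 3 and not local:
                break
            length += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != 255:
                ident += 1
            i -= 1
            j -= 1
            if prev == 3:
                break
            state = prev
        elif state == 1:
            prev = px[i, j]
            length += 1
            i -= 1
            state = prev
        else:
            prev = py[i, j]
            length += 1
            j -= 1
            state = prev
    return best_s, ident, length, i, best_i, j, best_j


def align_pair(
    seq_a: str,
    seq_b: str,
    mode: str = "global",
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = 2,
    gap_extend: int = 1,
) -> Alignment:
    """Optimally align two nucleotide sequences.

    Parameters
    ----------
    mode
        ``"global"`` (end-to-end) or ``"local"`` (best-scoring subalignment).
    gap_open, gap_extend
        Penalties given as positive magnitudes; a gap of length k costs
        ``gap_open + (k - 1) * gap_extend``.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = _encode(seq_a)
    b = _encode(seq_b)
    score, ident, length, a0, a1, b0, b1 = _gotoh(
        a, b, match, mismatch, gap_open, gap_extend, mode == "local"
    )
    return Alignment(int(score), int(ident), int(length), int(a0), int(a1), int(b0), int(b1))


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical columns over the shorter length.

    This is the CD-HIT global-identity convention used by the 97% clustering.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_a == seq_b:
        return 1.0
    aln = align_pair(seq_a, seq_b, mode="global")
    return aln.identities / min(len(seq_a), len(seq_b))
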