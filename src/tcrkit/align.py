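"""Affine-gap Smith–Waterman local alignment.

The kernel is compiled with numba; a gap of length ``k`` scores
``gap_open + (k - 1) * gap_extend`` (both negative).  ``N`` counts as a
mismatch against everything, including another ``N``.

Two entry points: :func:`sw_score` (score only, rolling arrays — used for
candidate ranking) and :func:`smith_waterman` (full alignment with
traceback).  Tie-breaking is deterministic: the first maximal cell in
row-major (read-major) order is chosen and the traceback prefers
substitutions over gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

DEFAULT_SCORING = {"match": 2, "mismatch": -2, "gap_open": -3, "gap_extend": -1}

_N_BYTE = ord("N")


def encode(seq: str) -> np.ndarray:
    """Sequence as uint8 byte array (upper-case assumed)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read against a reference segment.

    Intervals are 0-based half-open; ``cigar`` is a list of
    ``(op, length)`` with ops ``"="`` (match), ``"X"`` (substitution),
    ``"I"`` (insertion in the read) and ``"D"`` (deletion from the read).
    """

    segment_name: str
    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    cigar: tuple[tuple[str, int], ...] = ()


@njit(cache=True)
def _sw_score_kernel(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], r.shape[0]
    NEG = -10**9
    H_prev = np.zeros(m + 1, dtype=np.int64)
    E_prev = np.full(m + 1, NEG, dtype=np.int64)  # gap in read (deletion) open along ref
    best = 0
    H_cur = np.zeros(m + 1, dtype=np.int64)
    E_cur = np.full(m + 1, NEG, dtype=np.int64)
    for i in range(1, n + 1):
        H_cur[0] = 0
        E_cur[0] = NEG
        F = NEG  # gap in ref (insertion in read), along current row
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi != _N_BYTE) else mismatch
            e = max(H_prev[j] + gap_open, E_prev[j] + gap_extend)
            F = max(H_cur[j - 1] + gap_open, F + gap_extend)
            h = H_prev[j - 1] + s
            if e > h:
                h = e
            if F > h:
                h = F
            if h < 0:
                h = 0
            H_cur[j] = h
            E_cur[j] = e
            if h > best:
                best = h
        H_prev, H_cur = H_cur, H_prev
        E_prev, E_cur = E_cur, E_prev
    return best


@njit(cache=True)
def _sw_full_kernel(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], r.shape[0]
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Fm = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi != _N_BYTE) else mismatch
            e = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_extend)
            f = max(H[i, j - 1] + gap_open, Fm[i, j - 1] + gap_extend)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            Fm[i, j] = f
            if h > best:  # strict: first maximum in row-major order wins
                best = h
                bi, bj = i, j
    # traceback from (bi, bj); prefer diagonal, then deletion (E), then insertion (F)
    ops = np.empty(n + m + 1, dtype=np.uint8)  # 0 '=', 1 'X', 2 'I'(read), 3 'D'(ref del)
    nops = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (q[i - 1] == r[j - 1] and q[i - 1] != _N_BYTE) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            ops[nops] = 0 if s == match else 1
            nops += 1
            i -= 1
            j -= 1
        elif H[i, j] == E[i, j]:
            # walk the read-gap (ref consumed? no: E consumes read) — E advances i
            k = i
            while True:
                ops[nops] = 2
                nops += 1
                k -= 1
                if E[k + 1, j] == H[k, j] + gap_open:
                    break
            i = k
        else:
            k = j
            while True:
                ops[nops] = 3
                nops += 1
                k -= 1
                if Fm[i, k + 1] == H[i, k] + gap_open:
                    break
            j = k
    return best, i, bi, j, bj, ops[:nops][::-1].copy()


_OP_CHARS = ("=", "X", "I", "D")


def sw_score(query: str | np.ndarray, ref: str | np.ndarray, scoring: dict | None = None) -> int:
    """Maximal local alignment score (affine gaps); score only, O(m) memory."""
    if isinstance(query, str):
        query = encode(query)
    if isinstance(ref, str):
        ref = encode(ref)
    if query.shape[0] == 0 or ref.shape[0] == 0:
        raise ValueError("empty sequence")
    sc = scoring or DEFAULT_SCORING
    return int(_sw_score_kernel(query, ref, sc["match"], sc["mismatch"], sc["gap_open"], sc["gap_extend"]))


def smith_waterman(
    query: str, ref: str, scoring: dict | None = None, segment_name: str = ""
) -> AlignmentHit | None:
    """Best local alignment of ``query`` against ``ref`` with traceback.

    Returns None for a degenerate (score 0) alignment — "no hit".
    """
    if not query or not ref:
        raise ValueError("empty sequence")
    sc = scoring or DEFAULT_SCORING
    q, r = encode(query), encode(ref)
    score, i0, i1, j0, j1, ops = _sw_full_kernel(
        q, r, sc["match"], sc["mismatch"], sc["gap_open"], sc["gap_extend"]
    )
    if score <= 0:
        return None
    cigar: list[tuple[str, int]] = []
    for op in ops:
        ch = _OP_CHARS[op]
        if cigar and cigar[-1][0] == ch:
            cigar[-1] = (ch, cigar[-1][1] + 1)
        else:
            cigar.append((ch, 1))
    # note: in the kernel, op "I" consumes read only and "D" consumes ref only
    return AlignmentHit(
        segment_name=segment_name,
        score=int(score),
        read_start=int(i0),
        read_end=int(i1),
        ref_start=int(j0),
        ref_end=int(j1),
        cigar=tuple(cigar),
    )


def map_ref_to_read(hit: AlignmentHit, ref_pos: int, read_length: int, max_extrapolate: int = 6) -> int | None:
    """Project a reference coordinate onto the read through an alignment.

    Inside the aligned interval the cigar is walked; a position falling in a
    read-insertion/ref-deletion gap is unmappable (None).  Up to
    ``max_extrapolate`` bases beyond either end of the aligned reference
    interval the projection is extended linearly; beyond that, None.
    """
    if ref_pos < hit.ref_start:
        d = hit.ref_start - ref_pos
        pos = hit.read_start - d
        return pos if d <= max_extrapolate and pos >= 0 else None
    if ref_pos >= hit.ref_end:
        d = ref_pos - hit.ref_end
        pos = hit.read_end + d
        return pos if d <= max_extrapolate and pos < read_length else None
    ri, qi = hit.ref_start, hit.read_start
    for op, length in hit.cigar:
        if op in ("=", "X"):
            if ri <= ref_pos < ri + length:
                return qi + (ref_pos - ri)
            ri += length
            qi += length
        elif op == "I":  # read-only bases
            qi += length
        elif op == "D":  # ref-only bases: ref position deleted from read
            if ri <= ref_pos < ri + length:
                return None
            ri += length
    return None
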