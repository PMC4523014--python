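"""Local affine-gap alignment with bisulfite-aware cytosine masking.

Bisulfite conversion turns unmethylated C into T, so a converted read
aligned against the untreated reference would be penalised at every
converted position, biasing alignment toward methylated molecules.  The
aligner therefore *masks* all reference cytosines: at a masked column a
read T scores as a match to the reference C.  Reverse-orientation reads
are reverse-complemented into the reference frame first, which turns
their G->A conversion pattern back into C->T, so the same masking rule
applies to both strands.

The dynamic program is the Gotoh three-state recurrence (match, gap in
read, gap in reference) with affine gap cost ``gap_open + L *
gap_extend`` for a gap of length ``L``, local (Smith-Waterman) boundary
conditions, and full traceback.  The inner loops are JIT-compiled with
numba so that aligning thousands of ~200 nt reads stays fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["Scoring", "PairwiseAlignment", "align_local", "encode", "revcomp"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

A, C, G, T = 0, 1, 2, 3


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; magnitudes follow common local-aligner defaults."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -12.0
    gap_extend: float = -2.0


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; anything else becomes 4 (never matches)."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for i, b in enumerate(seq.upper()):
        out[i] = _BASE_CODE.get(b, 4)
    return out


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


@njit(cache=True)
def _gotoh_fill(ref, mask, read, match, mismatch, gap_open, gap_extend):
    m = ref.size
    n = read.size
    neg = -1e18
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), neg, dtype=np.float64)  # gap in read
    F = np.full((n + 1, m + 1), neg, dtype=np.float64)  # gap in reference
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qb = read[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + gap_open + gap_extend
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + gap_open + gap_extend
            if fo > f:
                f = fo
            F[i, j] = f
            rb = ref[j - 1]
            if qb == rb or (mask[j - 1] and qb == T and rb == C):
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _gotoh_traceback(H, E, F, bi, bj, ref, mask, read,
                     match, mismatch, gap_open, gap_extend):
    # Columns of the alignment as (ref_index, read_index); -1 marks a gap.
    maxlen = H.shape[0] + H.shape[1]
    ref_idx = np.empty(maxlen, dtype=np.int64)
    read_idx = np.empty(maxlen, dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E (gap in read), 2 = F (gap in reference)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0.0:
                break
            rb = ref[j - 1]
            qb = read[i - 1]
            if qb == rb or (mask[j - 1] and qb == T and rb == C):
                s = match
            else:
                s = mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ref_idx[k] = j - 1
                read_idx[k] = i - 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            # consume a reference base not present in the read
            ref_idx[k] = j - 1
            read_idx[k] = -1
            k += 1
            if E[i, j] == E[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            # consume a read base not present in the reference (insertion)
            ref_idx[k] = -1
            read_idx[k] = i - 1
            k += 1
            if F[i, j] == F[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = 0
    return ref_idx[:k][::-1].copy(), read_idx[:k][::-1].copy()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local alignment of a read against the (masked) reference.

    ``pairs`` holds one (ref_index, read_index) per alignment column,
    with -1 marking a gap on that side.  Indices are 0-based into the
    forward reference and into the read *as aligned* (i.e. into its
    reverse complement when ``reverse`` is True).
    """

    score: float
    pairs: np.ndarray  # shape (L, 2)
    ref_start: int
    ref_end: int  # half-open
    reverse: bool


def align_local(
    read: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray,
    scoring: Scoring = Scoring(),
) -> PairwiseAlignment:
    """Best local alignment of an encoded read against an encoded
    reference, with read T matching reference C at masked columns."""
    H, E, F, best, bi, bj = _gotoh_fill(
        ref, mask, read,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    if best <= 0.0:
        return PairwiseAlignment(0.0, np.empty((0, 2), dtype=np.int64), 0, 0, False)
    ref_idx, read_idx = _gotoh_traceback(
        H, E, F, bi, bj, ref, mask, read,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    pairs = np.column_stack((ref_idx, read_idx))
    covered = ref_idx[ref_idx >= 0]
    if covered.size == 0:
        return PairwiseAlignment(0.0, np.empty((0, 2), dtype=np.int64), 0, 0, False)
    return PairwiseAlignment(
        score=float(best),
        pairs=pairs,
        ref_start=int(covered.min()),
        ref_end=int(covered.max()) + 1,
        reverse=False,
    )
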