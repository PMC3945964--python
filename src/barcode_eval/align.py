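"""Local alignment scoring for best-hit identification.

Smith-Waterman with affine gaps (Gotoh recurrences) over ungapped nucleotide
sequences, scored with the classic megablast-style scheme (match +2,
mismatch -3, gap open 5, gap extend 2) and summarized with Karlin-Altschul
statistics:

    bit = (lambda * S - ln K) / ln 2,      E = m * n * 2**(-bit)

where S is the raw score and m, n the sequence lengths.  The inner dynamic
program is jitted with numba when available; a pure-Python fallback keeps
the package importable without it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch rewards, affine gap costs and Karlin parameters.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    K: float = 0.41

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment: raw score, identity and significance."""

    score: int
    matches: int
    aln_length: int
    bit_score: float
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aln_length if self.aln_length else 0.0


def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = a.shape[0]
    n = b.shape[0]
    NEG = -(2**30)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    tb = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbe = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbf = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                tbe[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                tbf[i, j] = 1
            else:
                F[i, j] = f_open
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            tb[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback: count matches and total aligned columns of the best path
    matches = 0
    aln_len = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            p = tb[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            aln_len += 1
            cont = tbe[i, j]
            j -= 1
            if cont == 0:
                state = 0
        else:
            aln_len += 1
            cont = tbf[i, j]
            i -= 1
            if cont == 0:
                state = 0
    return best, matches, aln_len


try:  # numba speeds the O(m*n) kernel by ~100x; fall back gracefully
    from numba import njit as _njit

    _sw_kernel = _njit(cache=False)(_sw_kernel)
except ImportError:  # pragma: no cover
    pass

_ENCODE = {c: i for i, c in enumerate("ACGT")}


def _encode_ungapped(seq: str) -> np.ndarray:
    # ambiguity codes get unique negative values so they never match
    out = np.empty(len(seq), dtype=np.int8)
    unknown = -1
    for i, ch in enumerate(seq):
        code = _ENCODE.get(ch)
        if code is None:
            out[i] = unknown
            unknown -= 1
            if unknown < -120:
                unknown = -1
        else:
            out[i] = code
    return out


def bit_score(score: float, scheme: ScoringScheme) -> float:
    return (scheme.lam * score - math.log(scheme.K)) / math.log(2.0)


def expect_value(bits: float, m: int, n: int) -> float:
    return m * n * math.pow(2.0, -bits)


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> AlignmentHit:
    """Best local alignment of two ungapped nucleotide strings."""
    scheme = scheme or ScoringScheme()
    q = query.upper().replace("-", "")
    s = subject.upper().replace("-", "")
    if not q or not s:
        raise ValueError("sequences must be non-empty after gap removal")
    score, matches, aln_len = _sw_kernel(
        _encode_ungapped(q),
        _encode_ungapped(s),
        scheme.match,
        scheme.mismatch,
        scheme.gap_open,
        scheme.gap_extend,
    )
    bits = bit_score(score, scheme)
    return AlignmentHit(
        score=int(score),
        matches=int(matches),
        aln_length=int(aln_len),
        bit_score=bits,
        evalue=expect_value(bits, len(q), len(s)),
    )
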