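"""Independent reference implementations used only as test oracles.

Nothing here imports from tdgfquant's alignment internals: translation uses
its own codon table and the local aligner is a quadratic-space Gotoh DP.
Only the BLOSUM62 *data* is shared (loaded from Biopython), since the
matrix values themselves are published constants.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

# Standard genetic code written out via the classical TCAG index trick
# (bacterial table 11 differs only in start codons, which do not affect
# frame translation).
_BASES = "TCAG"
_AA_STRING = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = _B62.alphabet
_B62_ARR = np.array(_B62)
_IDX = {aa: i for i, aa in enumerate(_ALPHA)}


def oracle_translate(nt: str) -> str:
    """One-frame translation; N-containing codons -> X, stops -> *."""
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        aa.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(aa)


def oracle_six_frames(nt: str) -> dict[int, str]:
    nt = nt.upper()
    rc = "".join(_RC[c] for c in reversed(nt))
    return {
        1: oracle_translate(nt),
        2: oracle_translate(nt[1:]),
        3: oracle_translate(nt[2:]),
        -1: oracle_translate(rc),
        -2: oracle_translate(rc[1:]),
        -3: oracle_translate(rc[2:]),
    }


def oracle_sw_score(
    query: str, target: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Quadratic-space affine-gap Smith-Waterman (Gotoh) best score.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; score floors
    at 0 (empty local alignment).
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return 0.0
    qi = np.array([_IDX[a] for a in query])
    ti = np.array([_IDX[a] for a in target])
    sub = _B62_ARR[np.ix_(qi, ti)]  # n x m
    NEG = -1e18
    H_prev = np.zeros(m + 1)
    E_prev = np.full(m + 1, NEG)  # gap in target (vertical)
    best = 0.0
    for i in range(1, n + 1):
        H_cur = np.zeros(m + 1)
        E_cur = np.full(m + 1, NEG)
        F = NEG  # gap in query (horizontal), scalar along the row
        for j in range(1, m + 1):
            E_cur[j] = max(H_prev[j] - gap_open, E_prev[j] - gap_extend)
            F = max(H_cur[j - 1] - gap_open, F - gap_extend)
            h = max(0.0, H_prev[j - 1] + sub[i - 1, j - 1], E_cur[j], F)
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, E_prev = H_cur, E_cur
    return float(best)


def oracle_translated_search(
    query: str, nt: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Best SW score over all six frames, aligning stop-free segments only."""
    best = 0.0
    for frame in (1, 2, 3, -1, -2, -3):
        for seg in oracle_six_frames(nt)[frame].split("*"):
            if seg:
                best = max(best, oracle_sw_score(query, seg, gap_open, gap_extend))
    return best


def oracle_welch(a, b) -> tuple[float, float, float]:
    """Welch's t via scipy, plus Welch-Satterthwaite df recomputed."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)
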