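"""Independent oracles used by the tests.

These deliberately avoid the implementation paths they check: exact
rational arithmetic for the probability models, and a plain dictionary DP
plus exhaustive traceback enumeration for alignment.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hg_pmf_exact(b: int, N: int, B: int, n: int) -> Fraction:
    """Hypergeometric point mass as an exact rational."""
    if b < 0 or b > B or n - b > N - B or b > n:
        return Fraction(0)
    return Fraction(comb(B, b) * comb(N - B, n - b), comb(N, n))


def hg_tail_exact(b: int, N: int, B: int, n: int) -> Fraction:
    """Upper tail P(X >= b) as an exact rational."""
    upper = min(n, B)
    total = Fraction(0)
    for i in range(max(b, 0), upper + 1):
        total += hg_pmf_exact(i, N, B, n)
    return min(total, Fraction(1))


def binom_pmf_exact(k: int, n: int, q: Fraction) -> Fraction:
    return comb(n, k) * q**k * (1 - q) ** (n - k)


def map_label_exact(
    n_tx: int, n_m: int, N_tx: int, N_m: int, prior: Fraction, q: Fraction
) -> str:
    """Exact-rational MAP decision between the edit and no-edit models."""
    post_edit = prior * binom_pmf_exact(n_tx, n_tx + n_m, q)
    post_noedit = (1 - prior) * hg_pmf_exact(n_tx, N_tx + N_m, n_tx + n_m, N_tx)
    return "edit" if post_edit > post_noedit else "noise"


def affine_nw_score(read: str, ref: str, match=5, mismatch=-4, go=-20, ge=-1) -> float:
    """Plain three-state affine-gap global alignment score (dict DP)."""
    NEG = float("-inf")
    n, m = len(read), len(ref)
    M = {(0, 0): 0.0}
    D = {(0, 0): NEG}
    I = {(0, 0): NEG}
    for j in range(1, m + 1):
        D[(0, j)] = go + ge * (j - 1)
        M[(0, j)] = NEG
        I[(0, j)] = NEG
    for i in range(1, n + 1):
        I[(i, 0)] = go + ge * (i - 1)
        M[(i, 0)] = NEG
        D[(i, 0)] = NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[(i, j)] = s + max(M[(i - 1, j - 1)], D[(i - 1, j - 1)], I[(i - 1, j - 1)])
            D[(i, j)] = max(M[(i, j - 1)] + go, I[(i, j - 1)] + go, D[(i, j - 1)] + ge)
            I[(i, j)] = max(M[(i - 1, j)] + go, D[(i - 1, j)] + go, I[(i - 1, j)] + ge)
    return max(M[(n, m)], D[(n, m)], I[(n, m)])


def enumerate_optimal_deletion_positions(
    read: str, ref: str, match=5, mismatch=-4, go=-20, ge=-1
) -> set[int]:
    """Reference positions of the 5'-most deleted base over *all* optimal
    alignments (exhaustive traceback; small instances only)."""
    NEG = float("-inf")
    n, m = len(read), len(ref)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        D[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        I[i][0] = go + ge * (i - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            D[i][j] = max(M[i][j - 1] + go, I[i][j - 1] + go, D[i][j - 1] + ge)
            I[i][j] = max(M[i - 1][j] + go, D[i - 1][j] + go, I[i - 1][j] + ge)

    best = max(M[n][m], D[n][m], I[n][m])
    positions: set[int] = set()

    def walk(i, j, state, cols):
        if i == 0 and j == 0:
            # collect 5'-most deleted ref positions from the column trace
            ref_pos = -1
            k = 0
            cols_f = cols[::-1]
            while k < len(cols_f):
                kind = cols_f[k][0]
                if kind == "D":
                    positions.add(ref_pos + 1)
                    while k < len(cols_f) and cols_f[k][0] == "D":
                        ref_pos += 1
                        k += 1
                elif kind == "I":
                    while k < len(cols_f) and cols_f[k][0] == "I":
                        k += 1
                else:
                    ref_pos += 1
                    k += 1
            return
        if state == "M":
            s = match if read[i - 1] == ref[j - 1] else mismatch
            for prev in ("M", "D", "I"):
                val = {"M": M, "D": D, "I": I}[prev][i - 1][j - 1]
                if val + s == M[i][j]:
                    walk(i - 1, j - 1, prev, cols + [("M",)])
        elif state == "D":
            if j >= 1:
                if M[i][j - 1] + go == D[i][j]:
                    walk(i, j - 1, "M", cols + [("D",)])
                if I[i][j - 1] + go == D[i][j]:
                    walk(i, j - 1, "I", cols + [("D",)])
                if D[i][j - 1] + ge == D[i][j]:
                    walk(i, j - 1, "D", cols + [("D",)])
                if j == 1 and go + ge * 0 == D[i][j] and i == 0:
                    pass
        else:
            if i >= 1:
                if M[i - 1][j] + go == I[i][j]:
                    walk(i - 1, j, "M", cols + [("I",)])
                if D[i - 1][j] + go == I[i][j]:
                    walk(i - 1, j, "D", cols + [("I",)])
                if I[i - 1][j] + ge == I[i][j]:
                    walk(i - 1, j, "I", cols + [("I",)])

    for state, table in (("M", M), ("D", D), ("I", I)):
        if table[n][m] == best:
            walk(n, m, state, [])
    return positions
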