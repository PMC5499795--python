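"""Independent oracles used by the test suite.

These reimplement the checked quantities by a different route than the
package (explicit Gotoh dynamic programming, pair counting, grid search)
and stay deliberately naive.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def gotoh_score(a: str, b: str, gap_open: float = -10.0,
                gap_extend: float = -0.5) -> float:
    """Global affine-gap alignment optimum by the three-matrix recursion.

    End gaps are penalized; a gap of length k costs open + (k-1)*extend.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        k = max(n, m)
        return gap_open + (k - 1) * gap_extend if k else 0.0
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming a
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming b
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_B62[a[i - 1], b[j - 1]])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def ranksum_auc(scores, labels) -> float:
    """AUC as the probability a random positive outscores a random negative
    (ties count half), by exhaustive pair counting."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def grid_isoelectric_point(seq: str, step: float = 1e-3) -> float:
    """pI by fine-grid scan for the minimal |net charge|."""
    from rbdkit.chemdata import (ACIDIC_SIDECHAINS, BASIC_SIDECHAINS,
                                 CTERM_PKA, NTERM_PKA, SIDECHAIN_PKA)

    def charge(ph: float) -> float:
        q = 1.0 / (1.0 + 10 ** (ph - NTERM_PKA))
        q -= 1.0 / (1.0 + 10 ** (CTERM_PKA - ph))
        for res in seq:
            if res in BASIC_SIDECHAINS:
                q += 1.0 / (1.0 + 10 ** (ph - SIDECHAIN_PKA[res]))
            elif res in ACIDIC_SIDECHAINS:
                q -= 1.0 / (1.0 + 10 ** (SIDECHAIN_PKA[res] - ph))
        return q

    best_ph, best_abs = 0.0, abs(charge(0.0))
    ph = 0.0
    while ph <= 14.0:
        c = abs(charge(ph))
        if c < best_abs:
            best_ph, best_abs = ph, c
        ph += step
    return best_ph
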