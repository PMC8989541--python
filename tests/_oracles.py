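"""Independent oracles used by the test suite.

These are deliberately separate implementations from the package code:
a hand-written three-state affine-gap alignment DP and a hand-summed
nearest-neighbour thermodynamic Tm with frozen published constants.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def affine_alignment_oracle(
    a: str, b: str, gap_open: float = -1.0, gap_extend: float = -0.1
) -> float:
    """Global affine-gap alignment score by explicit three-matrix DP.

    Match +1, mismatch 0; a gap of length L costs gap_open +
    gap_extend*(L-1); end gaps are penalized.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in aligned pair
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


# SantaLucia (1998) unified DNA/DNA nearest-neighbour parameters
# (delta H kcal/mol, delta S cal/mol/K)
_NN_TABLE = {
    "init": (0.0, 0.0),
    "init_A/T": (2.3, 4.1),
    "init_G/C": (0.1, -2.8),
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _nn(dinuc: str) -> tuple[float, float]:
    key = f"{dinuc}/{_COMP[dinuc[0]]}{_COMP[dinuc[1]]}"
    if key in _NN_TABLE:
        return _NN_TABLE[key]
    rc = _COMP[dinuc[1]] + _COMP[dinuc[0]]
    return _NN_TABLE[f"{rc}/{_COMP[rc[0]]}{_COMP[rc[1]]}"]


def tm_oracle(
    seq: str, na_mm: float = 50.0, dnac1_nm: float = 25.0, dnac2_nm: float = 25.0
) -> float:
    """Nearest-neighbour Tm (deg C) against the perfect complement.

    Hand-summed stack enthalpies/entropies with terminal corrections,
    the 0.368*(N-1)*ln[Na+] entropy salt correction, and Tm =
    1000*dH / (dS + R*ln(CT/4)) - 273.15 with R = 1.987 cal/mol/K.
    """
    dH, dS = _NN_TABLE["init"]
    for end in (seq[0], seq[-1]):
        key = "init_A/T" if end in "AT" else "init_G/C"
        dH += _NN_TABLE[key][0]
        dS += _NN_TABLE[key][1]
    for i in range(len(seq) - 1):
        h, s = _nn(seq[i : i + 2])
        dH += h
        dS += s
    dS += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)
    ct = (dnac1_nm - dnac2_nm / 2.0) * 1e-9
    return 1000.0 * dH / (dS + 1.987 * math.log(ct)) - 273.15
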