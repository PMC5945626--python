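"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the alignment oracle is a
plain Gotoh dynamic programme maximised over reference substrings, the
binomial oracle an explicit pmf tail sum, and the protein oracle a direct
edit-translate-diff on strings.
"""

import math


def semiglobal_affine_score(
    ref: str, read: str, match: float = 1.0, mismatch: float = -2.0,
    gap_open: float = -5.0, gap_extend: float = -1.0,
) -> float:
    """Best score aligning the whole read against any substring of ref,
    affine gaps (a length-L gap costs gap_open + L * gap_extend)."""

    def global_affine(s: str, q: str) -> float:
        m, n = len(s), len(q)
        NEG = -1e18
        # three-state Gotoh: M ends in sub, X ends in ref-gap (deletion),
        # Y ends in read-gap (insertion)
        M = [[NEG] * (n + 1) for _ in range(m + 1)]
        X = [[NEG] * (n + 1) for _ in range(m + 1)]
        Y = [[NEG] * (n + 1) for _ in range(m + 1)]
        M[0][0] = 0.0
        for i in range(1, m + 1):
            X[i][0] = gap_open + i * gap_extend
        for j in range(1, n + 1):
            Y[0][j] = gap_open + j * gap_extend
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                sub = match if s[i - 1] == q[j - 1] else mismatch
                best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = best_prev + sub
                X[i][j] = max(
                    M[i - 1][j] + gap_open + gap_extend,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open + gap_extend,
                )
                Y[i][j] = max(
                    M[i][j - 1] + gap_open + gap_extend,
                    Y[i][j - 1] + gap_extend,
                    X[i][j - 1] + gap_open + gap_extend,
                )
        return max(M[m][n], X[m][n], Y[m][n])

    best = -math.inf
    for a in range(len(ref) + 1):
        for b in range(a, len(ref) + 1):
            best = max(best, global_affine(ref[a:b], read))
    return best


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by explicit pmf summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


GENCODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate from position 0; returns (peptide, stop_seen)."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = GENCODE[seq[i : i + 3]]
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False
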