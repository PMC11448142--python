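"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (dict-of-sets
IUPAC semantics, explicit offset enumeration, quadratic affine-gap DP) and
shares no code with the package's engines.
"""

from __future__ import annotations

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def compat(a: str, b: str) -> bool:
    return bool(IUPAC[a] & IUPAC[b])


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def brute_force_sites(
    primer_seq: str,
    orientation: str,
    template: str,
    min_match: int = 11,
    max_mm: int = 3,
    min3: int = 2,
    allow_overhang: bool = True,
):
    """Enumerate every primer placement and apply the qualification rules.

    Returns tuples (start, end, aligned_len, mm_count, mm_positions) sorted
    by start, with mm_positions indexed from the primer's 3' end.
    """
    fwd = orientation == "forward"
    scan = primer_seq if fwd else revcomp(primer_seq)
    k, L = len(scan), len(template)
    out = []
    for off in range(-k + 1, L):
        cols = [i for i in range(k) if 0 <= off + i < L]
        if not cols:
            continue
        overhang_left = off < 0
        overhang_right = off + k > L
        if fwd:
            if overhang_right:  # 3' end must stay on the template
                continue
            if overhang_left and not allow_overhang:
                continue
        else:
            if overhang_left:  # primer 3' end is scan column 0
                continue
            if overhang_right and not allow_overhang:
                continue
        mism = [i for i in cols if not compat(scan[i], template[off + i])]
        three = range(k - min3, k) if fwd else range(0, min3)
        if any(i not in cols or i in mism for i in three):
            continue
        if len(cols) < min_match or len(mism) > max_mm:
            continue
        mm_positions = tuple(sorted((k - i) if fwd else (i + 1) for i in mism))
        start = off + cols[0]
        out.append((start, start + len(cols), len(cols), len(mism), mm_positions))
    out.sort()
    return out


def local_align_score(a: str, b: str, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Best local (Smith-Waterman) affine-gap score; gap of length k costs
    gap_open + k * gap_extend.  Quadratic DP, small inputs only."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best
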