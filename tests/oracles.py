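"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the local aligner is
a naive full-matrix Gotoh with explicit traceback, and the codon-pathway
enumerator leans on Biopython's translator rather than the package's codon
tables.
"""

from __future__ import annotations

from typing import Dict, Tuple

from Bio.Seq import Seq

NEG = -(10 ** 9)


def sw_oracle(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> Dict[str, float]:
    """Naive quadratic-space Smith-Waterman with affine gaps and traceback.

    Gap of length L costs gap_open + L * gap_extend.  Returns the optimal
    score plus the statistics of one optimal alignment (diagonal-preferring
    traceback): matches, total columns, query/subject spans.
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - first)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - first)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best == 0:
        return {"score": 0, "matches": 0, "columns": 0,
                "q_span": (0, 0), "s_span": (0, 0)}
    i, j, state = bi, bj, "H"
    matches = columns = 0
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT":
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] - first:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] - first:
                state = "H"
            i -= 1
    return {
        "score": best,
        "matches": matches,
        "columns": columns,
        "q_span": (i, bi),
        "s_span": (j, bj),
    }


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def ng86_pair_oracle(c1: str, c2: str) -> Tuple[float, float]:
    """(Sd, Nd) by exhaustive enumeration of substitution orderings.

    Minimal pathways through stop codons are excluded; when every pathway is
    blocked, all pathways are averaged instead.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    clean, blocked = [], []

    def rec(cur: str, remaining, sd: float, nd: float, hit_stop: bool):
        if not remaining:
            (blocked if hit_stop else clean).append((sd, nd))
            return
        for p in remaining:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            stop = _translate_codon(nxt) == "*" and nxt != c2
            syn = _translate_codon(nxt) == _translate_codon(cur)
            rec(
                nxt,
                [q for q in remaining if q != p],
                sd + (1.0 if syn else 0.0),
                nd + (0.0 if syn else 1.0),
                hit_stop or stop,
            )

    rec(c1, diff, 0.0, 0.0, False)
    pool = clean if clean else blocked
    sd = sum(x for x, _ in pool) / len(pool)
    nd = sum(y for _, y in pool) / len(pool)
    return sd, nd


def ng86_sites_oracle(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops nonsynonymous)."""
    aa = _translate_codon(codon)
    s = 0.0
    for p in range(3):
        for alt in "ACGT":
            if alt == codon[p]:
                continue
            nxt = codon[:p] + alt + codon[p + 1 :]
            if _translate_codon(nxt) == aa and _translate_codon(nxt) != "*":
                s += 1.0 / 3.0
    return s
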