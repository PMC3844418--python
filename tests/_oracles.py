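"""Independent brute-force oracles used across the test suite.

Every oracle here recomputes a quantity by the most naive correct method —
exhaustive enumeration, linear scans, exact rational arithmetic — sharing no
code path with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_tail_fraction(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact upper-tail hypergeometric probability as a rational number."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return Fraction(total, denom)


def sw_enumerate(seq_a: str, seq_b: str, scheme) -> float:
    """Best local alignment score by explicit enumeration of alignment paths.

    Paths are sequences of match/insert/delete columns starting and ending
    on a match column (flanking gaps can only lower a local score); a gap of
    length L costs gap_open + L * gap_extend. Exponential — for tiny inputs
    only.
    """
    if not seq_a or not seq_b:
        return 0.0
    s = scheme.score
    gap1 = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    la, lb = len(seq_a), len(seq_b)
    best = 0.0

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "M" and score > best:
            best = score
        if i < la and j < lb:
            rec(i + 1, j + 1, score + s(seq_a[i], seq_b[j]), "M")
        if i < la:
            rec(i + 1, j, score - (ge if last == "I" else gap1), "I")
        if j < lb:
            rec(i, j + 1, score - (ge if last == "D" else gap1), "D")

    for i0 in range(la):
        for j0 in range(lb):
            rec(i0 + 1, j0 + 1, s(seq_a[i0], seq_b[j0]), "M")
    return best


def genes_overlapping_scan(genes, chrom: str, start: int, end: int):
    """Linear-scan interval overlap, sorted by (start, gene_id)."""
    hits = [g for g in genes if g.chrom == chrom and g.start < end and g.end > start]
    return sorted(hits, key=lambda g: (g.start, g.gene_id))


def adjacent_scan(genes, chrom: str, pos: int):
    """Full-scan nearest-flanker mapping: containing genes plus, per strand
    and side of the SNP, the closest non-containing gene."""
    on_chrom = [g for g in genes if g.chrom == chrom]
    picked = {g.gene_id: g for g in on_chrom if g.start <= pos < g.end}
    for strand in "+-":
        left = [g for g in on_chrom if g.strand == strand and g.end <= pos]
        if left:
            g = min(left, key=lambda g: (pos - g.end, g.start, g.gene_id))
            picked.setdefault(g.gene_id, g)
        right = [g for g in on_chrom if g.strand == strand and g.start > pos]
        if right:
            g = min(right, key=lambda g: (g.start - pos, g.start, g.gene_id))
            picked.setdefault(g.gene_id, g)
    return sorted(picked.values(), key=lambda g: (g.start, g.gene_id))
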