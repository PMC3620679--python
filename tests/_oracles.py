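"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exact rational arithmetic, per-base
boolean arrays, character-by-character scans.  None of it shares code with
the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration in rationals."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_stepup(pvals: list[float]) -> list[float]:
    """Hand-applied Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


def per_base_occupancy_merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merged regions by pairwise union-find on shared bases.

    Two intervals belong to the same region iff they are connected through
    a chain of intervals each sharing >= 1 base (so half-open abutment does
    NOT connect them).  O(n^2), fine for test sizes.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and min(ei, ej) - max(si, sj) > 0:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        chrom = intervals[members[0]][0]
        out.append((chrom,
                    min(intervals[i][1] for i in members),
                    max(intervals[i][2] for i in members)))
    return out


def per_base_intersection(
    region: tuple[str, int, int],
    spots: list[tuple[str, int, int]],
    min_overlap: int = 1,
) -> tuple[int, int, bool]:
    """(n_spots_overlapped, covered_bases, contains_full_spot) by per-base scan."""
    chrom, rs, re_ = region
    mask = np.zeros(re_ - rs, dtype=bool)
    n_hits = 0
    full = False
    for c, ss, se in spots:
        if c != chrom:
            continue
        lo, hi = max(rs, ss), min(re_, se)
        if hi - lo >= min_overlap:
            n_hits += 1
            mask[lo - rs:hi - rs] = True
            if rs <= ss and se <= re_:
                full = True
    return n_hits, int(mask.sum()), full


def naive_motif_count(seq: str, pattern: str, both_strands: bool = True) -> int:
    """Sliding-window scan with explicit IUPAC set membership."""
    def matches_at(s: str, pat: str, i: int) -> bool:
        return all(s[i + j] in IUPAC_SETS[pat[j]] for j in range(len(pat)))

    pats = [pattern]
    if both_strands:
        rc = "".join(_COMP[c] for c in reversed(pattern))
        if rc != pattern:
            pats.append(rc)
    hits = set()
    for pat in pats:
        for i in range(len(seq) - len(pat) + 1):
            if matches_at(seq, pat, i):
                hits.add(i)
    return len(hits)


def permutation_rank_sum_p(x, y, n_perm: int, seed: int) -> float:
    """Two-sided permutation p-value for the rank-sum statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    # midranks for ties
    order = np.argsort(pooled)
    sorted_vals = pooled[order]
    ranks_sorted = np.arange(1, len(pooled) + 1, dtype=float)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks_sorted[i:j + 1] = ranks_sorted[i:j + 1].mean()
        i = j + 1
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    nx = len(x)
    obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2.0
    perm = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(len(pooled))[:nx]
        perm[k] = ranks[idx].sum()
    return float(np.mean(np.abs(perm - mu) >= abs(obs - mu) - 1e-9))
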