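"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately written from first principles —
enumeration, literal sums, O(n^2) pair loops — and shares no code with
the package implementations it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def fisher_two_sided(table) -> Fraction:
    """Two-sided Fisher exact p by full enumeration of all tables with
    the observed margins; tie rule w <= w_obs * (1 + 1e-7) applied with
    exact integer arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    extreme = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        total += w
        # w <= w_obs * (1 + 1e-7), exactly
        if w * 10_000_000 <= w_obs * 10_000_001:
            extreme += w
    return Fraction(extreme, total)


def phi_st_bruteforce(alleles_by_pop: list[list[int]]) -> float:
    """Single-locus AMOVA phi_ST from explicit pairwise 0/1 distances."""
    k = len(alleles_by_pop)
    ns = [len(a) for a in alleles_by_pop]
    N = sum(ns)
    flat = [x for pop in alleles_by_pop for x in pop]

    def ssd(items):
        n = len(items)
        s = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                s += 1.0 if items[i] != items[j] else 0.0
        return s / n

    ssd_total = ssd(flat)
    ssd_within = sum(ssd(pop) for pop in alleles_by_pop)
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (k - 1)
    sigma_w = ssd_within / (N - k)
    n0 = (N - sum(n * n for n in ns) / N) / (k - 1)
    sigma_a = (ms_among - sigma_w) / n0
    return sigma_a / (sigma_a + sigma_w)


def site_pi_bruteforce(counts: list[int]) -> Fraction:
    """Fraction of unordered allele pairs that differ, by enumeration."""
    alleles = [i for i, c in enumerate(counts) for _ in range(c)]
    n = len(alleles)
    pairs = diff = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if alleles[i] != alleles[j]:
                diff += 1
    return Fraction(diff, pairs)


def tajimas_d_oracle(S: int, k_hat: float, n: int) -> float:
    """Step-by-step Tajima statistic for integer sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def naive_filter(records, thresholds, pop_masks):
    """Reference reimplementation of the full site-filter cascade.

    Returns (kept_keys, removed_by_rule) with keys (unigene, pos).
    Cluster detection scans every possible window start coordinate.
    """
    t = thresholds
    by_gene: dict[str, list[int]] = {}
    for r in records:
        by_gene.setdefault(r.unigene_id, []).append(r.pos)
    clustered = set()
    for gene, positions in by_gene.items():
        for w in range(1, max(positions) + 1):
            inside = [p for p in positions if w <= p <= w + t.cluster_window - 1]
            if len(inside) > t.cluster_max_snps:
                clustered.update((gene, p) for p in inside)

    kept = []
    removed = {}

    def hit(rule):
        removed[rule] = removed.get(rule, 0) + 1

    for r in records:
        gts = list(r.genotypes)
        if (r.fs is None and t.strict_info) or (r.fs is not None and r.fs > t.fs_max):
            hit("fs")
            continue
        if (r.qd is None and t.strict_info) or (r.qd is not None and r.qd < t.qd_min):
            hit("qd")
            continue
        if (r.unigene_id, r.pos) in clustered:
            hit("snp_cluster")
            continue
        if (r.depth is None and t.strict_info) or (
            r.depth is not None and r.depth < t.depth_min
        ):
            hit("depth")
            continue
        short = False
        for mask in pop_masks.values():
            called = sum(
                1 for g, m in zip(gts, mask) if m and g != -1
            )
            if called < t.min_called_per_pop:
                short = True
        if short:
            hit("min_called_per_pop")
            continue
        called_gts = [g for g in gts if g != -1]
        copies = 2 * len(called_gts)
        if copies == 0:
            hit("maf")
            continue
        alt = sum(called_gts)
        maf = min(alt / copies, 1 - alt / copies)
        if maf < t.maf_min:
            hit("maf")
            continue
        kept.append((r.unigene_id, r.pos))
    return kept, removed
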