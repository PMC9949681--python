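"""Independent brute-force oracles used by the tests.

Each function is a literal transcription of the defining formula or a naive
enumeration, kept free of any code path from the package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def wc_fst_oracle(gtA: list[list[tuple[int, int]]], gtB: list[list[tuple[int, int]]]) -> float:
    """Weir & Cockerham (1984) theta-hat for two populations, ratio of sums.

    ``gtA``/``gtB`` are per-site lists of diploid genotypes (allele pairs).
    Scalar arithmetic straight from the published component definitions.
    """
    num = den = 0.0
    r = 2
    for site_a, site_b in zip(gtA, gtB):
        stats = []
        for site in (site_a, site_b):
            n_i = len(site)
            p_i = sum(a + b for a, b in site) / (2 * n_i)
            h_i = sum(1 for a, b in site if a != b) / n_i
            stats.append((n_i, p_i, h_i))
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def d_stat_oracle(p1, p2, p3, pO) -> float:
    """Per-site double loop over the ABBA/BABA definition."""
    abba_sum = baba_sum = 0.0
    for a, b, c, d in zip(p1, p2, p3, pO):
        abba_sum += (1 - a) * b * c * (1 - d)
        baba_sum += a * (1 - b) * c * (1 - d)
    if abba_sum + baba_sum == 0:
        return float("nan")
    return (abba_sum - baba_sum) / (abba_sum + baba_sum)


def fd_oracle(p1, p2, p3, pO) -> float:
    """f_d with the per-site max(P2, P3) dynamic donor, scalar arithmetic."""
    num = den = 0.0
    for a, b, c, d in zip(p1, p2, p3, pO):
        num += (1 - a) * b * c * (1 - d) - a * (1 - b) * c * (1 - d)
        pd_ = max(b, c)
        den += (1 - a) * pd_ * pd_ * (1 - d) - a * (1 - pd_) * pd_ * (1 - d)
    if d_stat_oracle(p1, p2, p3, pO) < 0 or den <= 0:
        return float("nan")
    return num / den


def copy_path_cost_oracle(target, templates, lam) -> float:
    """Exhaustive minimum over all template paths (n_templates ** n_sites)."""
    n_sites, n_templates = templates.shape
    best = float("inf")
    for path in itertools.product(range(n_templates), repeat=n_sites):
        mism = sum(
            1
            for i, j in enumerate(path)
            if target[i] != -1 and templates[i, j] != -1 and target[i] != templates[i, j]
        )
        switches = sum(1 for k in range(1, n_sites) if path[k] != path[k - 1])
        best = min(best, mism + lam * switches)
    return best


def merge_intervals_oracle(intervals, max_gap=0):
    """Naive O(n^2) interval union with gap joining."""
    ivs = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if not (a[1] + max_gap < b[0] or b[1] + max_gap < a[0]):
                    ivs[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del ivs[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in ivs)


def mst_weight_oracle(dist: np.ndarray) -> float:
    """Kruskal with an explicit union-find over the full distance matrix."""
    n = dist.shape[0]
    edges = sorted(
        (dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    total = 0.0
    used = 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
            total += w
            used += 1
            if used == n - 1:
                break
    return total


def overlap_pairs_oracle(set_a, set_b, min_overlap=1):
    """Quadratic intersection of two interval sets -> set of (i, j) pairs."""
    hits = set()
    for i, (ca, sa, ea) in enumerate(set_a):
        for j, (cb, sb, eb) in enumerate(set_b):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap:
                hits.add((i, j))
    return hits
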