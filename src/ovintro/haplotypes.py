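"""Candidate-region haplotype analysis: MAF filtering, recombinant screening,
haplogroup clustering, per-breed frequency tables and pairwise-difference
networks (minimum spanning tree over Hamming distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel, PopMap, Window, sites_in_window


@dataclass
class RegionHaplotypes:
    """Phased haplotypes of one region after MAF filtering.

    ``matrix`` has one row per haplotype over the retained sites; entries are
    0/1/MISSING. ``breeds`` maps each haplotype id to its breed.
    """

    region: Window
    positions: np.ndarray
    matrix: np.ndarray
    hap_ids: list[str]
    breeds: dict[str, str]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Haplogroup:
    """Cluster of near-identical haplotypes in a region."""

    label: str
    members: list[str]
    consensus: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


def extract_region(
    panel: HaplotypePanel,
    popmap: PopMap,
    region: Window,
    maf_min: float = 0.05,
) -> RegionHaplotypes:
    """Extract phased haplotypes of ``region``, dropping sites with minor
    allele frequency <= ``maf_min`` (computed over non-missing alleles).

    Raises if no polymorphic site survives the filter.
    """
    sl = sites_in_window(panel, region)
    pos = panel.positions[region.contig][sl]
    mat = panel.alleles[region.contig][sl].T  # (haps, sites)
    valid = mat != MISSING
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, mat, 0).sum(axis=0) / np.where(n > 0, n, 1)
    maf = np.minimum(p, 1 - p)
    keep = (n > 0) & (maf > maf_min)
    if not keep.any():
        raise ValueError(
            f"no site with MAF > {maf_min} in {region.contig}:{region.start}-{region.end}"
        )
    hap_ids = panel.haplotype_ids
    breeds = {
        f"{s}_h{k}": popmap.sample_breed.get(s, "?") for s in panel.samples for k in (0, 1)
    }
    return RegionHaplotypes(region, pos[keep], mat[:, keep], hap_ids, breeds)


def _pair_mismatch(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance over sites non-missing in both haplotypes."""
    both = (a != MISSING) & (b != MISSING)
    return int(np.sum((a != b) & both))


def _site_mismatch(hap: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    both = (hap != MISSING) & (consensus != MISSING)
    return ((hap != consensus) & both).astype(np.int64)


def screen_recombinants(
    rh: RegionHaplotypes, k_major: int = 3, min_advantage: int = 5
) -> tuple[list[str], list[str]]:
    """Flag haplotypes that look like two-segment chimeras of major haplotypes.

    The ``k_major`` largest classes of identical haplotypes seed the consensus
    set; a haplotype is flagged recombinant when its best single-breakpoint
    chimera of two consensus strings scores at least ``min_advantage`` fewer
    mismatches than its best single consensus. Returns (kept, flagged)
    haplotype ids.
    """
    strings, counts = np.unique(rh.matrix, axis=0, return_counts=True)
    if len(strings) < k_major:
        warnings.warn(
            f"only {len(strings)} distinct haplotypes; reducing k_major", stacklevel=2
        )
        k_major = len(strings)
    order = np.argsort(-counts, kind="stable")
    consensus = strings[order[:k_major]]

    kept: list[str] = []
    flagged: list[str] = []
    n = rh.n_sites
    for row, hap_id in zip(rh.matrix, rh.hap_ids):
        mism = np.stack([_site_mismatch(row, c) for c in consensus])  # (k, n)
        totals = mism.sum(axis=1)
        d_single = int(totals.min())
        pref = np.concatenate(
            [np.zeros((len(consensus), 1), dtype=np.int64), np.cumsum(mism, axis=1)], axis=1
        )  # pref[c, j] = mismatches of consensus c on sites [0, j)
        left_best = pref.min(axis=0)  # best prefix donor per breakpoint
        right_best = (totals[:, None] - pref).min(axis=0)
        d_chimera = int((left_best + right_best).min())
        if d_single - d_chimera >= min_advantage:
            flagged.append(hap_id)
        else:
            kept.append(hap_id)
    return kept, flagged


def cluster_haplogroups(
    rh: RegionHaplotypes, max_diff_frac: float = 0.05, hap_ids: Sequence[str] | None = None
) -> list[Haplogroup]:
    """Single-linkage clustering of haplotypes at Hamming distance
    <= max_diff_frac * n_sites (pairwise-complete over missing data).

    Groups are ordered by size (largest first, ties by smallest member id) and
    labelled hap-1, hap-2, ... Consensus is the per-site majority allele.
    """
    ids = list(hap_ids) if hap_ids is not None else list(rh.hap_ids)
    index = {h: i for i, h in enumerate(rh.hap_ids)}
    rows = np.array([index[h] for h in ids])
    mat = rh.matrix[rows]
    n = len(ids)
    cutoff = max_diff_frac * rh.n_sites

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _pair_mismatch(mat[i], mat[j]) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(
        clusters.values(), key=lambda m: (-len(m), min(ids[i] for i in m))
    )
    groups = []
    for k, members in enumerate(ordered, 1):
        sub = mat[members]
        valid = sub != MISSING
        ones = np.where(valid, sub, 0).sum(axis=0)
        votes = valid.sum(axis=0)
        consensus = (ones * 2 > votes).astype(np.int8)
        groups.append(
            Haplogroup(
                label=f"hap-{k}",
                members=sorted(ids[i] for i in members),
                consensus=consensus,
            )
        )
    return groups


def haplogroup_frequencies(
    groups: Sequence[Haplogroup], popmap: PopMap
) -> pd.DataFrame:
    """Per-breed (and overall) haplogroup carrier counts and frequencies.

    Frequencies are reported as carriers/total and round-half-even to three
    decimals; the exact fraction is recoverable from the count columns.
    """
    breed_of = {}
    for g in groups:
        for hap in g.members:
            sample, _, _ = hap.rpartition("_h")
            breed = popmap.sample_breed.get(sample)
            if breed is None:
                raise KeyError(f"sample {sample!r} of haplotype {hap!r} unmapped")
            breed_of[hap] = breed
    totals: dict[str, int] = {}
    for hap, breed in breed_of.items():
        totals[breed] = totals.get(breed, 0) + 1
    grand_total = len(breed_of)

    rows = []
    for g in groups:
        by_breed: dict[str, int] = {}
        for hap in g.members:
            by_breed[breed_of[hap]] = by_breed.get(breed_of[hap], 0) + 1
        for breed in sorted(totals):
            c = by_breed.get(breed, 0)
            rows.append(
                {
                    "haplogroup": g.label,
                    "breed": breed,
                    "carriers": c,
                    "total": totals[breed],
                    "freq": round(c / totals[breed], 3),
                }
            )
        rows.append(
            {
                "haplogroup": g.label,
                "breed": "overall",
                "carriers": g.size,
                "total": grand_total,
                "freq": round(g.size / grand_total, 3),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HaploNetwork:
    """Pairwise-difference haplotype network.

    ``graph`` holds one node per distinct haplotype (attributes ``count`` and
    ``members``); every pairwise edge carries its Hamming ``weight`` plus
    boolean flags ``mst`` (minimum-spanning-tree membership) and
    ``alternative`` (non-MST edge that could replace an MST edge on the cycle
    it closes without increasing total weight).
    """

    graph: nx.Graph

    @property
    def mst_edges(self) -> list[tuple[str, str]]:
        return [
            (u, v) for u, v, d in self.graph.edges(data=True) if d["mst"]
        ]

    def total_mst_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True) if d["mst"]))


def build_network(rh: RegionHaplotypes, hap_ids: Sequence[str] | None = None) -> HaploNetwork:
    """Collapse identical haplotypes and build an MST network over Hamming
    distances, with deterministic tie-breaking by node label.
    """
    ids = list(hap_ids) if hap_ids is not None else list(rh.hap_ids)
    index = {h: i for i, h in enumerate(rh.hap_ids)}
    classes: dict[bytes, list[str]] = {}
    reps: dict[bytes, np.ndarray] = {}
    for h in ids:
        row = rh.matrix[index[h]]
        key = row.tobytes()
        classes.setdefault(key, []).append(h)
        reps[key] = row
    if len(classes) < 2:
        raise ValueError("need at least two distinct haplotypes to build a network")

    labels = {key: sorted(members)[0] for key, members in classes.items()}
    keys = sorted(classes, key=lambda k: labels[k])
    g = nx.Graph()
    for key in keys:
        g.add_node(labels[key], count=len(classes[key]), members=sorted(classes[key]))
    edges = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            w = _pair_mismatch(reps[keys[i]], reps[keys[j]])
            edges.append((labels[keys[i]], labels[keys[j]], w))
    edges.sort(key=lambda e: (e[2], e[0], e[1]))
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, mst=False, alternative=False)

    mst = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    for u, v in mst.edges:
        g.edges[u, v]["mst"] = True
    # alternative edges: closing a cycle whose heaviest MST edge is no lighter
    for u, v, d in g.edges(data=True):
        if d["mst"]:
            continue
        path = nx.shortest_path(mst, u, v)
        path_max = max(
            mst.edges[path[k], path[k + 1]]["weight"] for k in range(len(path) - 1)
        )
        if d["weight"] <= path_max:
            d["alternative"] = True
    return HaploNetwork(g)


def network_edge_table(net: HaploNetwork) -> pd.DataFrame:
    rows = [
        {"u": u, "v": v, "weight": d["weight"], "mst": d["mst"], "alternative": d["alternative"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows).sort_values(["weight", "u", "v"]).reset_index(drop=True)
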