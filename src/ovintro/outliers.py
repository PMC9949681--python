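"""Introgressed-tract frequency profiles across meta-populations, outlier
selection, high-F_ST region construction and region overlap annotation.

A candidate tract's frequency in a meta-population is the fraction of its
haplotypes whose same-source ancestry covers at least ``coverage_frac`` of the
candidate interval; outliers are long (>= 100 kb), non-rare (total frequency
>= 0.05) tracts whose frequency varies strongly across meta-populations
(SD > 0.1) — conserved within but not across populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lai import AncestryTract
from .panel import PopMap


@dataclass
class FrequencyProfile:
    """Per-meta-population carrier frequencies of one candidate tract."""

    contig: str
    start: int
    end: int
    source: str
    freq_by_pop: dict[str, float]
    total_freq: float
    sd: float
    range_: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HighFstRegion:
    """Run of significant high-F_ST windows joined across gaps <= join_gap."""

    contig: str
    start: int
    end: int
    n_windows: int
    min_p: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _hap_sample(hap_id: str) -> str:
    sample, sep, _ = hap_id.rpartition("_h")
    if not sep:
        raise ValueError(f"haplotype id {hap_id!r} not of the form <sample>_h<phase>")
    return sample


def _overlap_bp(intervals: np.ndarray, start: int, end: int) -> int:
    """Total bp of [start, end) covered by the (sorted, disjoint) intervals."""
    if len(intervals) == 0:
        return 0
    lo = np.minimum(np.maximum(intervals[:, 0], start), end)
    hi = np.minimum(np.maximum(intervals[:, 1], start), end)
    return int(np.sum(hi - lo))


def tract_frequency(
    tracts: Sequence[AncestryTract],
    popmap: PopMap,
    metapops: Sequence[str],
    coverage_frac: float = 0.8,
    candidates: Sequence[AncestryTract] | None = None,
) -> list[FrequencyProfile]:
    """Carrier-frequency profile of each candidate tract interval.

    ``candidates`` defaults to the distinct (contig, start, end, source)
    intervals occurring in ``tracts`` (each inferred fragment is a candidate).
    A haplotype carries a candidate when its same-source tracts cover at least
    ``coverage_frac`` of the interval. The total frequency pools all
    meta-population haplotypes; the SD is over per-meta-population frequencies
    with equal weight per meta-population.
    """
    if candidates is None:
        seen: dict[tuple, AncestryTract] = {}
        for t in tracts:
            seen.setdefault((t.contig, t.start, t.end, t.source), t)
        candidates = [seen[k] for k in sorted(seen)]

    # haplotype population sizes (2 haplotypes per mapped sample)
    hap_count = {pop: 2 * len(popmap.samples_in_group(pop)) for pop in metapops}
    pop_of_sample = {
        s: popmap.group_of(s) for pop in metapops for s in popmap.samples_in_group(pop)
    }

    cover: dict[tuple[str, str, str], np.ndarray] = {}
    for t in tracts:
        cover.setdefault((t.haplotype_id, t.contig, t.source), []).append((t.start, t.end))
    cover = {
        k: np.array(sorted(v), dtype=np.int64) for k, v in cover.items()
    }
    haps_by_key: dict[tuple[str, str], list[str]] = {}
    for hap, contig, source in cover:
        haps_by_key.setdefault((contig, source), []).append(hap)

    profiles = []
    for cand in candidates:
        need = coverage_frac * cand.length
        carriers: dict[str, int] = {pop: 0 for pop in metapops}
        for hap in haps_by_key.get((cand.contig, cand.source), []):
            sample = _hap_sample(hap)
            pop = pop_of_sample.get(sample)
            if pop is None:
                continue  # haplotype outside the meta-populations of interest
            ivals = cover[(hap, cand.contig, cand.source)]
            if _overlap_bp(ivals, cand.start, cand.end) >= need:
                carriers[pop] += 1
        freqs = {pop: carriers[pop] / hap_count[pop] for pop in metapops}
        total = sum(carriers.values()) / sum(hap_count.values())
        vals = np.array(list(freqs.values()))
        profiles.append(
            FrequencyProfile(
                contig=cand.contig,
                start=cand.start,
                end=cand.end,
                source=cand.source,
                freq_by_pop=freqs,
                total_freq=float(total),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                range_=float(vals.max() - vals.min()),
            )
        )
    return profiles


def select_outlier_tracts(
    profiles: Sequence[FrequencyProfile],
    min_len: int = 100_000,
    min_total_freq: float = 0.05,
    min_sd: float = 0.1,
) -> list[FrequencyProfile]:
    """Keep profiles with length >= min_len AND total frequency >=
    min_total_freq AND frequency SD strictly > min_sd."""
    return [
        p
        for p in profiles
        if p.length >= min_len and p.total_freq >= min_total_freq and p.sd > min_sd
    ]


def high_fst_regions(
    window_stats: pd.DataFrame, p_cut: float = 0.001, join_gap: int = 50_000
) -> list[HighFstRegion]:
    """Join significant F_ST windows (upper-tail p < p_cut) separated by
    <= join_gap bp into non-overlapping regions."""
    sig = window_stats[
        np.isfinite(window_stats["p_fst"]) & (window_stats["p_fst"] < p_cut)
    ].sort_values(["contig", "start"])
    regions: list[HighFstRegion] = []
    for contig, sub in sig.groupby("contig", sort=True):
        cur_start = cur_end = None
        cur_n = 0
        cur_p = np.inf
        for _, row in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end = int(row.start), int(row.end)
                cur_n, cur_p = 1, float(row.p_fst)
            elif int(row.start) - cur_end <= join_gap:
                cur_end = max(cur_end, int(row.end))
                cur_n += 1
                cur_p = min(cur_p, float(row.p_fst))
            else:
                regions.append(HighFstRegion(contig, cur_start, cur_end, cur_n, cur_p))
                cur_start, cur_end = int(row.start), int(row.end)
                cur_n, cur_p = 1, float(row.p_fst)
        if cur_start is not None:
            regions.append(HighFstRegion(contig, cur_start, cur_end, cur_n, cur_p))
    return regions


def overlap_regions(
    outliers: Sequence[FrequencyProfile],
    regions: Sequence[HighFstRegion],
    min_overlap: int = 1,
) -> list[tuple[FrequencyProfile, list[int]]]:
    """Annotate each outlier profile with the indices of high-F_ST regions it
    overlaps by at least ``min_overlap`` bp."""
    annotated = []
    for prof in outliers:
        hits = [
            i
            for i, reg in enumerate(regions)
            if reg.contig == prof.contig
            and min(prof.end, reg.end) - max(prof.start, reg.start) >= min_overlap
        ]
        annotated.append((prof, hits))
    return annotated


def profiles_to_frame(profiles: Sequence[FrequencyProfile]) -> pd.DataFrame:
    """Tabulate profiles (1-based start in the printed table)."""
    rows = []
    for p in profiles:
        row = {
            "contig": p.contig,
            "start1": p.start + 1,
            "end": p.end,
            "source": p.source,
            "length": p.length,
            "total_freq": p.total_freq,
            "sd": p.sd,
            "range": p.range_,
        }
        row.update({f"freq_{k}": v for k, v in p.freq_by_pop.items()})
        rows.append(row)
    return pd.DataFrame(rows)
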