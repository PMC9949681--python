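"""Local ancestry inference by minimal-cost haplotype copying.

Each admixed haplotype is modelled as a mosaic of reference-panel haplotypes:
a copy path assigns every site to one template, paying one unit per allele
mismatch and ``lam`` units per template switch. The globally optimal path is
found by dynamic programming (Viterbi over templates), ancestry runs are cut
into tracts at the midpoint between the flanking sites of each switch, and
adjacent same-source tracts are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import MISSING, HaplotypePanel, PopMap


@dataclass(frozen=True)
class AncestryTract:
    """Half-open ancestry interval of one haplotype, 0-based coordinates."""

    haplotype_id: str
    contig: str
    start: int
    end: int
    source: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("tract end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyPath:
    """Optimal copying path of one target haplotype through the templates."""

    template_index: np.ndarray  # per-site template column
    source: list[str]  # per-site source-population label
    n_switches: int
    n_mismatches: int
    cost: float


def copy_path_dp(
    target: np.ndarray,
    templates: np.ndarray,
    template_sources: Sequence[str],
    lam: float = 1.5,
) -> CopyPath:
    """Minimal-cost copy path of ``target`` through ``templates``.

    Parameters
    ----------
    target : int8 array of shape (n_sites,), entries 0/1/MISSING.
    templates : int8 array of shape (n_sites, n_templates).
    template_sources : source-population label per template column.
    lam : switch penalty in mismatch-equivalents.

    Cost of a path is ``n_mismatches + lam * n_switches``; sites where either
    allele is missing never count as mismatches. Ties are broken in favour of
    fewer switches (staying on the current template), then the lowest template
    index. Complexity O(n_sites * n_templates).
    """
    target = np.asarray(target)
    templates = np.asarray(templates)
    n_sites, n_templates = templates.shape
    if n_templates == 0 or len(template_sources) != n_templates:
        raise ValueError("need at least one template with a source label per column")
    if target.shape[0] != n_sites:
        raise ValueError("target and templates disagree on number of sites")

    valid = (target[:, None] != MISSING) & (templates != MISSING)
    mism = ((templates != target[:, None]) & valid).astype(np.float64)

    cost = mism[0].copy()
    # stay[i, j]: optimal predecessor of template j at site i is j itself;
    # origin[i]: template switched from otherwise (argmin is lowest index,
    # identical for every destination column).
    stay = np.empty((n_sites, n_templates), dtype=bool)
    stay[0] = True
    origin = np.zeros(n_sites, dtype=np.intp)
    for i in range(1, n_sites):
        origin[i] = int(np.argmin(cost))
        switch_cost = cost[origin[i]] + lam
        stay[i] = cost <= switch_cost
        cost = mism[i] + np.minimum(cost, switch_cost)

    j = int(np.argmin(cost))
    total = float(cost[j])
    path = np.empty(n_sites, dtype=np.intp)
    path[-1] = j
    for i in range(n_sites - 1, 0, -1):
        j = j if stay[i, j] else int(origin[i])
        path[i - 1] = j
    n_switches = int(np.sum(path[1:] != path[:-1]))
    n_mismatches = int(mism[np.arange(n_sites), path].sum())
    return CopyPath(
        template_index=path,
        source=[template_sources[k] for k in path],
        n_switches=n_switches,
        n_mismatches=n_mismatches,
        cost=total,
    )


def _runs_to_tracts(
    sources: Sequence[str],
    positions: np.ndarray,
    contig: str,
    contig_length: int,
    hap_id: str,
) -> list[AncestryTract]:
    """Convert per-site source labels to tracts partitioning [0, contig_length).

    Boundaries between ancestry runs are placed at the midpoint between the
    last site of one run and the first site of the next.
    """
    tracts: list[AncestryTract] = []
    run_start_bp = 0
    cur = sources[0]
    for k in range(1, len(sources)):
        if sources[k] != cur:
            boundary = int((positions[k - 1] + positions[k] + 1) // 2)
            tracts.append(AncestryTract(hap_id, contig, run_start_bp, boundary, cur))
            run_start_bp = boundary
            cur = sources[k]
    tracts.append(AncestryTract(hap_id, contig, run_start_bp, contig_length, cur))
    return tracts


def infer_tracts(
    panel: HaplotypePanel,
    popmap: PopMap,
    target_group: str,
    reference_groups: Sequence[str],
    lam: float = 1.5,
    bagging_reps: int = 1,
    bag_frac: float = 0.8,
    recipient_source: str | None = None,
    seed: int | None = None,
) -> list[AncestryTract]:
    """Infer ancestry tracts for every haplotype of ``target_group``.

    ``reference_groups`` supply the copy templates; the first listed group is
    by convention the non-introgressed recipient reference, so that "no donor"
    is always expressible. With ``bagging_reps > 1``, the DP is repeated on
    random ``bag_frac`` subsamples of the templates and each site takes the
    majority-vote source, ties resolved to the recipient source (conservative).
    """
    if target_group in reference_groups:
        raise ValueError("target group must be disjoint from reference groups")
    if recipient_source is None:
        recipient_source = reference_groups[0]
    rng = np.random.default_rng(seed)

    ref_cols: list[int] = []
    ref_sources: list[str] = []
    for group in reference_groups:
        cols = panel.sample_hap_indices(popmap.samples_in_group(group))
        ref_cols.extend(int(c) for c in cols)
        ref_sources.extend([group] * len(cols))
    target_samples = popmap.samples_in_group(target_group)
    target_cols = panel.sample_hap_indices(target_samples)
    hap_ids = panel.haplotype_ids

    tracts: list[AncestryTract] = []
    for contig, length in panel.contigs.items():
        pos = panel.positions.get(contig)
        if pos is None or len(pos) == 0:
            continue
        templates = panel.alleles[contig][:, ref_cols]
        for col in target_cols:
            target = panel.alleles[contig][:, col]
            if bagging_reps <= 1:
                site_sources = copy_path_dp(target, templates, ref_sources, lam).source
            else:
                n_ref = len(ref_sources)
                n_bag = max(2, int(round(bag_frac * n_ref)))
                votes: dict[str, np.ndarray] = {}
                for _ in range(bagging_reps):
                    pick = rng.choice(n_ref, size=n_bag, replace=False)
                    sub_sources = [ref_sources[k] for k in pick]
                    path = copy_path_dp(target, templates[:, pick], sub_sources, lam)
                    for i, s in enumerate(path.source):
                        votes.setdefault(s, np.zeros(len(pos), dtype=np.int64))[i] += 1
                counts = np.stack([votes[s] for s in votes])
                labels = list(votes)
                best = counts.max(axis=0)
                site_sources = []
                for i in range(len(pos)):
                    winners = [labels[k] for k in range(len(labels)) if counts[k, i] == best[i]]
                    site_sources.append(
                        recipient_source if len(winners) > 1 and recipient_source in winners
                        else winners[0]
                    )
            tracts.extend(
                _runs_to_tracts(site_sources, pos, contig, length, hap_ids[col])
            )
    return merge_tracts(tracts, max_gap=0)


def merge_tracts(tracts: Sequence[AncestryTract], max_gap: int = 0) -> list[AncestryTract]:
    """Merge same-haplotype, same-source tracts that overlap or lie within
    ``max_gap`` bp of each other; lengths are recomputed from merged bounds."""
    by_key: dict[tuple[str, str, str], list[AncestryTract]] = {}
    for t in tracts:
        by_key.setdefault((t.haplotype_id, t.contig, t.source), []).append(t)
    merged: list[AncestryTract] = []
    for (hap, contig, source), group in by_key.items():
        group.sort(key=lambda t: (t.start, t.end))
        cur_start, cur_end = group[0].start, group[0].end
        for t in group[1:]:
            if t.start - cur_end <= max_gap:
                cur_end = max(cur_end, t.end)
            else:
                merged.append(AncestryTract(hap, contig, cur_start, cur_end, source))
                cur_start, cur_end = t.start, t.end
        merged.append(AncestryTract(hap, contig, cur_start, cur_end, source))
    merged.sort(key=lambda t: (t.contig, t.start, t.end, t.haplotype_id, t.source))
    return merged
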