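"""Evaluation of inferred ancestry tracts against simulated ground truth."""

from __future__ import annotations

from typing import Sequence


def _index(tracts, min_len: int = 0) -> dict:
    d: dict[str, list[tuple[int, int]]] = {}
    for t in tracts:
        if t.length >= min_len:
            d.setdefault(t.haplotype_id, []).append((t.start, t.end))
    return d


def _intersection_bp(a: dict, b: dict) -> int:
    total = 0
    for hap, ivs in a.items():
        for s, e in ivs:
            for s2, e2 in b.get(hap, []):
                total += max(0, min(e, e2) - max(s, s2))
    return total


def bp_precision_recall(
    inferred: Sequence, truth: Sequence, min_len: int = 0
) -> tuple[float, float]:
    """Base-pair precision and recall of inferred tracts against truth tracts.

    Precision is measured on inferred tracts of at least ``min_len`` bp
    against all truth tracts (an inferred call overlapping any true donor
    sequence counts as correct); recall on truth tracts of at least
    ``min_len`` against all inferred tracts. Tracts are matched within
    haplotypes. Returns NaN for an empty denominator.
    """
    inf_big = _index(inferred, min_len)
    truth_all = _index(truth)
    truth_big = _index(truth, min_len)
    inf_all = _index(inferred)
    prec_den = sum(e - s for ivs in inf_big.values() for s, e in ivs)
    rec_den = sum(e - s for ivs in truth_big.values() for s, e in ivs)
    precision = _intersection_bp(inf_big, truth_all) / prec_den if prec_den else float("nan")
    recall = _intersection_bp(truth_big, inf_all) / rec_den if rec_den else float("nan")
    return precision, recall
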