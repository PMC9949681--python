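"""Windowed population-genetic statistics: F_ST, d_XY, D (ABBA-BABA) and f_d,
Z-test significance and the permutation-derived genome-wide F_ST threshold.

Statistics are computed in sliding windows (default 50-kb windows, 20-kb step)
from per-site derived-allele frequencies. F_ST uses the Weir-Cockerham (1984)
weighted ratio-of-sums estimator by default (matching vcftools' windowed
estimator); Hudson's estimator is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, HaplotypePanel, PopMap, Window, iterate_windows, sites_in_window

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele frequencies


def group_site_frequencies(
    panel: HaplotypePanel, popmap: PopMap, group: str, contig: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency ``p`` and non-missing allele count
    ``n`` for one group on one contig."""
    cols = panel.sample_hap_indices(popmap.samples_in_group(group))
    sub = panel.alleles[contig][:, cols]
    valid = sub != MISSING
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(valid, sub, 0).sum(axis=1) / np.where(n > 0, n, 1)
    p[n == 0] = np.nan
    return p, n


def polarize_by_outgroup(
    freqs: dict[str, np.ndarray], outgroup: str, poly_band: tuple[float, float] = (0.1, 0.9)
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Polarize derived-allele frequencies by the outgroup consensus.

    The outgroup consensus allele is taken as ancestral: where the outgroup
    ALT frequency is >= the upper band edge, all frequencies are flipped
    (p -> 1-p); sites where the outgroup is polymorphic (ALT frequency inside
    ``poly_band``) are masked out. Returns (polarized freqs, keep mask).
    """
    lo, hi = poly_band
    q = freqs[outgroup]
    keep = ~np.isnan(q) & ((q <= lo) | (q >= hi))
    for name, arr in freqs.items():
        keep &= ~np.isnan(arr)
    flip = q >= hi
    out = {name: np.where(flip, 1.0 - arr, arr) for name, arr in freqs.items()}
    return out, keep


# ---------------------------------------------------------------------------
# F_ST


def _wc_site_components(
    subA: np.ndarray, subB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components a, b, c per site for two
    populations of diploid samples given their phased haplotype matrices.

    Samples missing either allele at a site are excluded there; a site is
    usable when both populations retain at least one sample and the mean
    sample count exceeds one.
    """
    comps = []
    ns = []
    ps = []
    hs = []
    for sub in (subA, subB):
        n_sites = sub.shape[0]
        dip = sub.reshape(n_sites, -1, 2)
        valid = np.all(dip != MISSING, axis=2)
        n_i = valid.sum(axis=1).astype(np.float64)
        alt = np.where(valid[:, :, None], dip, 0).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt / (2 * n_i)
            h_i = (np.logical_and(dip[:, :, 0] != dip[:, :, 1], valid)).sum(axis=1) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    r = 2.0
    nbar = (n1 + n2) / r
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def _hudson_site_components(
    subA: np.ndarray, subB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson's F_ST numerator/denominator per site from haploid allele counts."""
    out = []
    for sub in (subA, subB):
        valid = sub != MISSING
        n = valid.sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(valid, sub, 0).sum(axis=1) / n
        out.append((p, n))
    (pA, nA), (pB, nB) = out
    usable = (nA >= 2) & (nB >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
        den = pA * (1 - pB) + pB * (1 - pA)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    return num, den, usable


def fst_window(
    panel: HaplotypePanel,
    popmap: PopMap,
    groupA: str,
    groupB: str,
    window: Window,
    estimator: str = "wc",
    min_sites: int = 10,
) -> float:
    """Windowed F_ST between two groups (ratio of sums over sites).

    Returns NaN when fewer than ``min_sites`` usable sites fall in the window.
    """
    colsA = panel.sample_hap_indices(popmap.samples_in_group(groupA))
    colsB = panel.sample_hap_indices(popmap.samples_in_group(groupB))
    sl = sites_in_window(panel, window)
    subA = panel.alleles[window.contig][sl][:, colsA]
    subB = panel.alleles[window.contig][sl][:, colsB]
    if subA.shape[0] == 0:
        warnings.warn(f"no sites in window {window}", stacklevel=2)
        return float("nan")
    if estimator == "wc":
        a, b, c, usable = _wc_site_components(subA, subB)
        if int(usable.sum()) < min_sites:
            return float("nan")
        denom = float((a + b + c).sum())
        return float(a.sum() / denom) if denom != 0 else float("nan")
    if estimator == "hudson":
        num, den, usable = _hudson_site_components(subA, subB)
        if int(usable.sum()) < min_sites:
            return float("nan")
        return float(num.sum() / den.sum()) if den.sum() != 0 else float("nan")
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


# ---------------------------------------------------------------------------
# d_XY, D, f_d (frequency-based, per window)


def dxy_window(pA: np.ndarray, pB: np.ndarray, window_length: int) -> float:
    """Mean per-bp pairwise sequence divergence between two populations:
    (1/window_length) * sum_sites [pA(1-pB) + pB(1-pA)]."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    pA = np.asarray(pA, dtype=np.float64)
    pB = np.asarray(pB, dtype=np.float64)
    return float(np.sum(pA * (1 - pB) + pB * (1 - pA)) / window_length)


def _abba_baba(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, pO: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def d_stat_window(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, pO: np.ndarray
) -> float:
    """ABBA-BABA D over the window's sites: sum(ABBA-BABA)/sum(ABBA+BABA);
    NaN when the denominator is zero. Frequencies must be outgroup-polarized
    derived-allele frequencies."""
    abba, baba = _abba_baba(
        np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float), np.asarray(pO, float)
    )
    denom = float((abba + baba).sum())
    if denom == 0:
        return float("nan")
    return float((abba - baba).sum() / denom)


def fd_window(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, pO: np.ndarray
) -> float:
    """Windowed f_d: S(P1,P2,P3,O) / S(P1,P_D,P_D,O) where S is sum(ABBA-BABA)
    and, per site, P_D is whichever of P2/P3 has the higher derived frequency.

    NaN when the window's D is negative or the denominator is <= 0 (the
    statistic only quantifies admixture where there is an ABBA excess).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    pO = np.asarray(pO, float)
    D = d_stat_window(p1, p2, p3, pO)
    if not np.isfinite(D) or D < -1e-12:  # tolerance: D == 0 windows are kept
        return float("nan")
    abba, baba = _abba_baba(p1, p2, p3, pO)
    pd_ = np.maximum(p2, p3)
    abba_d, baba_d = _abba_baba(p1, pd_, pd_, pO)
    denom = float((abba_d - baba_d).sum())
    if denom <= 0:
        return float("nan")
    return float((abba - baba).sum() / denom)


# ---------------------------------------------------------------------------
# Z-test over windows


def z_scan(
    values: np.ndarray | Sequence[float], tail: str = "two", alpha: float = 0.001
) -> pd.DataFrame:
    """Z-transform a per-window statistic and attach Normal-tail P values.

    ``tail`` is "upper" (one-tailed, large values significant) or "two".
    NaN windows are ignored in the mean/sd and get NaN z and p. A constant
    vector (sd == 0) yields a warning and p = 1 everywhere.
    """
    x = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least two non-NA windows for a Z scan")
    mean = float(x[finite].mean())
    sd = float(x[finite].std(ddof=1))
    z = np.full_like(x, np.nan)
    p = np.full_like(x, np.nan)
    if sd == 0:
        warnings.warn("constant statistic: all P values set to 1", stacklevel=2)
        z[finite] = 0.0
        p[finite] = 1.0
    else:
        z[finite] = (x[finite] - mean) / sd
        if tail == "upper":
            p[finite] = stats.norm.sf(z[finite])
        elif tail == "two":
            p[finite] = 2 * stats.norm.sf(np.abs(z[finite]))
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return pd.DataFrame({"z": z, "p": p, "significant": p < alpha})


# ---------------------------------------------------------------------------
# scan driver


def scan_windows(
    panel: HaplotypePanel,
    popmap: PopMap,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    size: int = 50_000,
    step: int = 20_000,
    min_sites: int = 10,
    fst_estimator: str = "wc",
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Genome-wide windowed scan for the quartet (P1, P2; P3, outgroup).

    Per window: usable site count, F_ST(P2, P3), per-bp d_XY(P2, P3),
    D(P1, P2, P3, O) and f_d, plus Z-transformed significance — two-tailed for
    f_d, upper one-tailed for F_ST, flagged at ``alpha``. In the introgression
    scan P1 is the non-introgressed domestic reference, P2 the recipient
    meta-population and P3 the wild donor.
    """
    rows = []
    for contig in panel.contigs:
        if contig not in panel.positions or len(panel.positions[contig]) == 0:
            continue
        freqs = {
            g: group_site_frequencies(panel, popmap, g, contig)[0]
            for g in (p1, p2, p3, outgroup)
        }
        pol, keep = polarize_by_outgroup(freqs, outgroup)
        for window in iterate_windows({contig: panel.contigs[contig]}, size, step):
            sl = sites_in_window(panel, window)
            k = keep[sl]
            n_sites = int(k.sum())
            if n_sites >= min_sites:
                f1, f2, f3, fo = (pol[g][sl][k] for g in (p1, p2, p3, outgroup))
                dxy = dxy_window(f2, f3, window.length)
                D = d_stat_window(f1, f2, f3, fo)
                fd = fd_window(f1, f2, f3, fo)
            else:
                dxy = D = fd = float("nan")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fst = fst_window(
                    panel, popmap, p2, p3, window, estimator=fst_estimator, min_sites=min_sites
                )
            rows.append(
                {
                    "contig": window.contig,
                    "start": window.start,
                    "end": window.end,
                    "clipped": window.clipped,
                    "n_sites": n_sites,
                    "fst": fst,
                    "dxy": dxy,
                    "D": D,
                    "fd": fd,
                }
            )
    df = pd.DataFrame(rows)
    zfd = z_scan(df["fd"].to_numpy(), tail="two", alpha=alpha)
    df["z_fd"], df["p_fd"], df["sig_fd"] = zfd["z"], zfd["p"], zfd["significant"]
    zfst = z_scan(df["fst"].to_numpy(), tail="upper", alpha=alpha)
    df["z_fst"], df["p_fst"], df["sig_fst"] = zfst["z"], zfst["p"], zfst["significant"]
    return df


def write_scan_tsv(df: pd.DataFrame, path) -> None:
    """Write a scan table with 1-based inclusive start coordinates."""
    out = df.copy()
    out.insert(1, "start1", out.pop("start") + 1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# permutation threshold


def fst_permutation_threshold(
    panel: HaplotypePanel,
    popmap: PopMap,
    domestic_groups: Sequence[str],
    wild_group: str,
    n_draw: int = 33,
    reps: int = 100,
    size: int = 50_000,
    step: int = 20_000,
    min_sites: int = 10,
    seed: int | None = None,
) -> float:
    """Permutation-derived genome-wide F_ST significance threshold.

    Each replicate draws ``n_draw`` domestic samples (from the pooled domestic
    groups), mixes them with ``n_draw`` wild samples, splits the pool randomly
    into two equal pseudo-populations, computes windowed F_ST genome-wide and
    records the maximum; the threshold returned is the largest of the recorded
    per-replicate maxima.
    """
    rng = np.random.default_rng(seed)
    domestic = []
    for g in domestic_groups:
        domestic.extend(popmap.samples_in_group(g))
    wild = popmap.samples_in_group(wild_group)
    if len(domestic) < n_draw or len(wild) < n_draw:
        raise ValueError(
            f"need at least {n_draw} samples in both pools "
            f"(have {len(domestic)} domestic, {len(wild)} wild)"
        )
    maxima = []
    for _ in range(reps):
        dom_pick = list(rng.choice(domestic, size=n_draw, replace=False))
        wild_pick = list(rng.choice(wild, size=n_draw, replace=False))
        pool = dom_pick + wild_pick
        perm = rng.permutation(len(pool))
        half = len(pool) // 2
        popA = [pool[i] for i in perm[:half]]
        popB = [pool[i] for i in perm[half:]]
        pm = PopMap(
            sample_breed={**{s: "permA" for s in popA}, **{s: "permB" for s in popB}},
            breed_group={"permA": "permA", "permB": "permB"},
        )
        rep_max = -np.inf
        for window in iterate_windows(panel.contigs, size, step):
            if window.contig not in panel.positions:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = fst_window(panel, pm, "permA", "permB", window, min_sites=min_sites)
            if np.isfinite(v) and v > rep_max:
                rep_max = v
        if np.isfinite(rep_max):
            maxima.append(rep_max)
    if not maxima:
        raise ValueError("no usable windows in any permutation replicate")
    return float(max(maxima))
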