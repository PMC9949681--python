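"""Readers and writers for the standard formats: phased VCF, popmap TSV,
recombination-map TSV, tract BED, phenotype TSV.

All writers emit sorted, deduplicated records; all readers raise on malformed
lines with the offending line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MISSING, HaplotypePanel, PopMap
from .lai import AncestryTract

log = logging.getLogger(__name__)


def read_phased_vcf(path: str | Path, allow_unphased: bool = False) -> HaplotypePanel:
    """Load a phased VCF into a :class:`HaplotypePanel`.

    Multiallelic records are dropped (counted and logged). Unphased genotypes
    raise unless ``allow_unphased`` is set, in which case the record is
    dropped. Missing calls become :data:`MISSING`.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contigs: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens):
        contigs[name] = int(length)
    positions: dict[str, list[int]] = {}
    rows: dict[str, list[np.ndarray]] = {}
    n_multi = n_unphased = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.genotypes, dtype=np.int64)  # (n_samples, 3)
        if not np.all(gts[:, 2] == 1):
            if not allow_unphased:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS}; "
                    "pass allow_unphased=True to drop such records"
                )
            n_unphased += 1
            continue
        alleles = gts[:, :2].reshape(-1).astype(np.int8)
        alleles[alleles < 0] = MISSING
        positions.setdefault(var.CHROM, []).append(var.POS - 1)
        rows.setdefault(var.CHROM, []).append(alleles)
    if n_multi:
        log.info("dropped %d multiallelic record(s)", n_multi)
    if n_unphased:
        log.info("dropped %d unphased record(s)", n_unphased)
    pos_arrays = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
    allele_mats = {c: np.vstack(r) for c, r in rows.items()}
    # contigs without header lengths: infer a length past the last site
    for c, p in pos_arrays.items():
        if c not in contigs or contigs[c] <= 0:
            contigs[c] = int(p[-1]) + 1
    used = {c: contigs[c] for c in contigs if c in pos_arrays or contigs[c] > 0}
    return HaplotypePanel(used, pos_arrays, allele_mats, samples)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF (GT only, alleles A/G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in panel.contigs.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for contig in panel.contigs:
            pos = panel.positions.get(contig)
            if pos is None:
                continue
            mat = panel.alleles[contig]
            for i, p in enumerate(pos):
                row = mat[i]
                gts = []
                for s in range(panel.n_samples):
                    a, b = row[2 * s], row[2 * s + 1]
                    gts.append(
                        f"{'.' if a == MISSING else int(a)}|{'.' if b == MISSING else int(b)}"
                    )
                fh.write(
                    f"{contig}\t{int(p) + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


def read_popmap(path: str | Path) -> PopMap:
    """Read a 3-column TSV (sample, breed, group) into a :class:`PopMap`."""
    sample_breed: dict[str, str] = {}
    breed_group: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or not all(parts):
                raise ValueError(f"{path}: malformed popmap line {lineno}: {line!r}")
            sample, breed, group = parts
            if sample in sample_breed:
                raise ValueError(f"{path}: duplicate sample {sample!r} at line {lineno}")
            prev = breed_group.get(breed)
            if prev is not None and prev != group:
                raise ValueError(
                    f"{path}: breed {breed!r} mapped to both {prev!r} and {group!r}"
                )
            sample_breed[sample] = breed
            breed_group[breed] = group
    if not sample_breed:
        raise ValueError(f"{path}: empty population map")
    return PopMap(sample_breed, breed_group)


def write_popmap(popmap: PopMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample in sorted(popmap.sample_breed):
            breed = popmap.sample_breed[sample]
            fh.write(f"{sample}\t{breed}\t{popmap.breed_group[breed]}\n")


@dataclass
class RecombMap:
    """Per-interval recombination rates with a genome-wide default.

    Intervals are 0-based half-open; positions falling in a gap between
    intervals get the default rate.
    """

    intervals: pd.DataFrame  # columns contig, start, end, rate
    default_rate: float = 1.0e-8

    def rate_at(self, contig: str, pos: int) -> float:
        sub = self.intervals
        hit = sub[(sub.contig == contig) & (sub.start <= pos) & (pos < sub.end)]
        if len(hit):
            return float(hit.iloc[0].rate)
        return self.default_rate


def read_recomb_map(path: str | Path, default_rate: float = 1.0e-8) -> RecombMap:
    """Read a 4-column TSV (contig, start, end, rate_per_bp_per_gen)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed recomb-map line {lineno}: {line!r}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: bad field at line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "rate"])
    if ((df.end - df.start) <= 0).any():
        raise ValueError(f"{path}: interval with nonpositive length")
    return RecombMap(df.sort_values(["contig", "start"]).reset_index(drop=True), default_rate)


def write_tracts_bed(tracts: Sequence[AncestryTract], path: str | Path) -> None:
    """Write ancestry tracts as BED3+ (contig, start, end, haplotype, source).

    Records are sorted by (contig, start, end, haplotype, source) and exact
    duplicates are dropped.
    """
    recs = sorted(
        {(t.contig, t.start, t.end, t.haplotype_id, t.source) for t in tracts}
    )
    with open(path, "w") as fh:
        for contig, start, end, hap, source in recs:
            fh.write(f"{contig}\t{start}\t{end}\t{hap}\t{source}\n")


def read_tracts_bed(path: str | Path) -> list[AncestryTract]:
    tracts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            contig, start, end, hap, source = parts
            tracts.append(AncestryTract(hap, contig, int(start), int(end), source))
    return tracts


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV with a 'sample' column."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: phenotype table must have a 'sample' column")
    return df
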