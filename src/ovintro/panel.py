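"""Core in-memory containers: phased haplotype panels, population maps, windows.

Coordinates are 0-based half-open everywhere inside the package; conversion to
1-based inclusive happens only at VCF output and in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

MISSING = -1  # missing allele code in the int8 allele matrix


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes over one or more contigs.

    Attributes
    ----------
    contigs : dict mapping contig id -> length in bp.
    positions : dict mapping contig id -> strictly increasing int array of
        0-based site positions.
    alleles : dict mapping contig id -> int8 array of shape (n_sites,
        n_haplotypes) with entries 0 (ancestral/REF), 1 (derived/ALT) or
        ``MISSING``.
    samples : sample identifiers; haplotype ``2*i`` and ``2*i+1`` belong to
        sample ``i`` (phase 0 and 1).
    """

    contigs: dict[str, int]
    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    samples: list[str]

    def __post_init__(self) -> None:
        for contig, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[contig] = pos
            mat = np.asarray(self.alleles[contig], dtype=np.int8)
            self.alleles[contig] = mat
            if mat.shape != (len(pos), self.n_haplotypes):
                raise ValueError(
                    f"allele matrix for {contig} has shape {mat.shape}, "
                    f"expected {(len(pos), self.n_haplotypes)}"
                )
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
            if contig not in self.contigs:
                raise ValueError(f"contig {contig} has sites but no length")
            if len(pos) and pos[-1] >= self.contigs[contig]:
                raise ValueError(f"site beyond end of contig {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_h{k}" for s in self.samples for k in (0, 1)]

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def haplotype_index(self, hap_id: str) -> int:
        try:
            return self.haplotype_ids.index(hap_id)
        except ValueError:
            raise KeyError(f"unknown haplotype id {hap_id!r}") from None

    def sample_hap_indices(self, samples: Sequence[str]) -> np.ndarray:
        """Column indices of all haplotypes belonging to ``samples``."""
        idx = {s: i for i, s in enumerate(self.samples)}
        cols = []
        for s in samples:
            if s not in idx:
                raise KeyError(f"sample {s!r} not in panel")
            cols.extend((2 * idx[s], 2 * idx[s] + 1))
        return np.asarray(cols, dtype=np.intp)


@dataclass
class PopMap:
    """sample -> breed -> group assignment.

    Groups are the analysis units: donor populations (e.g. Iranian mouflon,
    urial, argali), an outgroup, a non-introgressed domestic reference group
    and the recipient meta-populations.
    """

    sample_breed: dict[str, str]
    breed_group: dict[str, str]

    def group_of(self, sample: str) -> str:
        breed = self.sample_breed.get(sample)
        if breed is None:
            raise KeyError(f"sample {sample!r} missing from population map")
        group = self.breed_group.get(breed)
        if group is None:
            raise KeyError(f"breed {breed!r} missing from population map")
        return group

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breed_group.values():
            seen.setdefault(b, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        got = [s for s in self.sample_breed if self.group_of(s) == group]
        if not got:
            raise KeyError(f"group {group!r} has no samples")
        return got

    def samples_in_breed(self, breed: str) -> list[str]:
        return [s for s, b in self.sample_breed.items() if b == breed]

    def validate_panel(self, panel: HaplotypePanel) -> None:
        """Every panel sample must be mapped (raises naming the offender)."""
        for s in panel.samples:
            if s not in self.sample_breed:
                raise KeyError(f"panel sample {s!r} missing from population map")


@dataclass(frozen=True)
class Window:
    """Genomic window, 0-based half-open."""

    contig: str
    start: int
    end: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def iterate_windows(
    contig_lengths: Mapping[str, int], size: int = 50_000, step: int = 20_000
) -> Iterator[Window]:
    """Enumerate sliding windows over contigs.

    Windows start at 0 and advance by ``step`` while the start lies inside the
    contig; windows running past the contig end are clipped there and flagged.
    Pure function of its inputs; deterministic order (contigs in mapping
    order, then left to right).
    """
    if step <= 0 or size < step:
        raise ValueError("require size >= step > 0")
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"nonpositive length for contig {contig}")
        for start in range(0, length, step):
            end = start + size
            if end >= length:
                yield Window(contig, start, length, clipped=end > length)
            else:
                yield Window(contig, start, end)


def sites_in_window(panel: HaplotypePanel, window: Window) -> slice:
    """Index slice of panel sites falling inside ``window``."""
    pos = panel.positions[window.contig]
    lo = int(np.searchsorted(pos, window.start, side="left"))
    hi = int(np.searchsorted(pos, window.end, side="left"))
    return slice(lo, hi)
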