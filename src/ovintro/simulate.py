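"""Synthetic phased panels with known introgression tracts, plus an F2-cross
genotype/phenotype fixture, so every downstream stage has exact ground truth.

The generator emulates a population tree (outgroup, wild donor populations,
several domestic recipient populations) by per-branch drift of allele
frequencies on the logit scale with variance proportional to branch length in
generations — a cheap stand-in for a coalescent that keeps ground truth exact.
Admixture pulses write donor-copied tracts into recipient haplotypes as a
stationary alternating-renewal process: donor segments are Exponential with
mean 1/(r * t_gen) bp (the expected admixture-tract length t_gen generations
after the pulse) and recipient gaps are Exponential with mean
(1-f)/(f * r * t_gen), so the per-bp probability of donor ancestry is exactly
the admixture fraction f. Tract placement is independent across haplotypes.
All randomness flows from a single integer seed through one generator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .lmm import GenotypeTable
from .panel import HaplotypePanel, PopMap

Pulse = tuple[str, str, float, float]  # donor, recipient, admix_time_years, fraction


@dataclass
class SimConfig:
    """Study conditions for one synthetic panel."""

    contig_length: int = 2_000_000
    n_contigs: int = 1
    mutation_density: float = 1.0e-3  # expected segregating sites per bp
    pop_tree: list[tuple[str, str | None, float]] = field(default_factory=list)
    n_haplotypes_per_pop: int | dict[str, int] = 20
    gen_time: float = 4.0
    recomb_rate: float = 1.0e-8
    pulses: list[Pulse] = field(default_factory=list)
    seed: int = 0
    effective_size: float = 10_000.0  # scales per-branch drift variance
    root_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        names = [p for p, _, _ in self.pop_tree]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population in pop_tree")
        times = {p: t for p, _, t in self.pop_tree}
        parents = {p: par for p, par, _ in self.pop_tree}
        roots = [p for p, par, _ in self.pop_tree if par is None]
        if len(roots) != 1:
            raise ValueError("pop_tree must have exactly one root")
        for p, par, t in self.pop_tree:
            if t <= 0:
                raise ValueError(f"divergence time of {p} must be positive")
            if par is not None:
                if par not in times:
                    raise ValueError(f"unknown parent {par!r} of {p}")
                if t >= times[par]:
                    raise ValueError(f"{p} must split more recently than its parent")
        for donor, recipient, admix_time, frac in self.pulses:
            if donor not in times or recipient not in times:
                raise ValueError(f"pulse references unknown population: {donor}/{recipient}")
            if not 0 < frac <= 1:
                raise ValueError("admix_fraction must be in (0, 1]")
            if admix_time >= self._mrca_time(donor, recipient, parents, times):
                raise ValueError("admixture must postdate donor/recipient divergence")

    @staticmethod
    def _mrca_time(a: str, b: str, parents: dict, times: dict) -> float:
        """Time at which the lineages of a and b first share a population:
        both must have entered the common ancestor for the lineages to
        coincide."""

        def entry_times(p):
            out = {}
            enter = 0.0
            cur = p
            while cur is not None:
                out[cur] = enter
                enter = times[cur]
                cur = parents[cur]
            return out

        ca, cb = entry_times(a), entry_times(b)
        shared = set(ca) & set(cb)
        return min(max(ca[p], cb[p]) for p in shared)

    @property
    def sampled_pops(self) -> list[str]:
        """Populations that receive haplotypes: leaves of the tree."""
        parents = {par for _, par, _ in self.pop_tree if par is not None}
        return [p for p, _, _ in self.pop_tree if p not in parents]

    def n_haps(self, pop: str) -> int:
        if isinstance(self.n_haplotypes_per_pop, dict):
            n = self.n_haplotypes_per_pop.get(pop, 0)
        else:
            n = self.n_haplotypes_per_pop if pop in self.sampled_pops else 0
        if n % 2:
            raise ValueError(f"haplotype count for {pop} must be even (diploid samples)")
        return n


@dataclass(frozen=True)
class TruthTract:
    """Ground-truth donor tract placed in a recipient haplotype."""

    haplotype_id: str
    contig: str
    start: int
    end: int
    donor: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("tract end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# allele-frequency drift along the tree


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _drift(freqs: dict[str, np.ndarray], years: float, cfg: SimConfig, rng) -> dict:
    """Logit-normal perturbation with variance = generations/(2*Ne)."""
    if years <= 0:
        return {c: a.copy() for c, a in freqs.items()}
    sd = np.sqrt((years / cfg.gen_time) / (2.0 * cfg.effective_size))
    out = {}
    for contig, p in freqs.items():
        x = _logit(np.clip(p, 1e-9, 1 - 1e-9)) + rng.normal(0.0, sd, size=len(p))
        out[contig] = np.clip(_expit(x), 1e-9, 1 - 1e-9)
    return out


def _present_day_frequencies(
    cfg: SimConfig, positions: dict[str, np.ndarray], rng
) -> dict[str, dict[str, np.ndarray]]:
    """Walk the tree from the root to the present, accumulating drift along
    each lineage and branching children off the lineage state at their split
    times. Returns pop -> contig -> present-day derived-allele frequency."""
    children: dict[str, list[tuple[str, float]]] = {}
    root = None
    root_age = 0.0
    for pop, parent, t in cfg.pop_tree:
        if parent is None:
            root, root_age = pop, t
        else:
            children.setdefault(parent, []).append((pop, t))
    lo, hi = cfg.root_freq_range
    base = {c: rng.uniform(lo, hi, size=len(p)) for c, p in positions.items()}
    result: dict[str, dict[str, np.ndarray]] = {}

    def walk(pop: str, t_start: float, state: dict[str, np.ndarray]) -> None:
        cur_t, cur = t_start, state
        for child, t_child in sorted(children.get(pop, []), key=lambda x: -x[1]):
            cur = _drift(cur, cur_t - t_child, cfg, rng)
            cur_t = t_child
            walk(child, t_child, cur)
        result[pop] = _drift(cur, cur_t, cfg, rng)

    walk(root, root_age, base)
    return result


# ---------------------------------------------------------------------------
# tract placement


def _draw_tracts(
    contig_length: int, admix_time_gen: float, frac: float, recomb_rate: float, rng
) -> list[tuple[int, int]]:
    """Stationary alternating-renewal donor tracts on [0, contig_length)."""
    if frac >= 1.0:
        return [(0, contig_length)]
    mean_len = 1.0 / (recomb_rate * admix_time_gen)
    mean_gap = mean_len * (1.0 - frac) / frac
    tracts = []
    x = 0.0
    in_donor = rng.random() < frac
    while x < contig_length:
        if in_donor:
            seg = rng.exponential(mean_len)
            start = int(x)
            end = int(min(x + seg, contig_length))
            if end > start:
                tracts.append((start, end))
            x += seg
        else:
            x += rng.exponential(mean_gap)
        in_donor = not in_donor
    return tracts


def _overlay_tracts(
    existing: list[tuple[int, int, str]], new: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    """Overwrite earlier tracts with later ones (last pulse wins on overlap)."""
    out = []
    for s, e, d in existing:
        cuts = [(s, e)]
        for ns, ne, _ in new:
            nxt = []
            for cs, ce in cuts:
                if ne <= cs or ns >= ce:
                    nxt.append((cs, ce))
                else:
                    if cs < ns:
                        nxt.append((cs, ns))
                    if ne < ce:
                        nxt.append((ne, ce))
            cuts = nxt
        out.extend((cs, ce, d) for cs, ce in cuts if ce > cs)
    out.extend(new)
    return sorted(out)


# ---------------------------------------------------------------------------
# panel simulation


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, list[TruthTract]]:
    """Simulate a phased panel under ``cfg`` with exact truth tracts.

    Recipient haplotypes are their population's baseline sequence with donor
    tracts copied verbatim from randomly chosen donor haplotypes; truth tracts
    are recorded exactly as placed (later pulses overwrite earlier ones on
    overlap).
    """
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.sampled_pops
    n_total = sum(cfg.n_haps(p) for p in pops)
    if n_total == 0:
        raise ValueError("zero haplotypes requested")

    contigs = {f"chr{i + 1}": cfg.contig_length for i in range(cfg.n_contigs)}
    positions: dict[str, np.ndarray] = {}
    for contig, length in contigs.items():
        n_sites = rng.poisson(cfg.mutation_density * length)
        n_sites = max(int(n_sites), 1)
        pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
        positions[contig] = pos.astype(np.int64)

    freqs = _present_day_frequencies(cfg, positions, rng)

    samples: list[str] = []
    pop_of_sample: dict[str, str] = {}
    for pop in pops:
        for i in range(cfg.n_haps(pop) // 2):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            pop_of_sample[name] = pop

    hap_pop = [pop_of_sample[s] for s in samples for _ in (0, 1)]
    alleles = {}
    for contig, pos in positions.items():
        mat = np.empty((len(pos), 2 * len(samples)), dtype=np.int8)
        for j, pop in enumerate(hap_pop):
            mat[:, j] = rng.random(len(pos)) < freqs[pop][contig]
        alleles[contig] = mat
    panel = HaplotypePanel(contigs, positions, alleles, samples)
    hap_ids = panel.haplotype_ids

    # donor haplotype columns per population, for tract copying
    cols_of_pop = {
        pop: panel.sample_hap_indices([s for s in samples if pop_of_sample[s] == pop])
        for pop in pops
    }

    truth: list[TruthTract] = []
    placed: dict[tuple[int, str], list[tuple[int, int, str]]] = {}
    for donor, recipient, admix_time, frac in cfg.pulses:
        t_gen = admix_time / cfg.gen_time
        donor_cols = cols_of_pop[donor]
        for col in cols_of_pop[recipient]:
            for contig, length in contigs.items():
                new = [
                    (s, e, donor)
                    for s, e in _draw_tracts(length, t_gen, frac, cfg.recomb_rate, rng)
                ]
                for s, e, d in new:
                    src = int(rng.choice(donor_cols))
                    pos = positions[contig]
                    lo = int(np.searchsorted(pos, s, side="left"))
                    hi = int(np.searchsorted(pos, e, side="left"))
                    alleles[contig][lo:hi, col] = alleles[contig][lo:hi, src]
                key = (int(col), contig)
                placed[key] = _overlay_tracts(placed.get(key, []), new)
    for (col, contig), tracts in sorted(placed.items()):
        for s, e, d in tracts:
            truth.append(TruthTract(hap_ids[col], contig, s, e, d))
    truth.sort(key=lambda t: (t.contig, t.start, t.end, t.haplotype_id))
    return panel, truth


def popmap_for(cfg: SimConfig) -> PopMap:
    """Population map for a simulated panel (one breed per population)."""
    sample_breed = {}
    for pop in cfg.sampled_pops:
        for i in range(cfg.n_haps(pop) // 2):
            sample_breed[f"{pop}_{i:03d}"] = pop
    return PopMap(sample_breed, {p: p for p in cfg.sampled_pops})


# ---------------------------------------------------------------------------
# F2 cross


def pick_causal_site(
    panel: HaplotypePanel, founders_a: Sequence[str], founders_b: Sequence[str]
) -> tuple[str, int]:
    """Site with the largest founder allele-frequency difference."""
    colsA = panel.sample_hap_indices(founders_a)
    colsB = panel.sample_hap_indices(founders_b)
    best = ("", -1, -1.0)
    for contig, mat in panel.alleles.items():
        diff = np.abs(mat[:, colsA].mean(axis=1) - mat[:, colsB].mean(axis=1))
        k = int(np.argmax(diff))
        if diff[k] > best[2]:
            best = (contig, k, float(diff[k]))
    return best[0], best[1]


def _gamete(
    panel: HaplotypePanel, hap0: dict[str, np.ndarray], hap1: dict[str, np.ndarray],
    morgans_per_bp: float, rng,
) -> dict[str, np.ndarray]:
    """Meiotic product of a diploid parent: per contig, alternate between the
    two parental haplotypes at Poisson crossovers; contigs assort freely."""
    out = {}
    for contig, length in panel.contigs.items():
        pos = panel.positions[contig]
        n_x = rng.poisson(morgans_per_bp * length)
        breaks = np.sort(rng.integers(0, length, size=n_x))
        phase = int(rng.integers(0, 2))
        which = (phase + np.searchsorted(breaks, pos, side="right")) % 2
        out[contig] = np.where(which == 0, hap0[contig], hap1[contig])
    return out


def simulate_f2_cross(
    panel: HaplotypePanel,
    causal_site: tuple[str, int],
    beta: float,
    h2: float,
    n_f2: int,
    seed: int,
    founders_a: Sequence[str] | None = None,
    founders_b: Sequence[str] | None = None,
    popmap: PopMap | None = None,
    n_f1: int = 50,
    morgans_per_bp: float = 1.0e-6,
    polygenic_ratio: float = 0.5,
    n_polygenic: int = 100,
    trait: str = "ear_width",
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate an F2 intercross between two founder populations of ``panel``.

    F1 individuals pair one haplotype from each founder population; F2
    individuals are offspring of random F1 x F1 matings with recombination
    (``morgans_per_bp`` sets the genetic map; contigs assort independently).
    The phenotype is intercept + beta * causal dosage + a polygenic term
    (variance ``polygenic_ratio`` times the causal variance, from
    ``n_polygenic`` random background SNPs) + Gaussian noise scaled so the
    genetic variance fraction equals ``h2``.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    if founders_a is None or founders_b is None:
        if popmap is None:
            raise ValueError("supply founders_a/founders_b or a two-group popmap")
        groups = popmap.groups
        if len(groups) != 2:
            raise ValueError("popmap must define exactly two founder groups")
        founders_a = popmap.samples_in_group(groups[0])
        founders_b = popmap.samples_in_group(groups[1])
    rng = np.random.default_rng(seed)
    colsA = panel.sample_hap_indices(founders_a)
    colsB = panel.sample_hap_indices(founders_b)

    def hap_of(col: int) -> dict[str, np.ndarray]:
        return {c: panel.alleles[c][:, col].copy() for c in panel.contigs}

    f1 = [
        (hap_of(int(rng.choice(colsA))), hap_of(int(rng.choice(colsB))))
        for _ in range(n_f1)
    ]
    f2_h0, f2_h1 = [], []
    for _ in range(n_f2):
        i, j = rng.integers(0, n_f1, size=2)
        f2_h0.append(_gamete(panel, *f1[i], morgans_per_bp, rng))
        f2_h1.append(_gamete(panel, *f1[j], morgans_per_bp, rng))

    contigs = list(panel.contigs)
    snp_rows = []
    col_arrays = []
    for contig in contigs:
        pos = panel.positions[contig]
        dose = np.stack(
            [f2_h0[k][contig] + f2_h1[k][contig] for k in range(n_f2)]
        ).astype(np.float64)
        col_arrays.append(dose)
        for i, p in enumerate(pos):
            snp_rows.append({"snp": f"{contig}_{int(p) + 1}", "contig": contig, "pos": int(p)})
    matrix = np.concatenate(col_arrays, axis=1)
    snps = pd.DataFrame(snp_rows)
    samples = [f"F2_{k:04d}" for k in range(n_f2)]
    gt = GenotypeTable(samples, snps, matrix)

    c_contig, c_idx = causal_site
    offset = 0
    for contig in contigs:
        if contig == c_contig:
            causal_col = offset + c_idx
            break
        offset += len(panel.positions[contig])
    else:
        raise ValueError(f"causal contig {c_contig!r} not in panel")
    x = matrix[:, causal_col]

    g = beta * x
    if polygenic_ratio > 0 and beta != 0:
        bg = rng.choice(matrix.shape[1], size=min(n_polygenic, matrix.shape[1]), replace=False)
        eff = rng.normal(0.0, 1.0, size=len(bg))
        poly = (matrix[:, bg] - matrix[:, bg].mean(axis=0)) @ eff
        target = polygenic_ratio * np.var(beta * x)
        if np.var(poly) > 0 and target > 0:
            poly *= np.sqrt(target / np.var(poly))
            g = g + poly
    var_g = float(np.var(g))
    noise_sd = np.sqrt(var_g * (1 - h2) / h2) if var_g > 0 else 1.0
    y = 10.0 + g + rng.normal(0.0, noise_sd, size=n_f2)
    sex = rng.integers(0, 2, size=n_f2)
    phen = pd.DataFrame({"sample": samples, trait: y, "sex": sex})
    return gt, phen


# ---------------------------------------------------------------------------
# named study conditions


def _base_tree() -> list[tuple[str, str | None, float]]:
    """Outgroup at 3.12 Ma (bighorn depth), urial-depth donor at 1.26 Ma,
    non-introgressed European reference and four recipient meta-populations
    splitting 10 ka ago."""
    return [
        ("DOM_ANC", None, 3_200_000.0),
        ("OUT", "DOM_ANC", 3_120_000.0),
        ("WLD", "DOM_ANC", 1_260_000.0),
        ("EU_OA", "DOM_ANC", 10_000.0),
        ("DOM1", "DOM_ANC", 10_000.0),
        ("DOM2", "DOM_ANC", 10_000.0),
        ("DOM3", "DOM_ANC", 10_000.0),
        ("DOM4", "DOM_ANC", 10_000.0),
    ]


def default_config(seed: int = 0) -> SimConfig:
    """Default introgression fixture: one 10% pulse from the wild donor into
    meta-population DOM1, 6 ka ago (mean truth-tract length ~67 kb)."""
    return SimConfig(
        contig_length=2_000_000,
        mutation_density=1.0e-3,
        pop_tree=_base_tree(),
        n_haplotypes_per_pop={"OUT": 8, "WLD": 20, "EU_OA": 20,
                              "DOM1": 20, "DOM2": 20, "DOM3": 20, "DOM4": 20},
        pulses=[("WLD", "DOM1", 6_000.0, 0.1)],
        seed=seed,
    )


def null_config(seed: int = 0) -> SimConfig:
    """No-admixture fixture for false-positive / calibration checks."""
    cfg = default_config(seed)
    cfg.pulses = []
    return cfg


def outlier_config(seed: int = 0) -> SimConfig:
    """Outlier-recovery fixture: a strong (60%), recent (2 ka) pulse into
    DOM1 leaving long shared tracts (mean ~200 kb)."""
    cfg = default_config(seed)
    cfg.pulses = [("WLD", "DOM1", 2_000.0, 0.6)]
    return cfg


def f2_founder_config(seed: int = 0, n_contigs: int = 1,
                      contig_length: int = 5_000_000) -> SimConfig:
    """Two founder breeds for the F2 cross, 10 ka apart with breed-scale
    effective size (strong drift, many near-fixed differences)."""
    return SimConfig(
        contig_length=contig_length,
        n_contigs=n_contigs,
        mutation_density=1.0e-3,
        pop_tree=[
            ("BREED_ANC", None, 11_000.0),
            ("EF", "BREED_ANC", 10_000.0),
            ("HU", "BREED_ANC", 10_000.0),
        ],
        n_haplotypes_per_pop=40,
        effective_size=500.0,
        seed=seed,
    )


def f2_calibration_config(seed: int = 0, n_contigs: int = 1_200) -> SimConfig:
    """Unlinked mini-contigs for LMM null calibration (independent markers)."""
    cfg = f2_founder_config(seed, n_contigs=n_contigs, contig_length=1_000)
    cfg.mutation_density = 3.0e-3
    return cfg


# ---------------------------------------------------------------------------
# fixture suite


def generate_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the default fixture set: phased VCF, popmap TSV, truth BED,
    F2 genotype/phenotype TSVs and a config YAML. Deterministic: identical
    seeds give byte-identical files."""
    from . import io as _io  # local import to avoid a cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed)
    panel, truth = simulate_panel(cfg)
    popmap = popmap_for(cfg)

    paths = {
        "vcf": outdir / "panel.vcf",
        "popmap": outdir / "popmap.tsv",
        "truth_bed": outdir / "truth_tracts.bed",
        "config": outdir / "config.yaml",
        "f2_genotypes": outdir / "f2_genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    _io.write_phased_vcf(panel, paths["vcf"])
    _io.write_popmap(popmap, paths["popmap"])
    with open(paths["truth_bed"], "w") as fh:
        for t in truth:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.haplotype_id}\t{t.donor}\n")

    fcfg = f2_founder_config(seed)
    fpanel, _ = simulate_panel(fcfg)
    fmap = popmap_for(fcfg)
    causal = pick_causal_site(
        fpanel, fmap.samples_in_group("EF"), fmap.samples_in_group("HU")
    )
    gt, phen = simulate_f2_cross(
        fpanel, causal, beta=0.8, h2=0.4, n_f2=300, seed=seed,
        founders_a=fmap.samples_in_group("EF"), founders_b=fmap.samples_in_group("HU"),
    )
    gdf = pd.concat(
        [gt.snps, pd.DataFrame(gt.matrix.T, columns=gt.samples)], axis=1
    )
    gdf.to_csv(paths["f2_genotypes"], sep="\t", index=False, float_format="%g")
    phen.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6g")

    meta = {
        "seed": seed,
        "panel": {
            "contig_length": cfg.contig_length,
            "mutation_density": cfg.mutation_density,
            "pulses": [list(p) for p in cfg.pulses],
            "pop_tree": [list(e) for e in cfg.pop_tree],
        },
        "f2": {
            "causal_contig": causal[0],
            "causal_index": int(causal[1]),
            "causal_pos": int(fpanel.positions[causal[0]][causal[1]]),
            "beta": 0.8,
            "h2": 0.4,
            "n_f2": 300,
        },
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
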