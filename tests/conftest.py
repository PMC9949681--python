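"""Shared fixtures: synthetic panels at the package's default study
conditions, reused across test modules (session scope — simulation and
local-ancestry inference are the expensive steps)."""

import numpy as np
import pytest

import ovintro as ov


@pytest.fixture(scope="session")
def default_run():
    """10% donor pulse into DOM1, 6 ka ago (2-Mb contig)."""
    cfg = ov.default_config(seed=1)
    panel, truth = ov.simulate_panel(cfg)
    return cfg, panel, truth, ov.popmap_for(cfg)


@pytest.fixture(scope="session")
def null_run():
    """No admixture, five contigs (500 windows for calibration checks)."""
    cfg = ov.null_config(seed=3)
    cfg.n_contigs = 5
    panel, truth = ov.simulate_panel(cfg)
    return cfg, panel, truth, ov.popmap_for(cfg)


@pytest.fixture(scope="session")
def outlier_run():
    """Strong recent pulse (60%, 2 ka) into DOM1 leaving long shared tracts."""
    cfg = ov.outlier_config(seed=1)
    panel, truth = ov.simulate_panel(cfg)
    return cfg, panel, truth, ov.popmap_for(cfg)


@pytest.fixture(scope="session")
def default_lai(default_run):
    cfg, panel, truth, pm = default_run
    tracts = ov.infer_tracts(panel, pm, "DOM1", ["EU_OA", "WLD"], lam=1.5)
    return tracts


def tiny_panel(alleles, samples=None, contig="chr1", length=None):
    """Build a small panel from a (sites x haplotypes) list of 0/1/-1."""
    mat = np.asarray(alleles, dtype=np.int8)
    n_sites, n_haps = mat.shape
    assert n_haps % 2 == 0
    if samples is None:
        samples = [f"s{i}" for i in range(n_haps // 2)]
    positions = np.arange(1, n_sites + 1) * 100
    if length is None:
        length = int(positions[-1]) + 100
    return ov.HaplotypePanel(
        {contig: length}, {contig: positions}, {contig: mat}, list(samples)
    )
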