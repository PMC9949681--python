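"""Incomplete-lineage-sorting tract-length model.

Shared ancestral haplotypes that survive since the species split are broken up
by recombination on both descendant lineages; the expected surviving tract
length is L = 1/(r*T) with T the total branch length in generations (twice the
divergence time), and the length of a shared tract is approximately Gamma
distributed with shape 2 and rate 1/L, so introgression candidates much longer
than L are unlikely to be ILS remnants.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .lai import AncestryTract

log = logging.getLogger(__name__)


def expected_ils_length(
    r: float, divergence_years: float, gen_time: float = 4.0
) -> int:
    """Expected ILS shared-tract length in bp, rounded to the nearest bp.

    ``r`` is the recombination rate per bp per generation; the total branch
    length separating the two lineages is ``2 * divergence_years / gen_time``
    generations (recombination accumulates on both branches).
    """
    if r <= 0 or divergence_years <= 0 or gen_time <= 0:
        raise ValueError("all ILS parameters must be positive")
    total_generations = 2.0 * divergence_years / gen_time
    return int(round(1.0 / (r * total_generations)))


def ils_survival_prob(m: float, L: float) -> float:
    """Probability that an ILS tract is at least ``m`` bp long.

    1 - GammaCDF(m; shape=2, rate=1/L) = (1 + m/L) * exp(-m/L).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if m < 0:
        raise ValueError("m must be nonnegative")
    x = m / L
    return float((1.0 + x) * np.exp(-x))


def filter_tracts_by_L(
    tracts: Sequence[AncestryTract], L_by_source: Mapping[str, float]
) -> list[AncestryTract]:
    """Drop tracts shorter than the ILS expectation for their source.

    A tract of length exactly L is retained (only strictly shorter tracts are
    removed). Removal counts are logged per source.
    """
    removed: dict[str, int] = {}
    kept: list[AncestryTract] = []
    for t in tracts:
        if t.source not in L_by_source:
            raise KeyError(f"no expected ILS length for source {t.source!r}")
        if t.length < L_by_source[t.source]:
            removed[t.source] = removed.get(t.source, 0) + 1
        else:
            kept.append(t)
    for source, n in sorted(removed.items()):
        log.info("ILS filter removed %d tract(s) from source %s", n, source)
    return kept
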