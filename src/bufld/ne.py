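"""Effective population size from distance-binned LD (Sved's relation).

Under drift–recombination equilibrium the expected r² between loci at
recombination distance ``c`` Morgans satisfies

    E[r²] ≈ 1 / (1 + 4·Ne·c),

so a mean adjusted r² observed at distance ``c`` inverts to

    Ne = (1 / 4c) · (1 / r² − 1),

interpreted as the effective size roughly ``T = 1/(2c)`` generations ago:
tightly linked pairs carry old signal, loosely linked pairs recent signal.
Physical distance is converted to Morgans with a constant map rate
(default 1 cM per Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .ld import LDDecayBin

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapFunction:
    """Constant genetic-map rate in centimorgans per megabase."""

    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")


@dataclass
class NePoint:
    c: float  # Morgans
    T: float  # generations in the past, 1/(2c)
    Ne: float
    mean_r2_adj: float
    n_pairs: int


def distance_to_morgans(distance_bp: float, map_function: MapFunction | None = None) -> float:
    """bp → Morgans at a constant rate: bp · (cM/Mb) · 1e-8."""
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    rate = (map_function or MapFunction()).cm_per_mb
    return float(distance_bp) * rate * 1e-8


def generation_for_c(c: float) -> float:
    """Generations in the past sampled by LD at distance ``c``: T = 1/(2c)."""
    if c <= 0:
        raise ValueError(f"recombination distance must be positive, got {c}")
    return 1.0 / (2.0 * c)


def sved_ne(mean_r2_adj: float, c: float) -> float:
    """Invert Sved's relation: Ne = (1/4c)(1/r² − 1)."""
    if c <= 0:
        raise ValueError(f"recombination distance must be positive, got {c}")
    if mean_r2_adj <= 0:
        raise ValueError(
            "Ne undefined for non-positive mean adjusted r2 (skip the bin)"
        )
    return (1.0 / (4.0 * c)) * (1.0 / mean_r2_adj - 1.0)


def sved_expected_r2(ne: float, c: float) -> float:
    """Forward model E[r²] = 1/(1 + 4·Ne·c) (the inverse of :func:`sved_ne`)."""
    return 1.0 / (1.0 + 4.0 * ne * c)


def ne_trajectory(
    decay: list[LDDecayBin],
    map_function: MapFunction | None = None,
    use_midpoint: bool = True,
) -> list[NePoint]:
    """One Ne point per usable decay bin, sorted by T ascending (recent first).

    ``c`` is taken at the bin midpoint by default (deterministic given the
    binning); bins that are empty or whose adjusted mean r² is ≤ 0 are
    skipped with a logged count — the correction can push weak long-range
    LD below zero, which carries no Ne information.
    """
    if not decay:
        raise ValueError("no decay bins supplied")
    mapf = map_function or MapFunction()
    points = []
    skipped = 0
    for b in decay:
        if b.n_pairs == 0 or not b.mean_r2_adj > 0:
            skipped += 1
            continue
        if not use_midpoint:
            raise NotImplementedError("mean-pair-distance mode requires per-pair data")
        c = distance_to_morgans(b.midpoint_bp, mapf)
        points.append(
            NePoint(
                c=c,
                T=generation_for_c(c),
                Ne=sved_ne(b.mean_r2_adj, c),
                mean_r2_adj=b.mean_r2_adj,
                n_pairs=b.n_pairs,
            )
        )
    if skipped:
        log.info("ne_trajectory: skipped %d unusable bins", skipped)
    if not points:
        raise ValueError("every decay bin was empty or had non-positive adjusted r2")
    return sorted(points, key=lambda p: p.T)


def expected_diversity_loss(ne: float, generations: int) -> float:
    """Percent heterozygosity lost after ``generations`` at effective size ``ne``.

    Standard compounding: 100 · (1 − (1 − 1/(2·Ne))^g).  At Ne = 25 over 10
    generations this is ≈ 18%, the figure conservation guidelines quote.
    """
    if ne <= 0:
        raise ValueError("ne must be positive")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return 100.0 * (1.0 - (1.0 - 1.0 / (2.0 * ne)) ** generations)
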