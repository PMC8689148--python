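"""Forward-time Wright–Fisher simulator with recombination.

Generates phased diploid SNP genotypes whose LD structure arises purely
from genetic drift and recombination acting on initialized standing
variation (no new mutation):

* discrete non-overlapping generations, census ``n_diploids`` (optionally a
  schedule of change points) — the census is the truth value the LD-based
  Ne estimator should recover;
* each offspring draws two parents uniformly at random (selfing allowed,
  as in the idealized Wright–Fisher population);
* each transmitted gamete recombines with a Poisson(``chrom_length_morgans``)
  number of crossovers at uniform genetic positions;
* initial haplotypes are drawn site-independently with allele frequencies
  uniform in ``init_maf_range`` — the founder generation is in exact
  linkage equilibrium, so all LD observed later accrued by drift;
* physical positions are laid down at exactly 1 cM/Mb (bp = Morgans·1e8),
  so the pipeline's default map function is exact on simulated data.

Everything is reproducible from the single ``seed`` via numpy's PCG64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import VARIANT_COLUMNS, GenotypeDataset
from .io import write_plink_binary, write_plink_text, write_vcf

_BP_PER_MORGAN = 1e8  # 1 cM = 1 Mb


@dataclass
class SimConfig:
    """Wright–Fisher scenario description.

    Defaults give a small constant-size population (census 100) with two
    1-Morgan chromosomes at 250 loci each (~400 kb marker spacing), run for
    400 burn-in generations — long enough for drift–recombination
    equilibrium at short range — and sample 40 diploids, a size at which
    the finite-sample r² correction still matters visibly.
    """

    n_diploids: int = 100
    ne_schedule: list[tuple[int, int]] | None = None  # (generation, new census)
    n_chromosomes: int = 2
    chrom_length_morgans: float = 1.0
    n_loci_per_chromosome: int = 250
    init_maf_range: tuple[float, float] = (0.1, 0.5)
    burn_in_generations: int = 400
    split_generations: int | None = None
    sample_sizes: tuple[int, ...] = (40,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diploids < 1 or self.n_chromosomes < 1 or self.n_loci_per_chromosome < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.init_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("init_maf_range must lie within (0, 0.5]")
        if self.chrom_length_morgans < 0:
            raise ValueError("chromosome length cannot be negative")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations cannot be negative")

    def census_at(self, generation: int) -> int:
        size = self.n_diploids
        if self.ne_schedule:
            for g, s in sorted(self.ne_schedule):
                if generation >= g:
                    size = s
        return size


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    true_ne_by_generation: list[int]
    split_generations: int | None
    positions_bp: np.ndarray
    positions_morgans: np.ndarray
    chromosomes: np.ndarray
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "pos_bp": self.positions_bp,
                "pos_morgans": self.positions_morgans,
            }
        )


def _locus_map(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evenly spaced loci per chromosome; returns (chrom labels, M, bp)."""
    L = config.n_loci_per_chromosome
    length = config.chrom_length_morgans
    # interior grid keeps loci off the chromosome ends
    per_chrom_m = (np.arange(L) + 0.5) * (length / L) if length > 0 else np.zeros(L)
    chroms = np.repeat([str(c + 1) for c in range(config.n_chromosomes)], L)
    morgans = np.tile(per_chrom_m, config.n_chromosomes)
    bp = np.maximum(1, np.round(morgans * _BP_PER_MORGAN)).astype(np.int64)
    if length == 0:  # degenerate: distinct positions, zero genetic length
        bp = np.tile(np.arange(1, L + 1, dtype=np.int64), config.n_chromosomes)
    return chroms, morgans, bp


def _next_generation(
    haps: list[np.ndarray],
    n_offspring: int,
    locus_m: np.ndarray,
    chrom_len: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One Wright–Fisher generation; ``haps`` holds (2N, L) arrays per chromosome."""
    n_parents = haps[0].shape[0] // 2
    out = []
    n_gametes = 2 * n_offspring
    parents = rng.integers(n_parents, size=n_gametes)
    for hap in haps:
        L = hap.shape[1]
        k = rng.poisson(chrom_len, size=n_gametes)
        kmax = int(k.max()) if n_gametes else 0
        start = rng.integers(2, size=n_gametes)
        if kmax == 0 or chrom_len == 0:
            choice = np.broadcast_to(start[:, None], (n_gametes, L))
        else:
            xo = rng.uniform(0.0, chrom_len, size=(n_gametes, kmax))
            xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf  # pad unused slots
            n_before = (xo[:, :, None] <= locus_m[None, None, :]).sum(axis=1)
            choice = (start[:, None] + n_before) & 1
        h0 = hap[2 * parents]
        h1 = hap[2 * parents + 1]
        out.append(np.where(choice == 0, h0, h1).astype(np.int8))
    return out


def _init_population(config: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = config.init_maf_range
    haps = []
    for _ in range(config.n_chromosomes):
        freqs = rng.uniform(lo, hi, size=config.n_loci_per_chromosome)
        haps.append(
            (rng.random((2 * config.n_diploids, config.n_loci_per_chromosome)) < freqs)
            .astype(np.int8)
        )
    return haps


def _sample_dataset(
    haps: list[np.ndarray],
    config: SimConfig,
    rng: np.random.Generator,
    n_sample: int,
    label: str,
    chroms: np.ndarray,
    bp: np.ndarray,
    individuals: np.ndarray | None = None,
) -> GenotypeDataset:
    census = haps[0].shape[0] // 2
    if n_sample > census:
        raise ValueError(f"cannot sample {n_sample} from census {census}")
    if individuals is None:
        individuals = rng.choice(census, size=n_sample, replace=False)
    rows = np.ravel(np.column_stack([2 * individuals, 2 * individuals + 1]))
    hap = np.hstack([h[rows] for h in haps])
    calls = hap[0::2] + hap[1::2]
    L = config.n_loci_per_chromosome
    variants = pd.DataFrame(
        {
            "id": [f"snp_{c}_{i % L}" for i, c in enumerate(chroms)],
            "chrom": chroms,
            "pos": bp,
            "ref": "A",
            "alt": "C",
        }
    )[VARIANT_COLUMNS]
    return GenotypeDataset(
        samples=[(f"{label}_{i}", label) for i in range(n_sample)],
        variants=variants,
        calls=calls,
        haplotypes=hap,
        phased=True,
    )


def simulate_wf(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Run the Wright–Fisher scenario and sample one population.

    Monomorphic sites (lost or fixed by drift) are retained — QC removes
    them exactly as it would on real array data.
    """
    rng = np.random.default_rng(config.seed)
    chroms, morgans, bp = _locus_map(config)
    locus_m = (np.arange(config.n_loci_per_chromosome) + 0.5) * (
        config.chrom_length_morgans / config.n_loci_per_chromosome
    ) if config.chrom_length_morgans > 0 else np.zeros(config.n_loci_per_chromosome)
    haps = _init_population(config, rng)
    ne_by_gen = []
    for g in range(config.burn_in_generations):
        census = config.census_at(g)
        ne_by_gen.append(census)
        haps = _next_generation(haps, census, locus_m, config.chrom_length_morgans, rng)
    ds = _sample_dataset(
        haps, config, rng, config.sample_sizes[0], "pop1", chroms, bp
    )
    truth = SimTruth(
        true_ne_by_generation=ne_by_gen,
        split_generations=None,
        positions_bp=bp,
        positions_morgans=morgans,
        chromosomes=chroms,
        seed=config.seed,
    )
    return ds, truth


def simulate_split(
    config: SimConfig,
) -> tuple[GenotypeDataset, GenotypeDataset, SimTruth]:
    """Two populations diverging from one ancestor.

    The ancestor evolves ``burn_in_generations``, is duplicated, and each
    copy evolves ``split_generations`` more before sampling.  With
    ``split_generations = 0`` the *same* individuals are sampled for both
    outputs, so phase agreement is exact by construction.
    """
    if config.split_generations is None:
        raise ValueError("split_generations must be set for simulate_split")
    rng = np.random.default_rng(config.seed)
    chroms, morgans, bp = _locus_map(config)
    locus_m = (np.arange(config.n_loci_per_chromosome) + 0.5) * (
        config.chrom_length_morgans / config.n_loci_per_chromosome
    ) if config.chrom_length_morgans > 0 else np.zeros(config.n_loci_per_chromosome)
    haps = _init_population(config, rng)
    ne_by_gen = []
    for g in range(config.burn_in_generations):
        census = config.census_at(g)
        ne_by_gen.append(census)
        haps = _next_generation(haps, census, locus_m, config.chrom_length_morgans, rng)

    sizes = config.sample_sizes if len(config.sample_sizes) >= 2 else config.sample_sizes * 2
    if config.split_generations == 0:
        census = haps[0].shape[0] // 2
        individuals = rng.choice(census, size=sizes[0], replace=False)
        ds_a = _sample_dataset(haps, config, rng, sizes[0], "popA", chroms, bp, individuals)
        ds_b = _sample_dataset(haps, config, rng, sizes[0], "popB", chroms, bp, individuals)
    else:
        branches = []
        for label, n_sample in zip(("popA", "popB"), sizes):
            bh = [h.copy() for h in haps]
            for g in range(config.split_generations):
                census = config.census_at(config.burn_in_generations + g)
                bh = _next_generation(bh, census, locus_m, config.chrom_length_morgans, rng)
            branches.append(_sample_dataset(bh, config, rng, n_sample, label, chroms, bp))
        ds_a, ds_b = branches
    truth = SimTruth(
        true_ne_by_generation=ne_by_gen,
        split_generations=config.split_generations,
        positions_bp=bp,
        positions_morgans=morgans,
        chromosomes=chroms,
        seed=config.seed,
    )
    return ds_a, ds_b, truth


def write_fixture(
    ds: GenotypeDataset, format: str, path: str | Path
) -> list[Path]:
    """Write a dataset as ``plink_text``, ``plink_binary`` or ``vcf`` files."""
    writers = {
        "plink_text": write_plink_text,
        "plink_binary": write_plink_binary,
        "vcf": write_vcf,
    }
    if format not in writers:
        raise ValueError(f"unknown fixture format '{format}'")
    return writers[format](ds, path)
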