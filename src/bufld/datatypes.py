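"""Core containers shared by every stage of the LD pipeline.

A :class:`GenotypeDataset` is the universal currency: a sample table with
population labels, a sorted variant map, a dosage matrix counting copies of
the alternate allele, and (optionally) phased haplotypes.  Dosages live in
``{0, 1, 2, MISSING}`` with :data:`MISSING` = -1 as the sentinel; every
downstream operation states its missing-data policy explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (distinct from the 0/1/2 dosages).
MISSING: int = -1

#: Chromosome labels treated as aliases of the X chromosome.  Buffalo/bovine
#: arrays label BTA X as chromosome "30"; both spellings are accepted.
X_ALIASES: frozenset[str] = frozenset({"X", "30"})

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class GenotypeError(ValueError):
    """Inconsistent genotype data (shape, alleles, or encoding)."""


class FormatError(GenotypeError):
    """A genotype file violates its format contract."""


class UndefinedLDError(ValueError):
    """LD is undefined for the pair (a locus is monomorphic or constant)."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: identifier, map position and its two alleles."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise GenotypeError(f"variant {self.id}: ref and alt alleles are equal")
        if self.pos < 0:
            raise GenotypeError(f"variant {self.id}: negative position")


def chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Sort numerically labelled chromosomes first, X/other labels after."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class GenotypeDataset:
    """Diploid SNP genotypes for one labelled population (or a pool).

    Parameters
    ----------
    samples
        ``(sample_id, population_label)`` pairs, one per row of ``calls``.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` sorted by
        ``(chrom, pos)``; one row per column of ``calls``.
    calls
        ``(n_samples, n_variants)`` int8 matrix of alternate-allele dosages
        in ``{0, 1, 2}`` with :data:`MISSING` for no-calls.
    haplotypes
        Optional ``(2 * n_samples, n_variants)`` matrix of phased alleles in
        ``{0, 1}``; rows ``2k`` and ``2k + 1`` are sample ``k``'s gametes.
    phased
        True iff ``haplotypes`` is present and authoritative.
    """

    samples: list[tuple[str, str]]
    variants: pd.DataFrame
    calls: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False
    counted_allele: str = "alt"  # dosage counts the alternate allele
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if list(self.variants.columns[:5]) != VARIANT_COLUMNS:
            raise GenotypeError(
                f"variant table must have columns {VARIANT_COLUMNS}, "
                f"got {list(self.variants.columns)}"
            )
        n, m = self.calls.shape
        if n != len(self.samples):
            raise GenotypeError(
                f"calls has {n} rows but {len(self.samples)} samples are declared"
            )
        if m != len(self.variants):
            raise GenotypeError(
                f"calls has {m} columns but {len(self.variants)} variants are declared"
            )
        if any(not pop for _, pop in self.samples):
            raise GenotypeError("every sample needs a non-empty population label")
        if self.phased:
            if self.haplotypes is None:
                raise GenotypeError("phased dataset without haplotypes")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * n, m):
                raise GenotypeError(
                    f"haplotypes shape {self.haplotypes.shape} != ({2 * n}, {m})"
                )
            dose = self.haplotypes[0::2] + self.haplotypes[1::2]
            ok = self.calls == MISSING
            if not np.array_equal(dose[~ok], self.calls[~ok]):
                raise GenotypeError("haplotype pairs do not sum to the dosages")
        self.variants = self.variants.reset_index(drop=True)

    # -- convenience ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.samples]

    @property
    def populations(self) -> list[str]:
        return sorted({pop for _, pop in self.samples})

    @property
    def population(self) -> str:
        """Label of a single-population dataset (joined labels for pools)."""
        pops = self.populations
        return pops[0] if len(pops) == 1 else "+".join(pops)

    def variant_keys(self) -> list[tuple[str, str, int]]:
        """Marker identity: ``(id, chrom, pos)`` triples in map order."""
        v = self.variants
        return list(zip(v["id"], v["chrom"].astype(str), v["pos"].astype(int)))

    def take_variants(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, index],
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        hap = None
        if self.haplotypes is not None:
            rows = np.ravel(np.column_stack([2 * index, 2 * index + 1]))
            hap = self.haplotypes[rows]
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            calls=self.calls[index],
            haplotypes=hap,
        )

    def relabel(self, population: str) -> "GenotypeDataset":
        return replace(self, samples=[(sid, population) for sid, _ in self.samples])

    def sort_variants(self) -> "GenotypeDataset":
        order = sorted(
            range(self.n_variants),
            key=lambda i: (
                chrom_sort_key(self.variants["chrom"].iloc[i]),
                int(self.variants["pos"].iloc[i]),
            ),
        )
        return self.take_variants(order)


def make_variant_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.id, str(r.chrom), int(r.pos), r.ref, r.alt) for r in records],
        columns=VARIANT_COLUMNS,
    )


def concat_samples(datasets: Sequence[GenotypeDataset], label: str) -> GenotypeDataset:
    """Stack samples of marker-identical datasets under one pool label."""
    first = datasets[0]
    keys = first.variant_keys()
    for ds in datasets[1:]:
        if ds.variant_keys() != keys:
            raise GenotypeError(
                "datasets do not share a marker set; run intersect_on_common_markers first"
            )
    phased = all(ds.phased for ds in datasets)
    hap = np.vstack([ds.haplotypes for ds in datasets]) if phased else None
    return GenotypeDataset(
        samples=[(sid, label) for ds in datasets for sid, _ in ds.samples],
        variants=first.variants.copy(),
        calls=np.vstack([ds.calls for ds in datasets]),
        haplotypes=hap,
        phased=phased,
    )
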