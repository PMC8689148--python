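"""Genotype editing: call-rate, HWE and MAF filters, then common-marker merge.

The filter order mirrors standard array QC practice: (1) individuals with
poor genotyping success, (2) SNPs with poor call rate, (3) SNPs out of
Hardy-Weinberg equilibrium, (4) monomorphic SNPs and SNPs below the MAF
floor — all applied within each population — then (5) the populations are
merged onto their common marker set.  Remaining missing calls are filled by
per-population mode imputation so downstream LD code may assume complete
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeDataset
from .io import intersect_on_common_markers

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common SNP-array practice.

    max_missing_individual
        Drop individuals missing more than this fraction of calls (MIND).
    max_missing_snp
        Drop SNPs missing in more than this fraction of individuals (GENO).
    min_maf
        Minor-allele-frequency floor; monomorphic SNPs always fail it.
    hwe_p_cutoff
        Exact-test p-value at or below which a SNP is removed
        (Bonferroni-style default 5.7e-7).
    """

    max_missing_individual: float = 0.05
    max_missing_snp: float = 0.05
    min_maf: float = 0.05
    hwe_p_cutoff: float = 5.7e-7
    hwe_scope: str = "per_population"  # or "merged"
    hwe_midp: bool = False

    def __post_init__(self) -> None:
        for name in ("max_missing_individual", "max_missing_snp", "min_maf"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.hwe_p_cutoff < 1:
            raise ValueError("hwe_p_cutoff must be in (0, 1)")
        if self.hwe_scope not in ("per_population", "merged"):
            raise ValueError("hwe_scope must be 'per_population' or 'merged'")


@dataclass
class QCReport:
    individuals_removed: int = 0
    snps_removed_missing: int = 0
    snps_removed_hwe: int = 0
    snps_removed_maf: dict[str, int] = field(default_factory=dict)
    snps_after_merge: int = 0
    total_genotyping_rate: float = float("nan")
    missing_calls_imputed: int = 0

    def as_dict(self) -> dict:
        return {
            "individuals_removed": self.individuals_removed,
            "snps_removed_missing": self.snps_removed_missing,
            "snps_removed_hwe": self.snps_removed_hwe,
            **{f"snps_removed_maf_{p}": c for p, c in self.snps_removed_maf.items()},
            "snps_after_merge": self.snps_after_merge,
            "total_genotyping_rate": self.total_genotyping_rate,
            "missing_calls_imputed": self.missing_calls_imputed,
        }


class PopulationEmptiedError(RuntimeError):
    """A filter removed every sample or every marker of a population."""


# ---------------------------------------------------------------------------
# elementary statistics


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF of one SNP from alternate-allele dosages (missing = -1 ignored)."""
    d = np.asarray(dosages)
    d = d[d != MISSING]
    if d.size == 0:
        raise ValueError("MAF undefined: all calls are missing")
    p = d.sum() / (2 * d.size)
    return float(min(p, 1 - p))


def hwe_exact_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, midp: bool = False
) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the conditional probabilities that are no larger than the
    observed one (probability-mass ordering, two-sided).  ``midp`` counts the
    observed configuration with weight one half.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele count
    probs = _hwe_het_distribution(n, n_rare)
    obs = probs[n_het]
    # relative tie tolerance so exact-tie configurations (symmetric tables)
    # are included despite floating-point jitter
    p = probs[probs <= obs * (1 + 1e-9) + 1e-300].sum()
    if midp:
        p -= 0.5 * obs
    return float(min(p, 1.0))


def _hwe_het_distribution(n: int, n_rare: int) -> np.ndarray:
    """Conditional distribution of the heterozygote count given allele totals.

    ``probs[h]`` is P(het = h | n genotypes, n_rare copies of the rarer
    allele); entries for infeasible ``h`` are zero.  Uses the standard
    ratio recurrence, normalised at the end.
    """
    probs = np.zeros(n + 1)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) // 2 + hets <= n]
    hets = hets[(2 * n - n_rare - hets) >= 0]
    # start from the mid-range het count and fill outward for stability
    h0 = int(hets[len(hets) // 2])
    vals = {h0: 1.0}
    # P(h+2)/P(h) = [h! rare_hom! com_hom! ] ratio: moving h -> h+2 converts one
    # rare hom + one common hom into two hets
    for h in range(h0, int(hets[-1]) - 1, 2):
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        vals[h + 2] = vals[h] * (4.0 * rare_hom * com_hom) / ((h + 2.0) * (h + 1.0))
    for h in range(h0, int(hets[0]) + 1, -2):
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        vals[h - 2] = vals[h] * (h * (h - 1.0)) / (4.0 * (rare_hom + 1.0) * (com_hom + 1.0))
    total = sum(vals.values())
    for h, v in vals.items():
        probs[h] = v / total
    return probs


def mode_impute(ds: GenotypeDataset) -> tuple[GenotypeDataset, int]:
    """Fill missing calls with the per-SNP modal dosage (ties -> ref hom).

    A coarse stand-in for haplotype-based imputation; adequate only because
    QC has already capped per-SNP missingness.
    """
    calls = ds.calls.copy()
    n_filled = 0
    for j in range(calls.shape[1]):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            fill = 0
        else:
            counts = np.bincount(obs, minlength=3)
            fill = int(np.flatnonzero(counts == counts.max())[0])  # tie -> 0
        col[miss] = fill
        n_filled += int(miss.sum())
    out = GenotypeDataset(
        samples=ds.samples,
        variants=ds.variants.copy(),
        calls=calls,
        haplotypes=ds.haplotypes,
        phased=ds.phased,
    )
    return out, n_filled


# ---------------------------------------------------------------------------
# the pipeline step


def run_qc(
    datasets: list[GenotypeDataset], thresholds: QCThresholds | None = None
) -> tuple[list[GenotypeDataset], QCReport]:
    """Apply the two-step editing to one dataset per population.

    Order: individual call rate -> SNP call rate -> HWE -> monomorphic/MAF
    (each within its population) -> intersection on common markers -> mode
    imputation of any remaining missing calls.
    """
    if not datasets:
        raise ValueError("run_qc needs at least one dataset")
    thr = thresholds or QCThresholds()
    report = QCReport()
    filtered: list[GenotypeDataset] = []

    for ds in datasets:
        pop = ds.population
        miss = ds.calls == MISSING

        ind_frac = miss.mean(axis=1)
        keep_ind = np.flatnonzero(ind_frac <= thr.max_missing_individual)
        if keep_ind.size == 0:
            raise PopulationEmptiedError(
                f"population {pop}: individual call-rate filter removed every sample"
            )
        report.individuals_removed += ds.n_samples - keep_ind.size
        ds = ds.take_samples(keep_ind)
        miss = ds.calls == MISSING

        snp_frac = miss.mean(axis=0)
        keep_snp = np.flatnonzero(snp_frac <= thr.max_missing_snp)
        report.snps_removed_missing += ds.n_variants - keep_snp.size
        ds = _take_or_raise(ds, keep_snp, pop, "SNP call-rate")

        if thr.hwe_scope == "per_population":
            keep_hwe = _hwe_keep_mask(ds, thr)
            report.snps_removed_hwe += ds.n_variants - keep_hwe.size
            ds = _take_or_raise(ds, keep_hwe, pop, "HWE")

        mafs = _maf_vector(ds)
        keep_maf = np.flatnonzero(mafs >= thr.min_maf)
        report.snps_removed_maf[pop] = int(ds.n_variants - keep_maf.size)
        ds = _take_or_raise(ds, keep_maf, pop, "MAF/monomorphic")
        filtered.append(ds)

    # genotyping rate of the surviving matrices, before imputation
    total_calls = sum(ds.calls.size for ds in filtered)
    total_miss = sum(int((ds.calls == MISSING).sum()) for ds in filtered)
    report.total_genotyping_rate = 1 - total_miss / total_calls if total_calls else 1.0

    if len(filtered) > 1:
        filtered = intersect_on_common_markers(filtered)
    if thr.hwe_scope == "merged":
        keep = None
        for ds in filtered:
            mask = np.zeros(ds.n_variants, dtype=bool)
            mask[_hwe_keep_mask(ds, thr)] = True
            keep = mask if keep is None else (keep & mask)
        idx = np.flatnonzero(keep)
        report.snps_removed_hwe += int(keep.size - idx.size)
        filtered = [_take_or_raise(ds, idx, ds.population, "HWE") for ds in filtered]
    report.snps_after_merge = filtered[0].n_variants

    imputed = []
    for ds in filtered:
        ds2, n_filled = mode_impute(ds)
        report.missing_calls_imputed += n_filled
        imputed.append(ds2)
    return imputed, report


def _take_or_raise(ds, idx, pop, stage):
    if len(idx) == 0:
        raise PopulationEmptiedError(
            f"population {pop}: {stage} filter removed every marker"
        )
    return ds.take_variants(idx)


def _hwe_keep_mask(ds: GenotypeDataset, thr: QCThresholds) -> np.ndarray:
    pvals = np.ones(ds.n_variants)
    for j in range(ds.n_variants):
        col = ds.calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=3)
        pvals[j] = hwe_exact_test(
            int(counts[0]), int(counts[1]), int(counts[2]), midp=thr.hwe_midp
        )
    return np.flatnonzero(pvals > thr.hwe_p_cutoff)


def _maf_vector(ds: GenotypeDataset) -> np.ndarray:
    out = np.zeros(ds.n_variants)
    for j in range(ds.n_variants):
        col = ds.calls[:, j]
        col = col[col != MISSING]
        out[j] = 0.0 if col.size == 0 else minor_allele_frequency(col)
    return out
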