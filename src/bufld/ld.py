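"""Pairwise linkage disequilibrium: D, D', r, r², the finite-sample
correction, adjacent-SNP summaries, and distance-binned decay curves.

Two estimation paths exist and are chosen by the ``phased`` flag:

* phased — gametes are counted directly from haplotypes; the signed r is
  the correlation of the two 0/1 gamete vectors, which equals
  ``D / sqrt(fA·fa·fB·fb)``; the correction uses β = 2;
* unphased — r is the product-moment correlation of the two dosage
  vectors (composite LD); the correction uses β = 1, reflecting the extra
  uncertainty of the unknown gametic phase.

The sample-size correction ``r²_adj = r² − 1/(β·n)`` subtracts the
expectation of r² under linkage equilibrium at sample size ``n``; adjusted
values may be negative and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeDataset, UndefinedLDError, chrom_sort_key

GENOME_WIDE = "ALL"


# ---------------------------------------------------------------------------
# haplotype frequencies and the classical two-locus statistics


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Allele and AB-haplotype frequencies of one SNP pair.

    ``A``/``B`` denote the allele coded 1 (the counted, alternate allele) at
    the first and second locus; ``a``/``b`` the complementary alleles.
    """

    freq_A: float
    freq_B: float
    freq_AB: float
    n_gametes: int

    @property
    def freq_a(self) -> float:
        return 1.0 - self.freq_A

    @property
    def freq_b(self) -> float:
        return 1.0 - self.freq_B


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    r: float
    r2: float


@dataclass
class LDPair:
    """LD of one SNP pair, with the sample-size-corrected r²."""

    variant_i: str
    variant_j: str
    distance_bp: int
    D: float
    D_prime: float
    r: float
    r2: float
    r2_adj: float
    n: int
    beta: int


def haplotype_freqs_phased(hap_i: np.ndarray, hap_j: np.ndarray) -> HaplotypeFreqs:
    """Count gametes: vectors of {0,1} alleles, one entry per gamete."""
    hap_i = np.asarray(hap_i)
    hap_j = np.asarray(hap_j)
    if hap_i.shape != hap_j.shape or hap_i.ndim != 1:
        raise ValueError(
            f"gamete vectors must be equal-length 1-D, got {hap_i.shape} vs {hap_j.shape}"
        )
    n = hap_i.size
    return HaplotypeFreqs(
        freq_A=float(hap_i.mean()),
        freq_B=float(hap_j.mean()),
        freq_AB=float(np.mean((hap_i == 1) & (hap_j == 1))),
        n_gametes=n,
    )


def ld_from_freqs(f: HaplotypeFreqs) -> LDStats:
    """D, Lewontin's D' and the allelic correlation from haplotype freqs.

    ``D = f_AB − f_A·f_B``; ``r = D / sqrt(f_A f_a f_B f_b)``;
    ``D' = |D| / D_max`` with ``D_max = min(f_A f_b, f_a f_B)`` for D > 0
    and ``min(f_A f_B, f_a f_b)`` for D < 0.  Undefined if a locus is
    monomorphic.
    """
    fA, fa, fB, fb = f.freq_A, f.freq_a, f.freq_B, f.freq_b
    if min(fA, fa, fB, fb) <= 0:
        raise UndefinedLDError("LD undefined: a locus is monomorphic")
    D = f.freq_AB - fA * fB
    r = D / np.sqrt(fA * fa * fB * fb)
    if D > 0:
        d_max = min(fA * fb, fa * fB)
    elif D < 0:
        d_max = min(fA * fB, fa * fb)
    else:
        return LDStats(D=0.0, D_prime=0.0, r=0.0, r2=0.0)
    return LDStats(D=float(D), D_prime=float(abs(D) / d_max), r=float(r), r2=float(r * r))


def r_unphased(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """Signed composite r: dosage correlation over complete pairs."""
    di = np.asarray(dosages_i, dtype=float)
    dj = np.asarray(dosages_j, dtype=float)
    if di.shape != dj.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (di != MISSING) & (dj != MISSING)
    di, dj = di[ok], dj[ok]
    if di.size < 2:
        raise UndefinedLDError("need at least two complete sample pairs")
    if np.ptp(di) == 0 or np.ptp(dj) == 0:
        raise UndefinedLDError("LD undefined: zero dosage variance at a locus")
    return float(np.corrcoef(di, dj)[0, 1])


def adjust_r2(r2: float, n: int, phased: bool) -> float:
    """Sample-size/phase correction ``r² − 1/(β·n)``, β = 2 if phased else 1.

    The result may be negative (the correction can exceed a small r²); such
    values are passed through and handled downstream.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    beta = 2 if phased else 1
    return float(r2 - 1.0 / (beta * n))


def ld_pair(ds: GenotypeDataset, i: int, j: int, phased: bool) -> LDPair:
    """Full LD record for the variant pair at column indices ``i`` and ``j``."""
    vi = ds.variants.iloc[i]
    vj = ds.variants.iloc[j]
    if str(vi["chrom"]) != str(vj["chrom"]):
        raise ValueError("LD pairs are intra-chromosomal")
    n = ds.n_samples
    if phased:
        f = haplotype_freqs_phased(ds.haplotypes[:, i], ds.haplotypes[:, j])
        stats = ld_from_freqs(f)
    else:
        r = r_unphased(ds.calls[:, i], ds.calls[:, j])
        dp = _d_prime_pairs(ds, False, np.array([i]), np.array([j]))[0]
        di = ds.calls[:, i].astype(float)
        dj = ds.calls[:, j].astype(float)
        D = float(np.cov(di, dj, bias=True)[0, 1]) / 2
        stats = LDStats(D=D, D_prime=float(dp), r=r, r2=r * r)
    return LDPair(
        variant_i=str(vi["id"]),
        variant_j=str(vj["id"]),
        distance_bp=abs(int(vi["pos"]) - int(vj["pos"])),
        D=stats.D,
        D_prime=stats.D_prime,
        r=stats.r,
        r2=stats.r2,
        r2_adj=adjust_r2(stats.r2, n, phased),
        n=n,
        beta=2 if phased else 1,
    )


# ---------------------------------------------------------------------------
# vectorised per-chromosome machinery


def _chrom_order(ds: GenotypeDataset) -> list[str]:
    seen = []
    for c in ds.variants["chrom"].astype(str):
        if c not in seen:
            seen.append(c)
    return sorted(seen, key=chrom_sort_key)


def _column_matrix(ds: GenotypeDataset, phased: bool, idx: np.ndarray) -> np.ndarray:
    """Gamete (phased) or dosage (unphased) columns for the given variants.

    The matrix routines require complete data (run QC/imputation first);
    missing dosages raise.
    """
    if phased:
        if not ds.phased or ds.haplotypes is None:
            raise ValueError("phased=True but the dataset carries no haplotypes")
        return ds.haplotypes[:, idx].astype(np.float64)
    sub = ds.calls[:, idx]
    if (sub == MISSING).any():
        raise ValueError(
            "matrix LD routines need complete dosages; run QC imputation first"
        )
    return sub.astype(np.float64)


def signed_r_matrix(X: np.ndarray) -> np.ndarray:
    """Column-wise correlation matrix; monomorphic columns give NaN."""
    Xc = X - X.mean(axis=0)
    sd = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = np.where(sd > 0, Xc / np.where(sd > 0, sd, 1.0), np.nan)
    R = Xn.T @ Xn
    return np.clip(R, -1.0, 1.0, out=R)


def pair_table(
    ds: GenotypeDataset,
    phased: bool,
    max_bp: float | None = None,
    scheme: str = "all",
):
    """Signed r for intra-chromosomal SNP pairs.

    Yields ``(chrom, i, j, dist_bp, r)`` arrays per chromosome, with global
    variant indices ``i < j``.  ``scheme`` is ``all`` (every pair within
    ``max_bp``) or ``adjacent`` (consecutive markers only).  Pairs where
    either locus is monomorphic carry NaN and are the caller's to drop.
    """
    if scheme not in ("all", "adjacent"):
        raise ValueError(f"unknown pair scheme '{scheme}'")
    chroms = ds.variants["chrom"].astype(str).to_numpy()
    pos = ds.variants["pos"].to_numpy(dtype=np.int64)
    for chrom in _chrom_order(ds):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < 2:
            continue
        R = signed_r_matrix(_column_matrix(ds, phased, idx))
        p = pos[idx]
        if scheme == "adjacent":
            ii = np.arange(idx.size - 1)
            jj = ii + 1
        else:
            ii, jj = np.triu_indices(idx.size, k=1)
        dist = p[jj] - p[ii]
        if max_bp is not None:
            keep = dist <= max_bp
            ii, jj, dist = ii[keep], jj[keep], dist[keep]
        yield chrom, idx[ii], idx[jj], dist, R[ii, jj]


# ---------------------------------------------------------------------------
# adjacent-SNP summaries


@dataclass
class AdjacentLDSummary:
    chromosome: str
    n_snps: int
    n_pairs: int
    n_pairs_undefined: int
    mean_spacing_kb: float
    mean_r2_adj: float
    sd_r2_adj: float
    mean_d_prime: float
    sd_d_prime: float
    fraction_r2_adj_above: dict[float, float] = field(default_factory=dict)


def _d_prime_pairs(
    ds: GenotypeDataset, phased: bool, gi: np.ndarray, gj: np.ndarray
) -> np.ndarray:
    """|D'| per pair; for unphased data D is the Burrows composite
    estimate cov(g_i, g_j)/2 normalised by the allele-frequency D_max."""
    out = np.full(gi.size, np.nan)
    for k, (i, j) in enumerate(zip(gi, gj)):
        if phased:
            f = haplotype_freqs_phased(ds.haplotypes[:, i], ds.haplotypes[:, j])
            try:
                out[k] = ld_from_freqs(f).D_prime
            except UndefinedLDError:
                continue
        else:
            di = ds.calls[:, i].astype(float)
            dj = ds.calls[:, j].astype(float)
            ok = (di != MISSING) & (dj != MISSING)
            di, dj = di[ok], dj[ok]
            fA, fB = di.mean() / 2, dj.mean() / 2
            if not (0 < fA < 1 and 0 < fB < 1):
                continue
            D = float(np.cov(di, dj, bias=True)[0, 1]) / 2
            if D > 0:
                d_max = min(fA * (1 - fB), (1 - fA) * fB)
            elif D < 0:
                d_max = min(fA * fB, (1 - fA) * (1 - fB))
            else:
                out[k] = 0.0
                continue
            out[k] = min(abs(D) / d_max, 1.0)
    return out


def adjacent_ld_summary(
    ds: GenotypeDataset,
    phased: bool,
    thresholds: tuple[float, ...] = (0.2, 0.3),
) -> list[AdjacentLDSummary]:
    """Per-chromosome and genome-wide LD between consecutive markers.

    Reports mean spacing, mean ± sd of the adjusted r² and of |D'|, and the
    fraction of adjacent pairs whose adjusted r² exceeds each threshold.
    Pairs with undefined LD (monomorphic loci) are excluded and counted.
    Chromosomes with fewer than two markers are skipped.
    """
    n = ds.n_samples
    rows: list[AdjacentLDSummary] = []
    all_r2a: list[np.ndarray] = []
    all_dp: list[np.ndarray] = []
    all_gaps: list[np.ndarray] = []
    tot_snps = 0
    tot_undef = 0
    for chrom, gi, gj, dist, r in pair_table(ds, phased, scheme="adjacent"):
        defined = ~np.isnan(r)
        r2_adj = np.array([adjust_r2(v * v, n, phased) for v in r[defined]])
        dp = _d_prime_pairs(ds, phased, gi[defined], gj[defined])
        n_snps = int((ds.variants["chrom"].astype(str) == chrom).sum())
        rows.append(
            _summary_row(chrom, n_snps, dist, r2_adj, dp, int((~defined).sum()), thresholds)
        )
        tot_snps += n_snps
        tot_undef += int((~defined).sum())
        all_r2a.append(r2_adj)
        all_dp.append(dp)
        all_gaps.append(dist)
    if not rows:
        return rows
    rows.append(
        _summary_row(
            GENOME_WIDE,
            tot_snps,
            np.concatenate(all_gaps),
            np.concatenate(all_r2a),
            np.concatenate(all_dp),
            tot_undef,
            thresholds,
        )
    )
    return rows


def _summary_row(chrom, n_snps, gaps, r2_adj, dp, n_undef, thresholds):
    dp = dp[~np.isnan(dp)]
    return AdjacentLDSummary(
        chromosome=str(chrom),
        n_snps=n_snps,
        n_pairs=int(r2_adj.size),
        n_pairs_undefined=n_undef,
        mean_spacing_kb=float(np.mean(gaps) / 1e3) if gaps.size else float("nan"),
        mean_r2_adj=float(np.mean(r2_adj)) if r2_adj.size else float("nan"),
        sd_r2_adj=float(np.std(r2_adj, ddof=1)) if r2_adj.size > 1 else float("nan"),
        mean_d_prime=float(np.mean(dp)) if dp.size else float("nan"),
        sd_d_prime=float(np.std(dp, ddof=1)) if dp.size > 1 else float("nan"),
        fraction_r2_adj_above={
            t: float(np.mean(r2_adj > t)) if r2_adj.size else float("nan")
            for t in thresholds
        },
    )


# ---------------------------------------------------------------------------
# distance-binned decay


@dataclass
class LDDecayBin:
    """One physical-distance interval ``(lower_bp, upper_bp]`` of the decay
    curve, with the unweighted mean raw and adjusted r² over its pairs."""

    lower_bp: int
    upper_bp: int
    n_pairs: int
    mean_r2: float
    mean_r2_adj: float

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.lower_bp + self.upper_bp)


def ld_decay(
    ds: GenotypeDataset,
    max_bp: float = 15e6,
    bin_bp: float = 1e5,
    phased: bool = True,
) -> list[LDDecayBin]:
    """Mean r² of intra-chromosomal pairs in contiguous distance bins.

    Bins are ``(k·bin_bp, (k+1)·bin_bp]`` covering ``(0, max_bp]``; each
    usable pair contributes to exactly one bin.  Pairs with undefined LD are
    dropped.  Deterministic given the dataset.
    """
    bin_bp = int(bin_bp)
    max_bp = int(max_bp)
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if max_bp < bin_bp:
        raise ValueError("max_bp must be at least one bin wide")
    n_bins = max_bp // bin_bp
    n = ds.n_samples
    beta_term = 1.0 / ((2 if phased else 1) * n)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, _, _, dist, r in pair_table(ds, phased, max_bp=max_bp, scheme="all"):
        ok = ~np.isnan(r)
        d, rr = dist[ok], r[ok]
        b = (d - 1) // bin_bp  # (0, bin] -> 0, etc.; positions are unique so d >= 1
        inside = (b >= 0) & (b < n_bins)
        np.add.at(sums, b[inside], rr[inside] ** 2)
        np.add.at(counts, b[inside], 1)
    bins = []
    for k in range(n_bins):
        if counts[k] > 0:
            mean_r2 = sums[k] / counts[k]
            bins.append(
                LDDecayBin(
                    lower_bp=k * bin_bp,
                    upper_bp=(k + 1) * bin_bp,
                    n_pairs=int(counts[k]),
                    mean_r2=float(mean_r2),
                    mean_r2_adj=float(mean_r2 - beta_term),
                )
            )
        else:
            bins.append(
                LDDecayBin(
                    lower_bp=k * bin_bp,
                    upper_bp=(k + 1) * bin_bp,
                    n_pairs=0,
                    mean_r2=float("nan"),
                    mean_r2_adj=float("nan"),
                )
            )
    return bins
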