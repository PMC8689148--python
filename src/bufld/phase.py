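"""Persistence of LD phase (PLDP) between two populations.

For each shared SNP pair the signed r (the square root of r² carrying the
sign of D) is computed in each population; PLDP in a distance bin is the
product-moment correlation of those signed values over the bin's pairs:

    r_bin = Σ (r_ij(A) − r̄_A)(r_ij(B) − r̄_B) / (S_A · S_B)

with S the corresponding deviation norms.  A PLDP near 1 means marker–QTL
phase learned in one population transfers to the other; it decays with both
marker distance and the populations' divergence time.

Signed r is only comparable across populations when both count the same
allele at every marker, hence :func:`align_alleles` must run first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import MISSING, GenotypeDataset, GenotypeError
from .ld import pair_table

log = logging.getLogger(__name__)

#: strand-ambiguous allele pairs (indistinguishable after strand flip)
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

MIN_PAIRS_PER_BIN = 3


@dataclass
class PLDPBin:
    lower_bp: int
    upper_bp: int
    n_pairs: int
    correlation: float | None  # None when fewer than MIN_PAIRS_PER_BIN pairs


@dataclass
class PLDPResult:
    population_a: str
    population_b: str
    bins: list[PLDPBin]
    n_pairs_dropped: int = 0  # monomorphic in either population


def align_alleles(
    ds_a: GenotypeDataset, ds_b: GenotypeDataset
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Make dataset B count the same allele as dataset A at every marker.

    Where B's ref/alt are swapped relative to A, B's dosages are
    complemented (2 − d) and its haplotypes flipped.  Markers whose allele
    pairs differ even after the swap are an error; strand-ambiguous A/T and
    C/G markers are flagged in ``meta['ambiguous_strand']`` (alignment by
    allele letters cannot detect a strand flip there).
    """
    if ds_a.variant_keys() != ds_b.variant_keys():
        raise GenotypeError(
            "datasets must share an identical marker set; "
            "run intersect_on_common_markers first"
        )
    va, vb = ds_a.variants, ds_b.variants
    same = (va["ref"].to_numpy() == vb["ref"].to_numpy()) & (
        va["alt"].to_numpy() == vb["alt"].to_numpy()
    )
    swapped = (va["ref"].to_numpy() == vb["alt"].to_numpy()) & (
        va["alt"].to_numpy() == vb["ref"].to_numpy()
    )
    bad = ~(same | swapped)
    if bad.any():
        names = list(va.loc[bad, "id"])
        raise GenotypeError(
            f"{bad.sum()} markers have irreconcilable allele pairs: {names[:10]}"
        )
    ambiguous = [
        str(i)
        for i, r, a in zip(va["id"], va["ref"], va["alt"])
        if frozenset({r, a}) in _AMBIGUOUS
    ]
    if ambiguous:
        log.warning("%d strand-ambiguous (A/T, C/G) markers", len(ambiguous))

    flip = swapped & ~same
    calls = ds_b.calls.copy()
    cols = np.flatnonzero(flip)
    mask = calls[:, cols] != MISSING
    calls[:, cols] = np.where(mask, 2 - calls[:, cols], MISSING)
    hap = None
    if ds_b.haplotypes is not None:
        hap = ds_b.haplotypes.copy()
        hap[:, cols] = 1 - hap[:, cols]
    new_vb = vb.copy()
    new_vb.loc[flip, ["ref", "alt"]] = va.loc[flip, ["ref", "alt"]].to_numpy()
    out_b = replace(ds_b, variants=new_vb, calls=calls, haplotypes=hap)
    out_a = replace(ds_a, meta={**ds_a.meta, "ambiguous_strand": ambiguous})
    out_b.meta = {**out_b.meta, "ambiguous_strand": ambiguous, "flipped": len(cols)}
    return out_a, out_b


def signed_r_vectors(
    ds_a: GenotypeDataset,
    ds_b: GenotypeDataset,
    pair_scheme: str = "all",
    max_bp: float = 1e6,
    phased: bool = True,
):
    """Per-pair signed r in both populations over the shared pair list.

    Returns ``(dist, r_a, r_b, n_dropped)`` over intra-chromosomal pairs
    within ``max_bp`` (or adjacent pairs), keeping only pairs polymorphic in
    both populations.
    """
    if ds_a.variant_keys() != ds_b.variant_keys():
        raise GenotypeError("datasets must share an identical marker set")
    parts_d, parts_a, parts_b = [], [], []
    table_b = {
        chrom: (gi, gj, r)
        for chrom, gi, gj, _, r in pair_table(ds_b, phased, max_bp=max_bp, scheme=pair_scheme)
    }
    for chrom, gi, gj, dist, r_a in pair_table(
        ds_a, phased, max_bp=max_bp, scheme=pair_scheme
    ):
        gi_b, gj_b, r_b = table_b[chrom]
        assert np.array_equal(gi, gi_b) and np.array_equal(gj, gj_b)
        parts_d.append(dist)
        parts_a.append(r_a)
        parts_b.append(r_b)
    dist = np.concatenate(parts_d) if parts_d else np.array([], dtype=np.int64)
    r_a = np.concatenate(parts_a) if parts_a else np.array([])
    r_b = np.concatenate(parts_b) if parts_b else np.array([])
    ok = ~(np.isnan(r_a) | np.isnan(r_b))
    return dist[ok], r_a[ok], r_b[ok], int((~ok).sum())


def phase_correlation(r_a: np.ndarray, r_b: np.ndarray) -> float:
    """Correlation of signed r between two populations over one set of pairs:
    Σ(r_ij(A) − r̄_A)(r_ij(B) − r̄_B) / (S_A·S_B) with S the deviation norms."""
    xa = np.asarray(r_a, dtype=float)
    xb = np.asarray(r_b, dtype=float)
    if xa.shape != xb.shape or xa.ndim != 1:
        raise ValueError("signed-r vectors must be equal-length 1-D")
    da = xa - xa.mean()
    db = xb - xb.mean()
    sa = np.sqrt((da**2).sum())
    sb = np.sqrt((db**2).sum())
    if sa == 0 or sb == 0:
        raise ValueError("phase correlation undefined: constant signed-r vector")
    return float(np.clip((da * db).sum() / (sa * sb), -1.0, 1.0))


def pldp(
    ds_a: GenotypeDataset,
    ds_b: GenotypeDataset,
    pair_scheme: str = "all",
    bin_bp: float = 1e5,
    max_bp: float = 1e6,
    phased: bool = True,
) -> PLDPResult:
    """Correlation of LD phase between two populations, per distance bin.

    ``pair_scheme`` is ``all`` (every intra-chromosomal pair within
    ``max_bp``, the default, binned at ``bin_bp``) or ``adjacent``.  Bins
    with fewer than three usable pairs report no correlation.  Requires
    allele-aligned datasets (see :func:`align_alleles`).
    """
    bin_bp = int(bin_bp)
    max_bp = int(max_bp)
    if bin_bp <= 0 or max_bp < bin_bp:
        raise ValueError("need 0 < bin_bp <= max_bp")
    dist, r_a, r_b, dropped = signed_r_vectors(
        ds_a, ds_b, pair_scheme=pair_scheme, max_bp=max_bp, phased=phased
    )
    n_bins = max_bp // bin_bp
    b = (dist - 1) // bin_bp
    bins = []
    for k in range(n_bins):
        sel = b == k
        n_pairs = int(sel.sum())
        corr = None
        if n_pairs >= MIN_PAIRS_PER_BIN:
            try:
                corr = phase_correlation(r_a[sel], r_b[sel])
            except ValueError:
                corr = None
        bins.append(
            PLDPBin(
                lower_bp=k * bin_bp,
                upper_bp=(k + 1) * bin_bp,
                n_pairs=n_pairs,
                correlation=corr,
            )
        )
    return PLDPResult(
        population_a=ds_a.population,
        population_b=ds_b.population,
        bins=bins,
        n_pairs_dropped=dropped,
    )
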