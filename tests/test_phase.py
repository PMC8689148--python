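"""Allele alignment and persistence of LD phase between populations."""

import numpy as np
import pytest

from bufld import (
    SimConfig,
    align_alleles,
    phase_correlation,
    pldp,
    simulate_split,
)
from bufld.datatypes import GenotypeError

from conftest import build_dataset


def test_phase_correlation_worked_example():
    """Hand-evaluated signed-r correlation, cross-checked with numpy."""
    r_a = np.array([0.1, 0.4, 0.2, 0.5])
    r_b = np.array([0.2, 0.5, 0.1, 0.6])
    got = phase_correlation(r_a, r_b)
    assert got == pytest.approx(0.9204, abs=5e-5)
    assert got == pytest.approx(np.corrcoef(r_a, r_b)[0, 1], abs=1e-12)


def flipped_copy(ds, cols):
    """Same genotypes with ref/alt swapped (and dosages complemented) at cols."""
    calls = ds.calls.copy()
    calls[:, cols] = 2 - calls[:, cols]
    hap = None
    if ds.haplotypes is not None:
        hap = ds.haplotypes.copy()
        hap[:, cols] = 1 - hap[:, cols]
    refs = list(ds.variants["ref"])
    alts = list(ds.variants["alt"])
    for c in cols:
        refs[c], alts[c] = alts[c], refs[c]
    return build_dataset(
        calls,
        pos=list(ds.variants["pos"]),
        chroms=list(ds.variants["chrom"]),
        population="B",
        haplotypes=hap,
        refs=refs,
        alts=alts,
    )


@pytest.fixture
def pair_of_datasets():
    rng = np.random.default_rng(5)
    hap = (rng.random((20, 6)) < 0.5).astype(np.int8)
    calls = hap[0::2] + hap[1::2]
    pos = [10_000 * (j + 1) for j in range(6)]
    ds = build_dataset(calls, pos=pos, haplotypes=hap, population="A")
    return ds


def test_align_alleles_identity_and_involution(pair_of_datasets):
    ds = pair_of_datasets
    same_a, same_b = align_alleles(ds, flipped_copy(ds, []))
    np.testing.assert_array_equal(same_b.calls, ds.calls)
    assert same_b.meta["flipped"] == 0

    flipped = flipped_copy(ds, [2])
    _, restored = align_alleles(ds, flipped)
    assert restored.meta["flipped"] == 1
    np.testing.assert_array_equal(restored.calls, ds.calls)
    np.testing.assert_array_equal(restored.haplotypes, ds.haplotypes)
    # applying the involution twice returns the original
    again = flipped_copy(flipped_copy(ds, [2]), [2])
    np.testing.assert_array_equal(again.calls, ds.calls)


def test_align_alleles_rejects_foreign_alleles(pair_of_datasets):
    ds = pair_of_datasets
    other = flipped_copy(ds, [])
    other.variants.loc[1, ["ref", "alt"]] = ["G", "T"]
    with pytest.raises(GenotypeError, match="irreconcilable"):
        align_alleles(ds, other)


def test_pldp_self_comparison_is_one(pair_of_datasets):
    ds = pair_of_datasets
    res = pldp(ds, ds.relabel("B"), bin_bp=1e4, max_bp=1e5, phased=True)
    defined = [b for b in res.bins if b.correlation is not None]
    assert defined, "expected at least one defined bin"
    for b in defined:
        assert b.correlation == pytest.approx(1.0, abs=1e-12)


def test_pldp_symmetric(pair_of_datasets):
    ds = pair_of_datasets
    other = flipped_copy(ds, [1, 4])
    _, other = align_alleles(ds, other)
    ab = pldp(ds, other, bin_bp=1e4, max_bp=1e5, phased=True)
    ba = pldp(other, ds, bin_bp=1e4, max_bp=1e5, phased=True)
    for x, y in zip(ab.bins, ba.bins):
        assert x.n_pairs == y.n_pairs
        if x.correlation is not None:
            assert x.correlation == pytest.approx(y.correlation, abs=1e-12)


def test_unaligned_coding_flips_the_sign_of_r():
    """Flipping one marker of a pair negates that pair's signed r; alignment
    restores it."""
    rng = np.random.default_rng(9)
    hap = (rng.random((40, 2)) < 0.5).astype(np.int8)
    calls = hap[0::2] + hap[1::2]
    ds = build_dataset(calls, pos=[10_000, 30_000], haplotypes=hap, population="A")
    from bufld.ld import pair_table

    (_, _, _, _, r_orig), = pair_table(ds, phased=True, scheme="adjacent")
    flipped = flipped_copy(ds, [0])
    (_, _, _, _, r_flip), = pair_table(flipped, phased=True, scheme="adjacent")
    assert r_flip[0] == pytest.approx(-r_orig[0], abs=1e-12)
    _, aligned = align_alleles(ds, flipped)
    (_, _, _, _, r_back), = pair_table(aligned, phased=True, scheme="adjacent")
    assert r_back[0] == pytest.approx(r_orig[0], abs=1e-12)


def test_split_time_zero_gives_identical_samples_and_unit_pldp():
    cfg = SimConfig(
        n_diploids=60,
        n_chromosomes=1,
        n_loci_per_chromosome=40,
        burn_in_generations=30,
        split_generations=0,
        sample_sizes=(25,),
        seed=21,
    )
    ds_a, ds_b, truth = simulate_split(cfg)
    np.testing.assert_array_equal(ds_a.calls, ds_b.calls)
    res = pldp(ds_a, ds_b, bin_bp=5e6, max_bp=5e7, phased=True)
    defined = [b for b in res.bins if b.correlation is not None]
    assert defined
    for b in defined:
        assert b.correlation == pytest.approx(1.0, abs=1e-12)


def test_pldp_bins_with_too_few_pairs_are_undefined(pair_of_datasets):
    ds = pair_of_datasets
    res = pldp(ds, ds.relabel("B"), bin_bp=1e4, max_bp=1e5, phased=True)
    for b in res.bins:
        if b.n_pairs < 3:
            assert b.correlation is None
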