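"""Two-locus LD statistics, the finite-sample correction, and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bufld import (
    adjacent_ld_summary,
    adjust_r2,
    haplotype_freqs_phased,
    ld_decay,
    ld_from_freqs,
    r_unphased,
)
from bufld.datatypes import UndefinedLDError
from bufld.ld import HaplotypeFreqs

from conftest import build_dataset, gametes_from_counts


# ---------------------------------------------------------------------------
# brute-force oracle on the 2x2 gamete table


def ld_oracle(hap_i, hap_j):
    """Independent route: r by product-moment correlation of the gamete
    indicator vectors; D by mean cross-product; D' from the frequency
    bounds of the AB-haplotype frequency."""
    hap_i = np.asarray(hap_i, float)
    hap_j = np.asarray(hap_j, float)
    fA, fB = hap_i.mean(), hap_j.mean()
    D = np.mean(hap_i * hap_j) - fA * fB
    r = np.corrcoef(hap_i, hap_j)[0, 1]
    if D > 0:
        d_max = min(fA, fB) - fA * fB  # fAB can rise to min(fA, fB)
    elif D < 0:
        d_max = fA * fB - max(0.0, fA + fB - 1.0)  # fAB can fall to max(0, fA+fB-1)
    else:
        return 0.0, 0.0, 0.0, 0.0
    return D, abs(D) / d_max, r, r * r


def test_haplotype_counting_worked_example():
    hap_i, hap_j = gametes_from_counts(n_ab=40, n_aB=10, n_Ab=10, n_AB=40)
    f = haplotype_freqs_phased(hap_i, hap_j)
    assert f.freq_A == pytest.approx(0.5)
    assert f.freq_B == pytest.approx(0.5)
    assert f.freq_AB == pytest.approx(0.40)
    assert f.n_gametes == 100
    stats = ld_from_freqs(f)
    assert stats.D == pytest.approx(0.15)
    assert stats.r2 == pytest.approx(0.36)
    assert stats.D_prime == pytest.approx(0.6)


def test_degenerate_and_null_tables():
    all_ab = haplotype_freqs_phased(np.ones(10, dtype=int), np.ones(10, dtype=int))
    assert all_ab.freq_AB == all_ab.freq_A == all_ab.freq_B == 1.0
    with pytest.raises(UndefinedLDError):
        ld_from_freqs(all_ab)  # monomorphic
    eq = haplotype_freqs_phased(*gametes_from_counts(25, 25, 25, 25))
    assert eq.freq_AB == pytest.approx(eq.freq_A * eq.freq_B)
    stats = ld_from_freqs(eq)
    assert stats.D == stats.r2 == stats.D_prime == 0.0


def test_perfect_coupling():
    f = HaplotypeFreqs(freq_A=0.5, freq_B=0.5, freq_AB=0.5, n_gametes=100)
    stats = ld_from_freqs(f)
    assert stats.D == pytest.approx(0.25)
    assert stats.r2 == pytest.approx(1.0)
    assert stats.D_prime == pytest.approx(1.0)


def test_ld_matches_bruteforce_oracle_on_random_small_tables():
    """ld_from_freqs vs the 2x2 enumeration oracle: 1,000 random gamete sets
    of <= 20 gametes, agreement to 1e-12."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 1000:
        n = int(rng.integers(4, 21))
        hap_i = rng.integers(0, 2, n)
        hap_j = rng.integers(0, 2, n)
        if np.ptp(hap_i) == 0 or np.ptp(hap_j) == 0:
            continue
        stats = ld_from_freqs(haplotype_freqs_phased(hap_i, hap_j))
        D, dp, r, r2 = ld_oracle(hap_i, hap_j)
        assert stats.D == pytest.approx(D, abs=1e-12)
        assert stats.D_prime == pytest.approx(dp, abs=1e-12)
        assert stats.r == pytest.approx(r, abs=1e-12)
        assert stats.r2 == pytest.approx(r2, abs=1e-12)
        checked += 1


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    counts=st.tuples(*[st.integers(0, 30)] * 4).filter(
        lambda t: (t[0] + t[1]) * (t[2] + t[3]) * (t[0] + t[2]) * (t[1] + t[3]) > 0
    )
)
def test_ld_invariants(counts):
    """r² and D' stay in [0,1] and |r| <= D' for every gamete table."""
    n_ab, n_aB, n_Ab, n_AB = counts
    hap_i, hap_j = gametes_from_counts(n_ab, n_aB, n_Ab, n_AB)
    stats = ld_from_freqs(haplotype_freqs_phased(hap_i, hap_j))
    assert 0.0 <= stats.r2 <= 1.0 + 1e-12
    assert 0.0 <= stats.D_prime <= 1.0 + 1e-12
    assert abs(stats.r) <= stats.D_prime + 1e-12


def test_r_unphased_identity_reflection_and_sampling():
    d = np.array([0, 1, 2, 1, 0, 2])
    assert r_unphased(d, d) == pytest.approx(1.0)
    assert r_unphased(d, 2 - d) == pytest.approx(-1.0)
    with pytest.raises(UndefinedLDError):
        r_unphased(d, np.ones_like(d))
    # random diploid pairing of the 40/10/10/40 gamete table: the dosage
    # correlation estimates the gametic r = +0.6
    rng = np.random.default_rng(3)
    hap_i, hap_j = gametes_from_counts(400, 100, 100, 400)
    perm = rng.permutation(1000)
    gi, gj = hap_i[perm], hap_j[perm]
    dos_i = gi[0::2] + gi[1::2]
    dos_j = gj[0::2] + gj[1::2]
    assert r_unphased(dos_i, dos_j) == pytest.approx(0.6, abs=0.08)


def test_adjust_r2_correction():
    # worked example: n = 15 unphased drops 0.34 by 1/15 to 0.2733
    assert adjust_r2(0.34, 15, phased=False) == pytest.approx(0.34 - 1 / 15)
    assert adjust_r2(0.36, 10, phased=True) == pytest.approx(0.31)
    assert adjust_r2(0.05, 10, phased=False) == pytest.approx(-0.05)
    # phased correction is exactly half the unphased one
    for n in (5, 33, 200):
        unphased_drop = 0.5 - adjust_r2(0.5, n, phased=False)
        phased_drop = 0.5 - adjust_r2(0.5, n, phased=True)
        assert phased_drop == pytest.approx(unphased_drop / 2)
    with pytest.raises(ValueError):
        adjust_r2(0.2, 0, phased=False)


# ---------------------------------------------------------------------------
# adjacent summaries and decay


def perfect_ld_dataset(n=20):
    """Three equally spaced markers in perfect mutual LD on one chromosome."""
    hap = np.tile(np.array([[1], [0]] * n, dtype=np.int8), (1, 3))
    calls = hap[0::2] + hap[1::2]
    return build_dataset(calls, pos=[10_000, 20_000, 30_000], haplotypes=hap)


def test_adjacent_summary_perfect_ld():
    ds = perfect_ld_dataset(n=20)
    rows = adjacent_ld_summary(ds, phased=True)
    per_chrom = rows[0]
    assert per_chrom.mean_r2_adj == pytest.approx(1 - 1 / 40)
    assert per_chrom.fraction_r2_adj_above[0.2] == 1.0
    assert per_chrom.fraction_r2_adj_above[0.3] == 1.0
    assert per_chrom.mean_d_prime == pytest.approx(1.0)
    assert per_chrom.mean_spacing_kb == pytest.approx(10.0)
    # single chromosome: genome-wide row repeats the chromosome row
    genome = rows[-1]
    assert genome.chromosome == "ALL"
    assert genome.mean_r2_adj == pytest.approx(per_chrom.mean_r2_adj)
    assert genome.n_pairs == per_chrom.n_pairs


def test_adjacent_summary_fraction_monotone_in_threshold(wf_dataset):
    ds, _, _ = wf_dataset
    from bufld import run_qc

    (ds,), _ = run_qc([ds])
    rows = adjacent_ld_summary(ds, phased=True, thresholds=(0.1, 0.2, 0.3, 0.5))
    for row in rows:
        fr = [row.fraction_r2_adj_above[t] for t in (0.1, 0.2, 0.3, 0.5)]
        assert all(a >= b for a, b in zip(fr, fr[1:]))


def test_linkage_equilibrium_mean_adjusted_r2_near_zero():
    """Unlinked loci: mean raw r² ≈ 1/(2n), mean adjusted r² ≈ 0."""
    rng = np.random.default_rng(11)
    n = 50
    n_pairs = 400
    freqs = rng.uniform(0.2, 0.5, 2 * n_pairs)
    hap = (rng.random((2 * n, 2 * n_pairs)) < freqs).astype(np.int8)
    r2 = []
    for k in range(n_pairs):
        f = haplotype_freqs_phased(hap[:, 2 * k], hap[:, 2 * k + 1])
        try:
            r2.append(ld_from_freqs(f).r2)
        except UndefinedLDError:
            continue
    r2 = np.array(r2)
    se = r2.std(ddof=1) / np.sqrt(r2.size)
    assert abs(r2.mean() - 1 / (2 * n)) < 3 * se
    adj = r2 - 1 / (2 * n)
    assert abs(adj.mean()) < 3 * se


def test_decay_bin_assignment_and_empty_bins(make_dataset):
    hap = np.array([[1, 1], [0, 0], [1, 1], [0, 0]], dtype=np.int8)
    calls = hap[0::2] + hap[1::2]
    ds = make_dataset(calls, pos=[50_000, 200_000], haplotypes=hap)
    bins = ld_decay(ds, max_bp=1e6, bin_bp=1e5, phased=True)
    # the single pair is 150 kb apart -> bin (100 kb, 200 kb]
    assert [b.n_pairs for b in bins[:3]] == [0, 1, 0]
    assert bins[1].lower_bp == 100_000 and bins[1].upper_bp == 200_000
    # all-distant dataset: everything out of range
    far = make_dataset(calls, pos=[1, 5_000_000], haplotypes=hap)
    assert all(b.n_pairs == 0 for b in ld_decay(far, max_bp=1e6, bin_bp=1e5, phased=True))
    with pytest.raises(ValueError):
        ld_decay(ds, max_bp=1e4, bin_bp=1e5, phased=True)


def test_decay_is_nonincreasing_on_wf_simulation(wf_dataset):
    """Drift-generated LD decays with distance across the first bins."""
    ds, _, _ = wf_dataset
    from bufld import run_qc

    (ds,), _ = run_qc([ds])
    bins = ld_decay(ds, max_bp=15e6, bin_bp=1e5, phased=True)
    used = [b for b in bins if b.n_pairs > 0][:10]
    means = np.array([b.mean_r2_adj for b in used])
    # allow modest sampling jitter between neighbouring bins
    assert means[0] > means[-1]
    assert all(means[i + 1] <= means[i] + 0.05 for i in range(len(means) - 1))


def test_sample_permutation_changes_nothing(wf_dataset):
    ds, _, _ = wf_dataset
    perm = np.random.default_rng(0).permutation(ds.n_samples)
    shuffled = ds.take_samples(perm)
    a = ld_decay(ds, max_bp=2e6, bin_bp=1e5, phased=True)
    b = ld_decay(shuffled, max_bp=2e6, bin_bp=1e5, phased=True)
    for x, y in zip(a, b):
        assert x.n_pairs == y.n_pairs
        if x.n_pairs:
            assert x.mean_r2 == pytest.approx(y.mean_r2, abs=1e-12)
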