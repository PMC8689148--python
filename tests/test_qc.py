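"""Per-population genotype editing: MAF, exact HWE test, and run_qc."""

import numpy as np
import pytest
from scipy.special import gammaln

from bufld import QCThresholds, hwe_exact_test, minor_allele_frequency, run_qc
from bufld.datatypes import MISSING
from bufld.qc import PopulationEmptiedError

from conftest import build_dataset


# ---------------------------------------------------------------------------
# independent HWE oracle: closed-form conditional probabilities


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p-value from the closed-form Levene-Haldane distribution.

    P(het = h | n, nA) = n! nA! na! 2^h / (hom_r! h! hom_c! (2n)!) summed over
    every h with probability <= that of the observed count.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    hs = hs[(n_rare - hs) // 2 + hs <= n]
    hom_r = (n_rare - hs) // 2
    hom_c = n - hs - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hs + 1)
        - gammaln(hom_c + 1)
        + hs * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard fp drift; sums to 1 analytically
    obs = probs[hs == n_het][0]
    return float(probs[probs <= obs * (1 + 1e-9)].sum())


def test_maf_examples():
    assert minor_allele_frequency([0, 0, 0, 0]) == 0.0
    assert minor_allele_frequency([1, 1, 1, 1]) == 0.5
    # (2,1,0,missing): 3 alt alleles among 6 -> p = 0.5
    assert minor_allele_frequency([2, 1, 0, MISSING]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        minor_allele_frequency([MISSING, MISSING])


def test_hwe_boundary_and_extreme_cases():
    # perfectly HWE-proportioned table: observed het count is the conditional
    # mode, so nearly all probability mass is included
    assert hwe_exact_test(25, 50, 25) >= 0.99
    assert hwe_exact_test(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)
    # total heterozygote deficit is astronomically unlikely
    assert hwe_exact_test(50, 0, 50) < 1e-20
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


@pytest.mark.parametrize("seed", [0, 1])
def test_hwe_matches_enumeration_oracle_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(200):
        n = int(rng.integers(1, 120))
        nA = int(rng.integers(0, n + 1))
        het = int(rng.integers(nA % 2, nA + 1))
        if (het - nA) % 2 or (nA - het) // 2 + het > n:
            continue
        hom_r = (nA - het) // 2
        hom_c = n - het - hom_r
        p = hwe_exact_test(hom_c, het, hom_r)
        assert p == pytest.approx(hwe_oracle(hom_c, het, hom_r), abs=1e-12)


def test_hwe_conditional_distribution_normalises():
    from bufld.qc import _hwe_het_distribution

    for n, n_rare in [(10, 7), (50, 50), (100, 3), (1, 1)]:
        assert _hwe_het_distribution(n, n_rare).sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# run_qc


def toy_qc_dataset():
    """4 individuals x 5 SNPs; individual 1 misses 2/5 calls and carries the
    only copy of SNP 4's alternate allele."""
    calls = np.array(
        [
            [0, 1, 2, 1, 0],
            [MISSING, MISSING, 1, 1, 1],
            [1, 1, 0, 2, 0],
            [2, 1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return build_dataset(calls)


def test_toy_qc_removes_one_individual_and_one_snp():
    ds = toy_qc_dataset()
    out, report = run_qc([ds])
    assert report.individuals_removed == 1
    assert out[0].n_samples == 3
    assert out[0].n_variants == 4
    total_snps_removed = (
        report.snps_removed_missing
        + report.snps_removed_hwe
        + sum(report.snps_removed_maf.values())
    )
    assert total_snps_removed == 1
    assert report.snps_removed_maf["pop1"] == 1
    # surviving matrix is complete after imputation
    assert (out[0].calls != MISSING).all()


def test_qc_noop_on_clean_data():
    calls = np.array([[0, 1], [1, 2], [2, 1], [1, 0]], dtype=np.int8)
    out, report = run_qc([build_dataset(calls)])
    assert report.individuals_removed == 0
    assert report.snps_after_merge == 2
    assert sum(report.snps_removed_maf.values()) == 0
    np.testing.assert_array_equal(out[0].calls, calls)


def test_qc_idempotent():
    ds = toy_qc_dataset()
    once, _ = run_qc([ds])
    twice, report2 = run_qc(once)
    np.testing.assert_array_equal(once[0].calls, twice[0].calls)
    assert report2.individuals_removed == 0
    assert sum(report2.snps_removed_maf.values()) == 0


def test_monomorphic_in_one_population_leaves_merged_panel():
    a = build_dataset(np.array([[0, 1], [1, 2], [2, 1]], dtype=np.int8), population="A")
    b = build_dataset(np.array([[0, 1], [0, 2], [0, 1]], dtype=np.int8), population="B")
    out, report = run_qc([a, b])
    assert report.snps_after_merge == 1
    assert all(ds.n_variants == 1 for ds in out)
    assert out[0].variants["id"].tolist() == ["snp1"]


def test_genotyping_rate_matches_surviving_matrix():
    ds = toy_qc_dataset()
    _, report = run_qc([ds])
    # recompute by hand: after dropping individual 1, no missing calls remain
    assert report.total_genotyping_rate == pytest.approx(1.0)


def test_population_emptied_raises_with_population_name():
    ds = build_dataset(np.array([[0, 0], [0, 0]], dtype=np.int8), population="EGY")
    with pytest.raises(PopulationEmptiedError, match="EGY"):
        run_qc([ds])


def test_threshold_validation():
    with pytest.raises(ValueError):
        QCThresholds(min_maf=0.0)
    with pytest.raises(ValueError):
        QCThresholds(hwe_scope="bogus")
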