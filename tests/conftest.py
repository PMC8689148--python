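"""Shared fixtures: hand-built toy datasets and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bufld import GenotypeDataset, SimConfig, simulate_wf
from bufld.datatypes import VARIANT_COLUMNS


def build_dataset(
    calls,
    pos=None,
    chroms=None,
    population="pop1",
    haplotypes=None,
    refs=None,
    alts=None,
):
    """Assemble a GenotypeDataset from a plain dosage matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pos = list(pos) if pos is not None else [1000 * (j + 1) for j in range(m)]
    chroms = [str(c) for c in (chroms if chroms is not None else ["1"] * m)]
    refs = refs if refs is not None else ["A"] * m
    alts = alts if alts is not None else ["C"] * m
    variants = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chroms,
            "pos": pos,
            "ref": refs,
            "alt": alts,
        }
    )[VARIANT_COLUMNS]
    return GenotypeDataset(
        samples=[(f"s{i}", population) for i in range(n)],
        variants=variants,
        calls=calls,
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
        phased=haplotypes is not None,
    )


@pytest.fixture
def make_dataset():
    return build_dataset


@pytest.fixture(scope="session")
def wf_dataset():
    """One modest Wright–Fisher sample reused by read-only tests."""
    cfg = SimConfig(
        n_diploids=100,
        n_chromosomes=2,
        n_loci_per_chromosome=120,
        burn_in_generations=120,
        sample_sizes=(30,),
        seed=7,
    )
    ds, truth = simulate_wf(cfg)
    return ds, truth, cfg


def gametes_from_counts(n_ab: int, n_aB: int, n_Ab: int, n_AB: int):
    """Two gamete vectors realising the 2x2 haplotype table.

    Using uppercase = allele 1: returns (hap_i, hap_j) with ``n_AB`` gametes
    carrying 1 at both loci, ``n_Ab`` carrying 1 only at the first, etc.
    """
    hap_i = np.array([0] * n_ab + [0] * n_aB + [1] * n_Ab + [1] * n_AB, dtype=np.int8)
    hap_j = np.array([0] * n_ab + [1] * n_aB + [0] * n_Ab + [1] * n_AB, dtype=np.int8)
    return hap_i, hap_j
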