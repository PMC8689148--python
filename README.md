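# bufld

Linkage-disequilibrium analysis for SNP-array genotype panels of small
livestock populations: per-population quality control, pairwise LD with a
finite-sample correction, distance-binned LD decay, persistence of LD phase
between populations, and LD-based effective-population-size trajectories.

The package targets the situation common in conservation genomics of local
breeds — a medium-density array (tens of thousands of SNPs) typed on small
samples (8–40 animals per population) from several related populations —
where raw r² is badly inflated by sample size and every downstream quantity
(decay curves, phase persistence, Ne) must be computed from corrected
values. Because panels like these are rarely deposited, the package ships a
forward-time Wright–Fisher simulator with recombination so the entire
pipeline is testable against known ground truth.

## The statistics

For a pair of biallelic loci with alleles A/a and B/b, gametic frequencies
give

- D = f(AB) − f(A)·f(B)
- D′ = |D| / D_max, with D_max = min(f(A)f(b), f(a)f(B)) for D > 0 and
  min(f(A)f(B), f(a)f(b)) for D < 0 (Lewontin's normalisation)
- r = D / √(f(A)f(a)f(B)f(b)), and r² = r²

With `n` sampled individuals, r² is biased upwards by roughly 1/(βn), where
β = 2 when the gametic phase is known and β = 1 when it is not; the
package works throughout with the corrected value

    r²_adj = r² − 1/(β·n)

**LD decay.** Intra-chromosomal pairs are grouped at 100 kb intervals from
0 to 15 Mb and the unweighted mean raw and corrected r² is reported per bin.

**Persistence of LD phase (PLDP).** For two populations sharing a marker
panel (allele-aligned first), the signed r of every shared pair is computed
in each; PLDP per distance bin is the product-moment correlation between
the two signed-r vectors. Values near 1 mean marker–QTL phase transfers
between the populations.

**Effective population size.** Sved's relation E[r²] = 1/(1 + 4·Ne·c)
inverts to Ne = (1/4c)(1/r²_adj − 1) at recombination distance c Morgans
(1 cM ≈ 1 Mb by default); the bin at distance c reflects the population
roughly T = 1/(2c) generations ago, so the decay curve maps to an Ne
trajectory through time.

## Worked example

```python
from bufld import (SimConfig, simulate_wf, run_qc, ld_decay, ne_trajectory)

cfg = SimConfig(n_diploids=100, n_chromosomes=1, chrom_length_morgans=1.0,
                n_loci_per_chromosome=250, burn_in_generations=400,
                sample_sizes=(40,), seed=1001)
ds, truth = simulate_wf(cfg)          # 40 diploids, phased, census 100
(ds,), report = run_qc([ds])          # drift-fixed loci removed
bins = ld_decay(ds, max_bp=15e6, bin_bp=1e5, phased=True)
points = [p for p in ne_trajectory(bins) if 10 <= p.T <= 100]
for p in points[:3]:
    print(f"T={p.T:5.1f} gen  c={p.c:.4f} M  r2_adj={p.mean_r2_adj:.4f}  Ne={p.Ne:.0f}")
```

prints

```
T= 10.5 gen  c=0.0475 M  r2_adj=0.0448  Ne=112
T= 11.5 gen  c=0.0435 M  r2_adj=0.0197  Ne=287
T= 12.7 gen  c=0.0395 M  r2_adj=0.0557  Ne=107
```

i.e. the LD-based estimator recovers the simulated census of 100 from a
40-animal sample, with visible bin-to-bin sampling noise (the second bin
happens to draw a low mean r², inflating its Ne): each line converts the
mean corrected r² of one distance bin into the effective size
T ≈ 1/(2c) generations ago. Across bins with T ∈ [10, 100] and five seeds
the median estimate lands well within a factor of two of the truth (see
`tests/test_acceptance.py`).

The full study-style workflow lives in `analysis/01…05` (simulate →
QC/adjacent LD → decay → PLDP → Ne trajectories); each script prints what it
found and writes its table under `results/`. A `bufld` CLI exposes the same
stages (`bufld simulate`, `qc`, `ld-adjacent`, `ld-decay`, `pldp`, `ne`,
`run`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the installed package, the worked-example target
quantities (e.g. the number of ancestral generations represented by marker
pairs 0.001 Morgan apart under T = 1/(2c)) and writes them as JSON.
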