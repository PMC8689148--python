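# Methods

This note documents the models, estimators and numerical choices behind
`bufld`, and states what the synthetic-data tests do and do not establish.

## Data model

The pipeline's universal container is a diploid genotype matrix over a
sorted biallelic SNP map, one dataset per labelled population. Dosages
count copies of the **alternate** allele (the second `.bim` allele / VCF
ALT) in {0, 1, 2}, with −1 as the missing sentinel. Phased haplotypes, when
present, are stored as two 0/1 gamete rows per sample and must sum to the
dosage wherever the dosage is non-missing. Coordinates are 1-based physical
bp; all distances are point-to-point |Δpos|. Chromosome labels are strings;
"30" is the conventional array label for the bovine/bubaline X and is
treated as such only in sorting, never in the genetics (male hemizygosity
is not modelled — an `--autosomes-only` style subset can be imposed by the
caller by dropping the chromosome before analysis).

Text PLINK (`.ped/.map`) carries no allele-order metadata, so on read the
two observed allele letters are assigned alphabetically (ref < alt);
dosage round-trips are exact whenever both alleles are observed in the
file, which QC-grade data satisfies. Binary PLINK and VCF round-trip
exactly in all cases.

## Quality control

Filters run in a fixed order within each population: (1) individuals with
more than 5% missing calls, (2) SNPs with more than 5% missing calls,
(3) SNPs failing the exact Hardy–Weinberg test at p ≤ 5.7×10⁻⁷ (a
Bonferroni-scale default), (4) monomorphic SNPs and SNPs with MAF < 5%.
The populations are then intersected on their common marker set. All
thresholds are parameters; the defaults above are standard array practice.

The HWE test is the exact conditional test: given the observed allele
totals, the heterozygote count follows the Levene–Haldane distribution,
computed by the stable ratio recurrence from the mid-range heterozygote
count outward and normalised; the p-value sums all configurations whose
conditional probability does not exceed the observed one (probability-mass
ordering, with a 10⁻⁹ relative tie tolerance so exactly-tied symmetric
configurations are included deterministically). A mid-p variant exists and
is off by default. HWE is evaluated per population before merging
(`hwe_scope="per_population"`), consistent with the per-population MAF
filtering; a merged-scope switch is provided.

Remaining missing calls after filtering are filled by per-population modal
dosage (ties resolved to the reference homozygote). This is a deliberately
crude stand-in for haplotype-based imputation — defensible only because
the call-rate filters have already capped missingness at 5% — and it is
bypassed entirely when the simulator supplies complete phased data.

## LD estimation

Two paths, selected by `phased`:

* **Phased** (β = 2): gametes are counted directly. The signed r is the
  product-moment correlation of the two 0/1 gamete vectors, which is
  algebraically identical to D/√(f_A f_a f_B f_b). D′ uses Lewontin's
  normalisation: D_max = min(f_A f_b, f_a f_B) for D > 0 and
  min(f_A f_B, f_a f_b) for D < 0; D = 0 reports D′ = 0.
* **Unphased** (β = 1): the signed r is the correlation of the two dosage
  vectors (composite LD) over complete sample pairs. For D′, D is
  estimated as the Burrows composite cov(g_i, g_j)/2 and normalised by the
  same allele-frequency D_max, capped at 1; this is an approximation that
  is exact under random mating and is reported as such.

The correction `r²_adj = r² − 1/(βn)` subtracts the expectation of r² under
linkage equilibrium at sample size n (n individuals; β converts to gamete
count when phase is known). Adjusted values can be negative; they are
propagated as-is and only excluded where an operation cannot use them
(Ne inversion). Pairs where either locus is monomorphic are skipped and
counted, never imputed as r² = 0. Means over pairs are unweighted.

Matrix routines (decay, PLDP, adjacent summaries) require complete dosages
— run QC first — and compute per-chromosome column correlations in one
pass, so permuting samples cannot change any statistic.

**Adjacent-SNP summaries** report, per chromosome and genome-wide, the mean
spacing, mean ± sd of r²_adj and |D′| for consecutive markers, and the
fraction of adjacent pairs with r²_adj above configurable thresholds
(defaults 0.2 and 0.3, the customary genomic-selection and GWAS levels).
Chromosomes with fewer than two markers are skipped.

**Decay curves** bin intra-chromosomal pairs into (k·100 kb, (k+1)·100 kb]
intervals out to 15 Mb (both configurable); empty bins carry no means.

## Persistence of LD phase

PLDP between populations A and B in a distance bin is the correlation of
the signed r vectors over the bin's shared pairs,
Σ(r_ij(A) − r̄_A)(r_ij(B) − r̄_B)/(S_A S_B). The "signed root of r²"
interpretation is used (r carrying the sign of D): unsigned roots could
never decay towards 0 at long range, which is the observable of interest.
Bins with fewer than three usable pairs report no correlation. Pairs
monomorphic in either population are dropped and counted.

Signed r is only comparable across populations when both count the same
allele everywhere, so `align_alleles` first complements B's dosages (and
flips its haplotypes) wherever B's ref/alt are swapped relative to A;
irreconcilable allele pairs are an error, and A/T, C/G markers are flagged
as strand-ambiguous (letter comparison cannot detect a strand flip there).
The default pair scheme is all intra-chromosomal pairs within 1 Mb binned
at 100 kb; an adjacent-only scheme is available.

## Effective population size

Sved's drift–recombination equilibrium E[r²] = 1/(1 + 4 Ne c) is inverted
bin-by-bin: c is the genetic distance of the bin **midpoint** under a
constant map rate (default 1 cM/Mb, i.e. c = bp × 10⁻⁸), T = 1/(2c), and
Ne = (1/4c)(1/r²_adj − 1). Midpoint-c keeps the trajectory deterministic
given the binning; a mean-pair-distance mode is deliberately not the
default. Bins with r²_adj ≤ 0 are skipped (with a count) rather than
clamped — after the finite-sample correction, weak long-range LD routinely
dips below zero and carries no Ne information. No mutation-rate
modification of the relation is applied. Note Ne is decreasing in c at
fixed r²: small c ↔ distant generations, where estimated sizes are larger
in a declining population.

The diversity-loss utility uses the standard heterozygosity compounding
100·(1 − (1 − 1/(2Ne))^g). At Ne = 25/50/125 over 10 generations this
reproduces the familiar 18/10/4-percent guideline figures; the guideline
values sometimes quoted for Ne = 250 and 500 (1.6, 0.8) do not follow from
this formula (it gives 1.98 and 1.00), so only the consistent cases are
used as reference points in tests.

## Synthetic data

The simulator is forward-time Wright–Fisher with recombination, chosen
over coalescent machinery because arbitrary census schedules (including
recent declines) are trivial to impose and the per-generation truth is
explicit. Specifics:

* non-overlapping generations; each offspring draws two parents uniformly
  with replacement (selfing possible);
* each transmitted gamete receives Poisson(chromosome length in Morgans)
  crossovers at uniform genetic positions;
* founders are drawn site-independently with allele frequencies uniform in
  `init_maf_range` (default 0.1–0.5), i.e. the founder generation is in
  exact linkage equilibrium — all later LD accrues from drift and
  recombination;
* **no new mutation**: loci drift to fixation and are removed by QC, as on
  a real array; this keeps the Sved-relation tests free of a
  mutation-rate nuisance parameter;
* physical positions are laid on an even grid at exactly 1 cM/Mb, so the
  default map function is exact on simulated data;
* the split mode duplicates the ancestral population after burn-in and
  evolves the branches independently; split time 0 returns the same
  sampled individuals twice so phase agreement is exactly 1 by
  construction.

Defaults (census 100, two 1-Morgan chromosomes × 250 loci, 400 burn-in
generations, 40 sampled diploids) describe a small livestock population
typed at ~400 kb effective spacing; they are sized so drift–recombination
equilibrium is reached at the distances the tests interrogate while a full
run stays under a second.

What a green synthetic test establishes: the estimators are internally
consistent and recover known truth under the model's own assumptions
(neutrality, random mating, constant map rate, no mutation, no structure).
What it does not establish: behaviour under real-data pathologies —
genotyping error, map error, variable recombination rate, selection,
admixture, overlapping generations — none of which the generator emulates.

## Numerical and edge-case policy

* LD is undefined (error / NaN, pair skipped and counted) when either
  locus is monomorphic; it is never coerced to 0.
* Correlations are clipped to [−1, 1] against floating-point overshoot.
* Bin assignment uses integer arithmetic ((d − 1) // width), so exact
  multiples of the bin width fall in the lower bin, matching the
  half-open-below (lower, upper] convention.
* The recurrence-based HWE distribution matches a closed-form log-gamma
  enumeration to < 10⁻¹² for all totals ≤ 200 (tested exhaustively).
* The PLINK .bed codec validates the magic bytes and the exact file size
  implied by the `.fam`/`.bim` counts; mismatches within the same 4-sample
  padding byte are intrinsically undetectable in the format.

## Known limitations

* Unphased D′ rests on the composite-D approximation; no EM haplotype
  inference is attempted.
* Mode imputation distorts allele frequencies slightly at high
  missingness; it exists to complete matrices after QC, not to phase.
* The X chromosome is treated like an autosome (no hemizygosity).
* Ne trajectories inherit every assumption of Sved's equilibrium relation;
  near-in-time bins (large c) are also the noisiest because long-range
  r²_adj is small relative to its sampling error.
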