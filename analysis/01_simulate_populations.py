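#!/usr/bin/env python
"""Simulate the genotype panels the downstream analyses consume.

Three scenarios, all Wright–Fisher with recombination at 1 cM/Mb:

* ``constant`` — one population at constant census N = 100 (the truth the
  LD-based Ne trajectory should recover);
* ``decline``  — census falls from 500 to 50 late in the run, emulating the
  recent contraction the buffalo panels show;
* ``split_10`` / ``split_60`` — population pairs diverging 10 and 60
  generations ago from a shared ancestor, for the phase-persistence
  contrast.

Genotype filesets (binary PLINK) land in scratch/sim/ (regenerable, not part
of the deliverable); the truth tables land in results/.
"""

from pathlib import Path

import pandas as pd

from bufld import SimConfig, simulate_split, simulate_wf, write_fixture

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

BASE = dict(
    n_diploids=100,
    n_chromosomes=2,
    chrom_length_morgans=1.0,
    n_loci_per_chromosome=250,
    burn_in_generations=400,
    sample_sizes=(40,),
)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    truth_rows = []

    cfg = SimConfig(**BASE, seed=11)
    ds, truth = simulate_wf(cfg)
    write_fixture(ds, "plink_binary", SCRATCH / "constant")
    truth_rows.append(("constant", cfg.n_diploids, cfg.burn_in_generations, None))
    print(f"constant: {ds.n_samples} samples x {ds.n_variants} SNPs, census 100")

    cfg = SimConfig(**{**BASE, "n_diploids": 500}, ne_schedule=[(360, 50)], seed=12)
    ds, truth = simulate_wf(cfg)
    write_fixture(ds, "plink_binary", SCRATCH / "decline")
    truth_rows.append(("decline", "500->50@360", cfg.burn_in_generations, None))
    print(f"decline: census 500 until generation 360, then 50")

    for split in (10, 60):
        cfg = SimConfig(
            **{**BASE, "sample_sizes": (40, 40)}, split_generations=split, seed=13
        )
        ds_a, ds_b, _ = simulate_split(cfg)
        write_fixture(ds_a, "plink_binary", SCRATCH / f"split{split}_A")
        write_fixture(ds_b, "plink_binary", SCRATCH / f"split{split}_B")
        truth_rows.append((f"split_{split}", cfg.n_diploids, cfg.burn_in_generations, split))
        print(f"split_{split}: two 40-sample panels diverged {split} generations ago")

    pd.DataFrame(
        truth_rows, columns=["scenario", "census", "burn_in", "split_generations"]
    ).to_csv(RESULTS / "sim_truth.tsv", sep="\t", index=False)
    print(f"fixtures in {SCRATCH}, truth table in {RESULTS / 'sim_truth.tsv'}")


if __name__ == "__main__":
    main()
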