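#!/usr/bin/env python
"""Persistence of LD phase between the diverged population pairs.

Compares the signed r of shared SNP pairs between the two branches of each
split scenario, per 500 kb distance bin out to 3 Mb.  Expectation: phase
agreement near 1 at short range, decaying with distance, and lower
throughout for the older (60-generation) split than the recent
(10-generation) one — the pattern that decides whether marker effects
estimated in one population transfer to another.
"""

from pathlib import Path

import pandas as pd

from bufld import align_alleles, pldp, read_plink, run_qc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for split in (10, 60):
        ds_a = read_plink(SCRATCH / f"split{split}_A")
        ds_b = read_plink(SCRATCH / f"split{split}_B")
        (ds_a, ds_b), _ = run_qc([ds_a, ds_b])
        ds_a, ds_b = align_alleles(ds_a, ds_b)
        res = pldp(ds_a, ds_b, bin_bp=5e5, max_bp=3e6, phased=False)
        for b in res.bins:
            rows.append(
                {
                    "split_generations": split,
                    "lower_kb": b.lower_bp // 1000,
                    "upper_kb": b.upper_bp // 1000,
                    "n_pairs": b.n_pairs,
                    "pldp": round(b.correlation, 4) if b.correlation is not None else "NA",
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "pldp.tsv", sep="\t", index=False)
    wide = df.pivot(index=["lower_kb", "upper_kb"], columns="split_generations", values="pldp")
    print(wide.to_string())
    num = wide.apply(pd.to_numeric, errors="coerce").dropna()
    lower = (num[60] < num[10]).mean() if len(num) else float("nan")
    print(
        f"\nIn {lower:.0%} of jointly defined bins the 60-generation split shows "
        f"weaker phase agreement than the 10-generation split; short-range PLDP "
        f"is {num[10].iloc[0]:.2f} (recent) vs {num[60].iloc[0]:.2f} (older split)."
    )


if __name__ == "__main__":
    main()
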