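"""End-to-end orchestration: ingest → QC → LD → PLDP → Ne, with TSV outputs.

Every stage writes one tab-separated table (single header line, ``#``
comment lines carrying the parameters used) so a run is fully auditable;
identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datatypes import GenotypeDataset, concat_samples
from .io import read_plink, read_vcf
from .ld import adjacent_ld_summary, ld_decay
from .ne import MapFunction, ne_trajectory
from .phase import align_alleles, pldp
from .qc import QCThresholds, run_qc

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of a full run (mirrors the YAML config file)."""

    inputs: dict[str, str]  # population label -> PLINK prefix or .vcf path
    out_dir: str = "results"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    phased: bool = False
    bin_bp: int = 100_000
    max_bp: int = 15_000_000
    pldp_max_bp: int = 1_000_000
    adjacent_thresholds: tuple[float, ...] = (0.2, 0.3)
    pldp_pairs: list[tuple[str, str]] | None = None  # default: all pairs
    pooling: dict[str, str] | None = None  # population label -> pool label
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.inputs)) != len(self.inputs) or not self.inputs:
            raise ValueError("population labels must be unique and non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = QCThresholds(**d["thresholds"])
        if "pldp_pairs" in d and d["pldp_pairs"] is not None:
            d["pldp_pairs"] = [tuple(p) for p in d["pldp_pairs"]]
        return cls(**d)


def load_dataset(path: str, population: str) -> GenotypeDataset:
    p = Path(path)
    if p.suffix in (".vcf", ".gz") or str(p).endswith(".vcf.gz"):
        ds = read_vcf(p, population=population)
    else:
        ds = read_plink(p)
    return ds.relabel(population)


def pool_populations(
    datasets: list[GenotypeDataset], pooling: dict[str, str]
) -> list[GenotypeDataset]:
    """Concatenate samples of populations mapped to the same pool label.

    The pooled sample count is what the (βn)⁻¹ correction then uses.
    Datasets must already share a marker set with aligned alleles.
    """
    groups: dict[str, list[GenotypeDataset]] = {}
    for ds in datasets:
        label = pooling.get(ds.population, ds.population)
        groups.setdefault(label, []).append(ds)
    return [
        parts[0].relabel(label) if len(parts) == 1 else concat_samples(parts, label)
        for label, parts in groups.items()
    ]


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the whole workflow; returns a manifest of written files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, path in config.inputs.items():
        p = Path(path)
        if not (p.exists() or p.with_suffix(".bed").exists() or p.with_suffix(".ped").exists()):
            raise FileNotFoundError(f"input for population {label} not found: {path}")

    manifest: dict[str, Path] = {}
    stage = "ingest"
    try:
        datasets = [load_dataset(path, label) for label, path in config.inputs.items()]

        stage = "qc"
        datasets, report = run_qc(datasets, config.thresholds)
        rep = pd.DataFrame([report.as_dict()])
        manifest["qc_report"] = _write_tsv(
            rep, out / "qc_report.tsv", _params(config, "qc")
        )

        stage = "align"
        if len(datasets) > 1:
            ref = datasets[0]
            aligned = [ref]
            for ds in datasets[1:]:
                ref, ds_al = align_alleles(ref, ds)
                aligned[0] = ref
                aligned.append(ds_al)
            datasets = aligned

        stage = "pool"
        if config.pooling:
            analysis_sets = pool_populations(datasets, config.pooling)
        else:
            analysis_sets = datasets

        stage = "adjacent-ld"
        rows = []
        for ds in analysis_sets:
            for s in adjacent_ld_summary(ds, config.phased, config.adjacent_thresholds):
                row = {
                    "population": ds.population,
                    "chromosome": s.chromosome,
                    "n_snps": s.n_snps,
                    "n_pairs": s.n_pairs,
                    "mean_spacing_kb": s.mean_spacing_kb,
                    "mean_r2_adj": s.mean_r2_adj,
                    "sd_r2_adj": s.sd_r2_adj,
                    "mean_d_prime": s.mean_d_prime,
                    "sd_d_prime": s.sd_d_prime,
                }
                for t, fr in s.fraction_r2_adj_above.items():
                    row[f"frac_r2_adj_gt_{t}"] = fr
                rows.append(row)
        manifest["adjacent_ld"] = _write_tsv(
            pd.DataFrame(rows), out / "adjacent_ld.tsv", _params(config, "adjacent")
        )

        stage = "ld-decay"
        decay_by_pop = {}
        rows = []
        for ds in analysis_sets:
            bins = ld_decay(ds, max_bp=config.max_bp, bin_bp=config.bin_bp, phased=config.phased)
            decay_by_pop[ds.population] = bins
            rows += [
                {
                    "population": ds.population,
                    "lower_bp": b.lower_bp,
                    "upper_bp": b.upper_bp,
                    "n_pairs": b.n_pairs,
                    "mean_r2": b.mean_r2,
                    "mean_r2_adj": b.mean_r2_adj,
                }
                for b in bins
            ]
        manifest["ld_decay"] = _write_tsv(
            pd.DataFrame(rows), out / "ld_decay.tsv", _params(config, "decay")
        )

        stage = "pldp"
        labels = [ds.population for ds in analysis_sets]
        by_label = {ds.population: ds for ds in analysis_sets}
        pairs = config.pldp_pairs or [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        rows = []
        for a, b in pairs:
            res = pldp(
                by_label[a],
                by_label[b],
                bin_bp=config.bin_bp,
                max_bp=config.pldp_max_bp,
                phased=config.phased,
            )
            rows += [
                {
                    "pair": f"{a}-{b}",
                    "lower_bp": pb.lower_bp,
                    "upper_bp": pb.upper_bp,
                    "n_pairs": pb.n_pairs,
                    "correlation": pb.correlation if pb.correlation is not None else "NA",
                }
                for pb in res.bins
            ]
        if rows:
            manifest["pldp"] = _write_tsv(
                pd.DataFrame(rows), out / "pldp.tsv", _params(config, "pldp")
            )

        stage = "ne"
        rows = []
        mapf = MapFunction(cm_per_mb=config.cm_per_mb)
        for pop, bins in decay_by_pop.items():
            try:
                points = ne_trajectory(bins, mapf)
            except ValueError as exc:
                log.warning("Ne trajectory for %s unavailable: %s", pop, exc)
                continue
            rows += [
                {
                    "population": pop,
                    "c_morgans": p.c,
                    "T_generations": p.T,
                    "n_pairs": p.n_pairs,
                    "mean_r2_adj": p.mean_r2_adj,
                    "Ne": p.Ne,
                }
                for p in points
            ]
        manifest["ne_trajectory"] = _write_tsv(
            pd.DataFrame(rows), out / "ne_trajectory.tsv", _params(config, "ne")
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    log_path = out / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"bufld {__version__} (python {sys.version.split()[0]})\n")
        fh.write(f"seed={config.seed}\n")
        for k, v in _params(config, "all").items():
            fh.write(f"{k}={v}\n")
        for name, path in manifest.items():
            fh.write(f"output:{name}={path}\n")
    manifest["run_log"] = log_path
    return manifest


def _params(config: PipelineConfig, stage: str) -> dict:
    thr = config.thresholds
    base = {
        "stage": stage,
        "version": __version__,
        "phased": config.phased,
        "bin_bp": config.bin_bp,
        "max_bp": config.max_bp,
        "pldp_max_bp": config.pldp_max_bp,
        "cm_per_mb": config.cm_per_mb,
        "mind": thr.max_missing_individual,
        "geno": thr.max_missing_snp,
        "maf": thr.min_maf,
        "hwe": thr.hwe_p_cutoff,
        "seed": config.seed,
    }
    return base
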