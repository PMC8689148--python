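"""Genotype file I/O: binary PLINK, text PLINK, VCF, and marker intersection.

Conventions
-----------
* Coordinates are 1-based physical bp, as in .bim/.map/VCF.
* Dosage counts the *alternate* allele: the second .bim allele (A2) or the
  VCF ALT.  The bed 2-bit codes are ``00`` hom-A1, ``01`` missing, ``10``
  het, ``11`` hom-A2 (SNP-major, low bits first within a byte).
* Text PLINK carries no allele-order metadata, so alleles are assigned
  alphabetically on read (ref < alt); sites where only one allele is
  observed get that allele as ref and a ``N`` placeholder alt.
"""

from __future__ import annotations

import gzip
import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    VARIANT_COLUMNS,
    FormatError,
    GenotypeDataset,
    GenotypeError,
)

log = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1 .bed
# 2-bit code -> alternate-allele dosage
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


# ---------------------------------------------------------------------------
# reading


def read_plink(path_prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK fileset (binary ``.bed/.bim/.fam`` or text ``.ped/.map``).

    Returns a dataset with variants sorted by (chromosome, position) and
    ``phased=False``; dosages count the second .bim allele.
    """
    prefix = Path(path_prefix)
    if prefix.with_suffix(".bed").exists():
        ds = _read_plink_binary(prefix)
    elif prefix.with_suffix(".ped").exists():
        ds = _read_plink_text(prefix)
    else:
        raise FileNotFoundError(
            f"no PLINK fileset at prefix '{prefix}' (looked for .bed and .ped)"
        )
    return ds.sort_variants()


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file is missing: {path}")
    return path


def _read_fam(path: Path) -> list[tuple[str, str]]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    # FID is the population label, IID the sample id (write_fixture convention)
    return list(zip(fam[1], fam[0]))


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise FormatError(f"{path}: expected 6 columns, found {bim.shape[1]}")
    out = pd.DataFrame(
        {
            "id": bim[1],
            "chrom": bim[0],
            "pos": bim[3].astype(int),
            "ref": bim[4],  # A1
            "alt": bim[5],  # A2 = counted allele
        }
    )
    return out[VARIANT_COLUMNS]


def _read_plink_binary(prefix: Path) -> GenotypeDataset:
    bed_path = _require(prefix.with_suffix(".bed"))
    samples = _read_fam(_require(prefix.with_suffix(".fam")))
    variants = _read_bim(_require(prefix.with_suffix(".bim")))
    n, m = len(samples), len(variants)

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not SNP-major PLINK 1 .bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: size {len(raw)} does not match {n} samples x {m} variants "
            f"(expected {expected}); .fam/.bim and .bed disagree"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample 0 in the lowest bits
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 3
    codes = codes.reshape(m, -1)[:, :n]
    calls = _BED_DECODE[codes].T  # (n, m)
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


def _read_plink_text(prefix: Path) -> GenotypeDataset:
    ped_path = _require(prefix.with_suffix(".ped"))
    map_path = _require(prefix.with_suffix(".map"))
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    chroms, ids, pos = mp[0], mp[1], mp[3].astype(int)
    m = len(mp)

    samples: list[tuple[str, str]] = []
    allele_rows: list[list[str]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields, found {len(fields)}"
            )
        samples.append((fields[1], fields[0]))
        allele_rows.append(fields[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(samples), m, 2)

    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise FormatError(
                f"{ped_path}: marker {ids[j]} has {len(observed)} alleles"
            )
        ref = observed[0] if observed else "A"
        alt = observed[1] if len(observed) == 2 else "N"
        refs.append(ref)
        alts.append(alt)
        valid = (col != "0").all(axis=1)
        calls[valid, j] = (col[valid] == alt).sum(axis=1)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": pos, "ref": refs, "alt": alts}
    )[VARIANT_COLUMNS]
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


def read_vcf(path: str | Path, population: str | None = None) -> GenotypeDataset:
    """Read biallelic SNP records from a plain or gzipped VCF.

    Multi-allelic and non-SNP records are dropped (the count is logged).
    ``phased`` is True iff every retained genotype uses the ``|`` separator.
    Population labels come from a ``##population_labels=`` header written by
    :func:`write_vcf` when present, else from ``population`` (default "pop1").
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required file is missing: {path}")
    try:
        vcf = cyvcf2.VCF(str(path))
        sample_ids = list(vcf.samples)
        header = vcf.raw_header
        records = []
        dropped = 0
        for var in vcf:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                dropped += 1
                continue
            records.append(
                (
                    var.ID or f"{var.CHROM}_{var.POS}",
                    str(var.CHROM),
                    int(var.POS),
                    var.REF,
                    var.ALT[0],
                    np.array(var.genotypes, dtype=np.int64),  # (n, 3): a0 a1 phased
                )
            )
        vcf.close()
    except FileNotFoundError:
        raise
    except Exception as exc:  # cyvcf2/htslib parse failures
        raise FormatError(f"{path}:{_first_bad_vcf_line(path)}: malformed VCF ({exc})")
    if dropped:
        log.info("read_vcf: dropped %d multi-allelic/non-SNP records", dropped)

    labels = _parse_population_header(header)
    pop = population or "pop1"
    samples = [(sid, labels.get(sid, pop)) for sid in sample_ids]

    n, m = len(sample_ids), len(records)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    hap = np.zeros((2 * n, m), dtype=np.int8)
    all_phased = m > 0
    rows = []
    for j, (vid, chrom, pos, ref, alt, gt) in enumerate(records):
        rows.append((vid, chrom, pos, ref, alt))
        a0, a1, ph = gt[:, 0], gt[:, 1], gt[:, 2]
        ok = (a0 >= 0) & (a1 >= 0)
        calls[ok, j] = (a0[ok] + a1[ok]).astype(np.int8)
        hap[0::2, j] = np.clip(a0, 0, 1)
        hap[1::2, j] = np.clip(a1, 0, 1)
        if not ph[ok].all() or (n > 0 and not ok.any()):
            all_phased = False
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    ds = GenotypeDataset(
        samples=samples,
        variants=variants,
        calls=calls,
        haplotypes=hap if all_phased else None,
        phased=all_phased,
    )
    return ds.sort_variants()


def _parse_population_header(header: str) -> dict[str, str]:
    for line in header.splitlines():
        if line.startswith("##population_labels="):
            body = line.split("=", 1)[1]
            return dict(item.split(":", 1) for item in body.split(",") if ":" in item)
    return {}


def _first_bad_vcf_line(path: Path) -> int:
    """Best-effort line number of the first structurally bad data line."""
    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            for ln, line in enumerate(fh, start=1):
                if line.startswith("#"):
                    continue
                if len(line.rstrip("\n").split("\t")) < 8:
                    return ln
    except OSError:
        pass
    return 0


# ---------------------------------------------------------------------------
# writing


def write_plink_binary(ds: GenotypeDataset, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = ds.n_samples, ds.n_variants
    fam = prefix.with_suffix(".fam")
    fam.write_text(
        "".join(f"{pop}\t{sid}\t0\t0\t0\t-9\n" for sid, pop in ds.samples)
    )
    bim = prefix.with_suffix(".bim")
    v = ds.variants
    bim.write_text(
        "".join(
            f"{c}\t{i}\t0\t{p}\t{r}\t{a}\n"
            for i, c, p, r, a in zip(v["id"], v["chrom"], v["pos"], v["ref"], v["alt"])
        )
    )
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, n), dtype=np.uint8)
    calls = ds.calls.T
    codes[calls == MISSING] = 0b01
    codes[calls == 0] = 0b00
    codes[calls == 1] = 0b10
    codes[calls == 2] = 0b11
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(m, bytes_per_snp, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint8
    )
    bed = prefix.with_suffix(".bed")
    bed.write_bytes(_BED_MAGIC + packed.tobytes())
    return [bed, prefix.with_suffix(".bim"), fam]


def write_plink_text(ds: GenotypeDataset, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = ds.variants
    map_path = prefix.with_suffix(".map")
    map_path.write_text(
        "".join(
            f"{c}\t{i}\t0\t{p}\n" for i, c, p in zip(v["id"], v["chrom"], v["pos"])
        )
    )
    refs = v["ref"].to_numpy()
    alts = v["alt"].to_numpy()
    lines = []
    for k, (sid, pop) in enumerate(ds.samples):
        fields = [pop, sid, "0", "0", "0", "-9"]
        row = ds.calls[k]
        for j, d in enumerate(row):
            if d == MISSING:
                fields += ["0", "0"]
            else:
                fields += [refs[j]] * (2 - d) + [alts[j]] * d
        lines.append(" ".join(fields))
    ped_path = prefix.with_suffix(".ped")
    ped_path.write_text("\n".join(lines) + "\n")
    return [ped_path, map_path]


def write_vcf(ds: GenotypeDataset, path: str | Path) -> list[Path]:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "|" if ds.phased else "/"
    pop_header = ",".join(f"{sid}:{pop}" for sid, pop in ds.samples)
    header = [
        "##fileformat=VCFv4.2",
        f"##population_labels={pop_header}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = []
    for c in ds.variants["chrom"]:
        if c not in chroms:
            chroms.append(c)
    header += [f"##contig=<ID={c}>" for c in chroms]
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(ds.sample_ids)
    )
    lines = header
    v = ds.variants
    for j in range(ds.n_variants):
        gts = []
        for k in range(ds.n_samples):
            d = ds.calls[k, j]
            if d == MISSING:
                gts.append(f".{sep}.")
            elif ds.phased:
                a0 = ds.haplotypes[2 * k, j]
                a1 = ds.haplotypes[2 * k + 1, j]
                gts.append(f"{a0}|{a1}")
            else:
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
        lines.append(
            f"{v['chrom'][j]}\t{v['pos'][j]}\t{v['id'][j]}\t{v['ref'][j]}\t"
            f"{v['alt'][j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return [path]


# ---------------------------------------------------------------------------
# marker intersection


def intersect_on_common_markers(
    datasets: Sequence[GenotypeDataset],
) -> list[GenotypeDataset]:
    """Restrict every dataset to the shared marker set, in identical order.

    Marker identity is the ``(id, chromosome, position)`` triple.  Allele
    coding across datasets is *not* reconciled here — run
    :func:`bufld.phase.align_alleles` before any cross-population statistic.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common = set(datasets[0].variant_keys())
    for ds in datasets[1:]:
        common &= set(ds.variant_keys())
    if not common:
        raise GenotypeError(
            "the datasets share no markers; check that they come from the same "
            "array/assembly and use matching variant ids"
        )
    out = []
    for ds in datasets:
        keys = ds.variant_keys()
        idx = [i for i, k in enumerate(keys) if k in common]
        out.append(ds.take_variants(idx))
    order = out[0].variant_keys()
    for i, ds in enumerate(out[1:], start=1):
        if ds.variant_keys() != order:
            lookup = {k: j for j, k in enumerate(ds.variant_keys())}
            out[i] = ds.take_variants([lookup[k] for k in order])
    return out
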