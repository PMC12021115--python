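"""Reading and writing the pipeline's file formats.

VCFs are written as plain-text VCFv4.2 (bi-allelic SNPs, GT plus the six
INFO keys used by hard filtering) and read back through cyvcf2.  Metadata,
depth tables and BED interval sets are TSVs handled by pandas.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import INFO_KEYS, MISSING, GenotypeMatrix, SampleMeta

_VCF_HEADER = """##fileformat=VCFv4.2
##source=ponypop
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias phred-scaled p">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio strand bias">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(gm: GenotypeMatrix, path, phased: bool = False) -> None:
    """Write the genotype matrix as an uncompressed VCFv4.2 file."""
    path = Path(path)
    use_haps = phased and gm.haplotypes is not None
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        contigs = pd.unique(gm.variants["chrom"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        var = gm.variants
        qual = var["qual"] if "qual" in var.columns else pd.Series(np.nan, index=var.index)
        sep = "|" if use_haps else "/"
        for j in range(gm.n_sites):
            info_parts = []
            for key in INFO_KEYS:
                if key in var.columns:
                    v = var[key].iloc[j]
                    if v is not None and not (isinstance(v, float) and math.isnan(v)):
                        info_parts.append(f"{key}={v:.4g}" if isinstance(v, float) else f"{key}={v}")
            info = ";".join(info_parts) if info_parts else "."
            q = qual.iloc[j]
            qs = "." if (q is None or (isinstance(q, float) and math.isnan(q))) else f"{q:.4g}"
            fields = [
                str(var["chrom"].iloc[j]),
                str(int(var["pos"].iloc[j])),
                ".",
                str(var.get("ref", pd.Series("A", index=var.index)).iloc[j]),
                str(var.get("alt", pd.Series("G", index=var.index)).iloc[j]),
                qs,
                ".",
                info,
                "GT",
            ]
            gts = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                if d == MISSING:
                    gts.append(f".{sep}.")
                elif use_haps:
                    a, b = gm.haplotypes[2 * i, j], gm.haplotypes[2 * i + 1, j]
                    gts.append(f"{a}|{b}")
                else:
                    gts.append({0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[int(d)])
            fh.write("\t".join(fields) + "\t" + "\t".join(gts) + "\n")


def read_vcf(path, keep_haplotypes: bool = True) -> GenotypeMatrix:
    """Read a bi-allelic SNP VCF into a GenotypeMatrix via cyvcf2.

    Phased haplotypes are kept when every genotype in the file is phased and
    ``keep_haplotypes`` is set; otherwise only dosages are stored.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    haps = []
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # bi-allelic SNPs only
        rec = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
            "qual": v.QUAL if v.QUAL is not None else np.nan,
        }
        for key in INFO_KEYS:
            val = v.INFO.get(key)
            rec[key] = float(val) if val is not None else np.nan
        rows.append(rec)
        site_dos = np.empty(len(samples), dtype=np.int8)
        site_hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                site_dos[i] = MISSING
                site_hap[2 * i] = site_hap[2 * i + 1] = MISSING
            else:
                site_dos[i] = a + b
                site_hap[2 * i], site_hap[2 * i + 1] = a, b
            if not g[2]:
                all_phased = False
        dosages.append(site_dos)
        haps.append(site_hap)
    vcf.close()
    variants = pd.DataFrame(rows)
    dos = np.array(dosages, dtype=np.int8).T if dosages else np.empty((len(samples), 0), np.int8)
    hp = None
    if keep_haplotypes and all_phased and haps:
        hp = np.array(haps, dtype=np.int8).T
    return GenotypeMatrix(dos, samples, variants, hp)


def write_meta(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_meta(path) -> SampleMeta:
    t = pd.read_csv(path, sep="\t", dtype={"sample": str, "breed": str})
    t["yakutia_adjacent"] = t["yakutia_adjacent"].astype(bool)
    return SampleMeta(t)


def write_depth(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_depth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 0-based half-open intervals (chrom, start, end[, extra...]) as BED."""
    intervals.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    return df.astype({"start": np.int64, "end": np.int64})


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("config must declare a seed")
    return cfg
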