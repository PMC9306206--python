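"""Readers and writers for the pipeline's on-disk formats.

VCFv4.2 (biallelic SNVs, ``AA`` and ``DP`` INFO keys), BED3+1 gene intervals,
PLINK ``.map`` genetic positions, sample->population TSV, VEP-style annotation
TSV and plain-text variant catalogs.  Reading VCF goes through cyvcf2 (htslib);
writing is plain text since only a narrow, fully specified subset is emitted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import GeneIntervals, GenotypeMatrix, PopulationMap

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    path = Path(path)
    v = geno.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean site depth, rounded">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in v["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        gts = geno.genotypes
        for i in range(geno.n_variants):
            row = v.iloc[i]
            info = []
            if isinstance(row["aa"], str) and row["aa"] != ".":
                info.append(f"AA={row['aa']}")
            if np.isfinite(row["depth"]):
                info.append(f"DP={int(round(row['depth']))}")
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ";".join(info) if info else ".",
                "GT",
            ]
            fields.extend(_GT_CODE[int(g)] for g in gts[i])
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF; multi-allelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, aas, depths = [], [], [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        aa = rec.INFO.get("AA")
        aas.append(aa if aa else ".")
        dp = rec.INFO.get("DP")
        depths.append(float(dp) if dp is not None else np.nan)
        g = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        g[g == 3] = -1
        rows.append(g)
    vcf.close()
    genotypes = np.vstack(rows) if rows else np.zeros((0, len(samples)), np.int8)
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "aa": aas,
            "cm": np.nan,
            "depth": depths,
        }
    )
    return GenotypeMatrix(variants, samples, genotypes)


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    if df["sample"].duplicated().any():
        raise ValueError("sample assigned more than once in population map")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def write_plink_map(geno: GenotypeMatrix, path) -> None:
    v = geno.variants
    with open(path, "w") as fh:
        for i in range(len(v)):
            row = v.iloc[i]
            cm = row["cm"]
            fh.write(
                f"{row['chrom']}\t{row['chrom']}:{int(row['pos'])}\t"
                f"{0.0 if not np.isfinite(cm) else cm:.8g}\t{int(row['pos'])}\n"
            )


def read_plink_map(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str},
    )
    return df


def attach_genetic_map(geno: GenotypeMatrix, gmap: pd.DataFrame) -> GenotypeMatrix:
    """Assign genetic positions by linear interpolation between map points,
    with constant extrapolation beyond the ends of each chromosome's map."""
    v = geno.variants.copy()
    cm = np.full(len(v), np.nan)
    for chrom, sub in v.groupby("chrom", sort=False):
        g = gmap[gmap["chrom"] == str(chrom)].sort_values("pos")
        if g.empty:
            continue
        cm[sub.index] = np.interp(
            sub["pos"].to_numpy(), g["pos"].to_numpy(), g["cm"].to_numpy()
        )
    v["cm"] = cm
    return GenotypeMatrix(v, list(geno.samples), geno.genotypes.copy())


def write_bed(genes: GeneIntervals, path) -> None:
    genes.records[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> GeneIntervals:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str},
    )
    return GeneIntervals(df[["gene_id", "chrom", "start", "end"]])


#: columns of the annotation TSV schema consumed by :mod:`trigene.varclass`
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "impact", "consequence", "sift_score", "polyphen_score",
]


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_catalog(path) -> set[str]:
    """Known-variant catalog: one ``chrom:pos:ref:alt`` key per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_catalog(keys: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for k in sorted(keys):
            fh.write(k + "\n")
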