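"""Standard-format readers and writers.

VCF 4.2 genotype I/O (cyvcf2 for reading, plain-text writing), sample
sheets, expression/serology TSV matrices, and the truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix
from .qc import SampleQc

__all__ = [
    "read_genotypes",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

_GT_CODE = {0: 0, 1: 1, 2: MISSING, 3: 2}  # cyvcf2 gt_types -> dose


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNV VCF into a genotype matrix.

    Codes are alternate-allele counts; ``./.`` maps to missing.  A
    multi-allelic record raises with its position.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, positions, rows = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split upstream"
            )
        variants.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        positions.append(rec.POS)
        rows.append([_GT_CODE[t] for t in rec.gt_types])
    vcf.close()
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        positions=np.array(positions, dtype=np.int64),
        genotypes=geno,
    )


def read_sample_sheet(path) -> list[SampleQc]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "status", "stratum", "call_rate", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleQc(
            sample_id=row.sample_id,
            call_rate=float(row.call_rate),
            mean_depth=float(row.mean_depth),
            status=row.status,
            stratum=row.stratum,
            sex=getattr(row, "sex", "U"),
        )
        for row in df.itertuples()
    ]


def read_genotypes(vcf_path, sheet_path) -> tuple[GenotypeMatrix, list[SampleQc]]:
    """Read VCF + sample sheet; sample order follows the sheet.

    Raises when the sheet and VCF disagree on the sample set, listing the
    offending ids.
    """
    G = read_vcf(vcf_path)
    sheet = read_sample_sheet(sheet_path)
    sheet_ids = [s.sample_id for s in sheet]
    vcf_set, sheet_set = set(G.samples), set(sheet_ids)
    if vcf_set != sheet_set:
        only_vcf = sorted(vcf_set - sheet_set)
        only_sheet = sorted(sheet_set - vcf_set)
        raise ValueError(
            f"sample sheet / VCF mismatch: only in VCF {only_vcf}, "
            f"only in sheet {only_sheet}"
        )
    return G.subset_samples(sheet_ids), sheet


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path, chrom: str = "5") -> None:
    """Write a minimal VCF 4.2 with GT fields only."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(G.samples),
    ]
    for j, vid in enumerate(G.variants):
        gts = "\t".join(_GT_STR[int(g)] for g in G.genotypes[:, j])
        lines.append(
            f"{chrom}\t{int(G.positions[j])}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(M: pd.DataFrame, path) -> None:
    M.to_csv(path, sep="\t")


def read_truth(path) -> dict:
    with open(path) as fh:
        truth = json.load(fh)
    truth["diplotypes"] = {k: tuple(v) for k, v in truth["diplotypes"].items()}
    return truth
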