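"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as TSV (subjects x variants, entries 0/1/2/NA) or
as a bi-allelic VCF with GT fields; subject, phenotype and annotation
tables are plain TSV with mandatory, schema-checked columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import PHENOTYPE_VARIABLES
from .synthetic import ANNOTATION_CLASSES

__all__ = [
    "read_genotypes",
    "read_subjects",
    "read_phenotypes",
    "read_annotation",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_table",
]

_MISSING = "NA"


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", na_rep=_MISSING, index=True)
    return path


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> Path:
    """Subjects x variants TSV; missing calls written as NA."""
    path = Path(path)
    out = genotypes.copy()
    # Integer formatting (0/1/2) with NA sentinels, not 0.0/1.0/2.0.
    out = out.astype("Int64")
    out.to_csv(path, sep="\t", na_rep=_MISSING, index=True)
    return path


def write_genotypes_vcf(genotypes: pd.DataFrame, path) -> Path:
    """Minimal bi-allelic VCF v4.2 with GT-only FORMAT.

    Variants are placed on chromosome 1 at consecutive positions with
    placeholder A>G alleles; the variant id is carried in the ID column so
    a re-read recovers the same matrix columns.
    """
    path = Path(path)
    subjects = [str(s) for s in genotypes.index]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects) + "\n")
        values = genotypes.to_numpy(dtype=float)
        for j, vid in enumerate(genotypes.columns):
            calls = []
            for value in values[:, j]:
                calls.append("./." if np.isnan(value) else gt_map[int(value)])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tG\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")
    return path


def _read_genotypes_tsv(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[_MISSING], dtype=str)
    try:
        values = frame.apply(pd.to_numeric).to_numpy(dtype=float)
    except Exception as exc:
        raise ValueError(f"{path}: non-numeric genotype entry ({exc})") from exc
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: genotype entry {values[i, j]!r} at row {i + 2} not in {{0,1,2,NA}}"
        )
    frame.index.name = "subject_id"
    out = pd.DataFrame(values, index=frame.index, columns=frame.columns)
    out.columns.name = "variant_id"
    return out


def _read_genotypes_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    columns: list[str] = []
    rows: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {record.CHROM}:{record.POS}; "
                "split multi-allelic sites before loading"
            )
        vid = record.ID if record.ID not in (None, ".") else (
            f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}"
        )
        counts = np.full(len(subjects), np.nan)
        for i, call in enumerate(record.genotypes):
            alleles = call[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: non-diploid GT for sample {subjects[i]} at "
                    f"{record.CHROM}:{record.POS}"
                )
            if -1 in alleles:
                continue
            counts[i] = sum(1 for a in alleles if a != 0)
        columns.append(vid)
        rows.append(counts)
    vcf.close()
    matrix = np.column_stack(rows) if rows else np.empty((len(subjects), 0))
    out = pd.DataFrame(matrix, index=pd.Index(subjects, name="subject_id"), columns=columns)
    out.columns.name = "variant_id"
    return out


def read_genotypes(path, format: str | None = None) -> pd.DataFrame:
    """Load a genotype matrix from TSV or VCF (alt-allele counts, NaN missing)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_subjects(path) -> pd.DataFrame:
    """Subject table: subject_id, status (0/1), age, sex (0/1), bmi."""
    frame = pd.read_csv(path, sep="\t", na_values=[_MISSING])
    required = ["subject_id", "status", "age", "sex", "bmi"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    frame = frame.set_index("subject_id")
    if not frame["status"].isin([0, 1]).all():
        bad = sorted(frame.loc[~frame["status"].isin([0, 1]), "status"].unique())
        raise ValueError(f"{path}: status values outside {{0,1}}: {bad}")
    if not frame["sex"].isin([0, 1]).all():
        raise ValueError(f"{path}: sex values outside {{0,1}}")
    return frame


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: subject_id plus any of the echo outcome variables.

    Only recognized outcome columns are kept; variables absent from the
    file are simply not evaluated downstream.
    """
    frame = pd.read_csv(path, sep="\t", na_values=[_MISSING])
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path}: missing mandatory column subject_id")
    frame = frame.set_index("subject_id")
    known = [c for c in frame.columns if c in PHENOTYPE_VARIABLES]
    if not known:
        raise ValueError(f"{path}: no recognized phenotype variables "
                         f"(expected some of {list(PHENOTYPE_VARIABLES)})")
    return frame[known].astype(float)


def read_annotation(path) -> pd.DataFrame:
    """Variant annotation: gene region, three class columns, reference_freq."""
    frame = pd.read_csv(path, sep="\t", na_values=[_MISSING])
    required = ["variant_id", "gene_region", "class_source1", "class_source2",
                "class_source3", "reference_freq"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    freq = frame["reference_freq"].to_numpy(dtype=float)
    if np.isnan(freq).any() or (freq < 0).any() or (freq > 1).any():
        raise ValueError(f"{path}: reference_freq values outside [0,1]")
    classes = frame[["class_source1", "class_source2", "class_source3"]].to_numpy(dtype=object)
    bad = sorted({str(v) for v in classes.ravel() if v not in ANNOTATION_CLASSES})
    if bad:
        raise ValueError(f"{path}: unknown functional class value(s) {bad}")
    return frame
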