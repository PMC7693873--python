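"""Burden-style aggregation of selected variants into gene-region features.

Summing alternate-allele counts of positive-effect variants within a gene
region concentrates weak signals from low-frequency variants into a single
count per gene.  Because every retained variant raises disease odds, the
sum is a directionally coherent burden.  The resulting nonnegative
feature-by-patient count matrix is the input to NMF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "aggregate_by_gene", "build_feature_matrix"]


@dataclass
class FeatureMatrix:
    """Nonnegative feature-by-patient count matrix (features = variants or genes)."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    dropped_rows: list[str] = field(default_factory=list)
    dropped_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if (self.values < 0).any():
            raise ValueError("feature matrix entries must be nonnegative")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("row/col ids do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def aggregate_by_gene(
    genotypes: pd.DataFrame,
    gene_map: Mapping[str, str],
) -> FeatureMatrix:
    """Sum variant allele counts within each gene region, per patient.

    ``genotypes`` is patients x variants (complete, nonnegative integer
    counts); the output is genes x patients.  Total allele mass is conserved:
    the grand sum equals the grand sum of the input.
    """
    missing = [v for v in map(str, genotypes.columns) if v not in gene_map]
    if missing:
        raise ValueError(f"variant(s) missing from gene map: {missing[:10]}")
    G = genotypes.to_numpy(dtype=float)
    if np.isnan(G).any():
        raise ValueError("genotypes contain missing values; impute first")
    genes: dict[str, np.ndarray] = {}
    for j, vid in enumerate(map(str, genotypes.columns)):
        gene = gene_map[vid]
        if gene in genes:
            genes[gene] = genes[gene] + G[:, j]
        else:
            genes[gene] = G[:, j].copy()
    gene_ids = sorted(genes)
    values = np.vstack([genes[g] for g in gene_ids]) if gene_ids else np.empty((0, G.shape[0]))
    return FeatureMatrix(values, gene_ids, [str(s) for s in genotypes.index])


def build_feature_matrix(
    genotypes: pd.DataFrame,
    selected_variants: Sequence[str],
    patients: Sequence[str],
    aggregate: bool = False,
    gene_map: Mapping[str, str] | None = None,
) -> FeatureMatrix:
    """Assemble the NMF input over the hypertensive patients.

    Rows are the selected variants (or their gene burdens when
    ``aggregate``); columns are patients.  All-zero rows and columns are
    dropped — the KL-divergence factorization is degenerate on them — and
    the drops are recorded on the result and logged.
    """
    selected = [str(v) for v in selected_variants]
    if not selected:
        raise ValueError("no variants selected; feature matrix would be empty")
    patients = [str(p) for p in patients]
    sub = genotypes.loc[patients, selected]
    if aggregate:
        if gene_map is None:
            raise ValueError("gene_map required when aggregate=True")
        fm = aggregate_by_gene(sub, gene_map)
    else:
        values = sub.to_numpy(dtype=float).T
        if np.isnan(values).any():
            raise ValueError("genotypes contain missing values; impute first")
        fm = FeatureMatrix(values, selected, patients)

    row_mass = fm.values.sum(axis=1)
    col_mass = fm.values.sum(axis=0)
    keep_rows = row_mass > 0
    keep_cols = col_mass > 0
    dropped_rows = [r for r, k in zip(fm.row_ids, keep_rows) if not k]
    dropped_cols = [c for c, k in zip(fm.col_ids, keep_cols) if not k]
    if not keep_rows.any():
        raise ValueError("no informative features: all rows are zero after filtering")
    if dropped_rows:
        logger.info("dropping %d all-zero feature row(s): %s", len(dropped_rows), dropped_rows[:10])
    if dropped_cols:
        logger.info("dropping %d all-zero patient column(s): %s", len(dropped_cols), dropped_cols[:10])
    return FeatureMatrix(
        fm.values[np.ix_(keep_rows, keep_cols)],
        [r for r, k in zip(fm.row_ids, keep_rows) if k],
        [c for c, k in zip(fm.col_ids, keep_cols) if k],
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )
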