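"""Depth normalization and per-gene group statistics.

Counts are put on a counts-per-million (CPM) scale — the minimal depth
correction that makes per-gene averages comparable across samples — and each
gene is then summarized per genotype: the mutant and wild-type means whose
ratio drives the fold-change criteria, and the standard deviation of the
individually sequenced wild-type samples that anchors the SD-based criteria.
Gene-length correction is deliberately absent: every criterion compares the
same gene across conditions, so length cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .simdata import MUT, WT, CountMatrix

__all__ = [
    "ExpressionMatrix",
    "GroupSummary",
    "normalize_cpm",
    "group_summary",
    "read_group_summary",
]

CPM_SCALE = 1e6

PooledPolicy = Literal["exclude_pooled_from_sd", "error_if_pooled_wt"]


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of CPM values with the same metadata contract as
    :class:`~pooldeg.simdata.CountMatrix` (every column sums to 10**6)."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("ExpressionMatrix gene_ids must be unique")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("ExpressionMatrix sample ids must match "
                             "sample_meta rows, in order")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("ExpressionMatrix contains negative entries")
        totals = self.values.sum(axis=0).to_numpy()
        if not np.allclose(totals, CPM_SCALE, rtol=1e-9):
            raise ValueError("ExpressionMatrix columns must each sum to 10^6")

    def samples_of(self, genotype: str, pooled: bool | None = None) -> list[str]:
        m = self.sample_meta["genotype"] == genotype
        if pooled is not None:
            m &= self.sample_meta["pooled"].astype(bool) == pooled
        return list(self.sample_meta.index[m])


@dataclass
class GroupSummary:
    """Per-gene group statistics.

    ``table`` is indexed by gene id with columns ``mean_wt``, ``mean_mut``
    and ``sd_wt`` (sample standard deviation, n-1 denominator, over the
    individually sequenced wild-type samples). ``n_wt`` / ``n_mut`` record
    how many columns each statistic used.
    """

    table: pd.DataFrame
    n_wt: int
    n_mut: int

    def validate(self) -> None:
        need = ["mean_wt", "mean_mut", "sd_wt"]
        if [c for c in need if c not in self.table.columns]:
            raise ValueError(f"GroupSummary table must have columns {need}")
        if (self.table[need].to_numpy() < 0).any():
            raise ValueError("GroupSummary statistics must be nonnegative")

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["n_wt"] = self.n_wt
        out["n_mut"] = self.n_mut
        out.to_csv(path, sep="\t", index_label="gene_id")


def read_group_summary(path) -> GroupSummary:
    t = pd.read_csv(path, sep="\t", index_col="gene_id")
    n_wt = int(t["n_wt"].iloc[0]) if "n_wt" in t.columns else 0
    n_mut = int(t["n_mut"].iloc[0]) if "n_mut" in t.columns else 0
    gs = GroupSummary(t[["mean_wt", "mean_mut", "sd_wt"]], n_wt, n_mut)
    gs.validate()
    return gs


def normalize_cpm(matrix: CountMatrix) -> ExpressionMatrix:
    """Scale each sample column to counts per million.

    Each value becomes ``10^6 * count / column_total``; gene and sample
    ordering are preserved. A sample with zero total counts is rejected by
    name (its relative composition is undefined).
    """
    totals = matrix.counts.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        raise ValueError(f"normalize_cpm: sample(s) {zero} have zero total "
                         "counts")
    values = matrix.counts / totals * CPM_SCALE
    return ExpressionMatrix(values, matrix.sample_meta.copy())


def group_summary(
    matrix: ExpressionMatrix,
    pooled_policy: PooledPolicy = "exclude_pooled_from_sd",
) -> GroupSummary:
    """Compute per-gene genotype means and the wild-type standard deviation.

    ``mean_wt`` and ``sd_wt`` use the individually sequenced wild-type
    columns only — a pooled sample is a mixture, not a biological replicate,
    so it never contributes to the spread estimate. ``mean_mut`` averages all
    mutant columns, so a design whose single mutant sample is a pooled
    library yields ``mean_mut`` equal to that column verbatim.

    ``pooled_policy`` governs a wild-type group consisting solely of pooled
    samples: ``error_if_pooled_wt`` rejects it, ``exclude_pooled_from_sd``
    summarizes it by its mean with ``sd_wt = 0`` (no replicate spread
    available).
    """
    meta = matrix.sample_meta
    for genotype in (WT, MUT):
        if not (meta["genotype"] == genotype).any():
            raise ValueError(f"group_summary: no samples with genotype "
                             f"{genotype!r}")

    wt_indiv = matrix.samples_of(WT, pooled=False)
    mut_cols = matrix.samples_of(MUT)

    if wt_indiv:
        wt_cols = wt_indiv
        sd_wt = matrix.values[wt_cols].std(axis=1, ddof=1).fillna(0.0)
    else:
        if pooled_policy == "error_if_pooled_wt":
            raise ValueError("group_summary: wild-type group contains only "
                             "pooled samples (error_if_pooled_wt)")
        wt_cols = matrix.samples_of(WT)
        sd_wt = pd.Series(0.0, index=matrix.values.index)

    table = pd.DataFrame({
        "mean_wt": matrix.values[wt_cols].mean(axis=1),
        "mean_mut": matrix.values[mut_cols].mean(axis=1),
        "sd_wt": sd_wt,
    })
    gs = GroupSummary(table, n_wt=len(wt_cols), n_mut=len(mut_cols))
    gs.validate()
    return gs
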