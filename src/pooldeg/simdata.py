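"""Synthetic two-genotype RNA-seq count experiments with known truth labels.

This module generates negative-binomial count matrices that emulate a bulk
RNA-seq comparison between a wild-type strain and a mutant strain, with a
configurable number of biological replicates per genotype, and provides an
in-silico equal-mass pooling operator that mixes replicate RNA into a single
pooled library. Because each simulated sample stands for a plate of hundreds
to thousands of animals, per-sample expression is smooth (bulk noise), not
single-animal noise.

Ground truth (which genes are truly up- or down-regulated, and by how much)
is recorded alongside the counts so that downstream DEG-calling criteria can
be scored for recall and precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "CountMatrix",
    "GeneParams",
    "draw_gene_params",
    "simulate_experiment",
    "pool_replicates",
    "read_count_matrix",
    "write_count_matrix",
    "read_truth_table",
]

WT = "wt"
MUT = "mut"

PoolingMode = Literal["expectation", "multinomial"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of a replicate + pooling experiment.

    Parameters
    ----------
    n_genes
        Number of genes in the transcriptome.
    replicates_wt, replicates_mut
        Individually sequenced biological replicates per genotype.
    baseline_log_mean, baseline_log_sd
        Natural-log location/scale of the log-normal distribution of
        per-gene baseline relative expression. Only the shape matters:
        profiles are renormalised to each sample's library size.
    dispersion
        Negative-binomial overdispersion phi, with variance ``m + phi*m**2``
        around mean ``m``. ``0`` gives the Poisson limit.
    frac_up, frac_down
        Fractions of genes planted as truly up-/down-regulated in the mutant.
    fc_low, fc_high
        Bounds (> 1) of the log-uniform law for true fold changes. Down
        genes use the reciprocal ``1/f`` of a draw from the same law.
    library_size
        Total counts per individually sequenced sample.
    pooled_library_size
        Total counts for a pooled library.
    pooling_mode
        ``"expectation"`` (noise-free mixing arithmetic) or ``"multinomial"``
        (one sequencing draw from the pooled profile).
    seed
        Single integer governing all randomness; sub-streams are derived
        deterministically per operation.
    """

    n_genes: int = 12_000
    replicates_wt: int = 6
    replicates_mut: int = 6
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    frac_up: float = 0.10
    frac_down: float = 0.0
    fc_low: float = 2.0
    fc_high: float = 8.0
    library_size: int = 2_000_000
    pooled_library_size: int = 2_000_000
    pooling_mode: PoolingMode = "multinomial"
    seed: int = 1

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        for name in ("n_genes", "replicates_wt", "replicates_mut",
                     "library_size", "pooled_library_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(
                    f"invalid SimulationConfig: {name} must be a strictly "
                    f"positive integer, got {v!r}")
        if self.baseline_log_sd < 0:
            raise ValueError("invalid SimulationConfig: baseline_log_sd must "
                             f"be >= 0, got {self.baseline_log_sd!r}")
        if self.dispersion < 0:
            raise ValueError("invalid SimulationConfig: dispersion must be "
                             f">= 0, got {self.dispersion!r}")
        for name in ("frac_up", "frac_down"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"invalid SimulationConfig: {name} must lie "
                                 f"in [0, 1], got {v!r}")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("invalid SimulationConfig: frac_up + frac_down "
                             f"must be <= 1, got {self.frac_up + self.frac_down!r}")
        if not self.fc_low > 1.0:
            raise ValueError(f"invalid SimulationConfig: fc_low must be > 1, "
                             f"got {self.fc_low!r}")
        if self.fc_low > self.fc_high:
            raise ValueError("invalid SimulationConfig: fc_low must be <= "
                             f"fc_high, got {self.fc_low!r} > {self.fc_high!r}")
        if self.pooling_mode not in ("expectation", "multinomial"):
            raise ValueError("invalid SimulationConfig: pooling_mode must be "
                             f"'expectation' or 'multinomial', got "
                             f"{self.pooling_mode!r}")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Per-gene ground truth: status in {up, down, null} and true fold change.

    ``table`` is indexed by gene id with columns ``status`` and
    ``true_fold_change`` (1.0 for null genes, > 1 for up, < 1 for down).
    """

    table: pd.DataFrame

    def validate(self) -> None:
        t = self.table
        if list(t.columns) != ["status", "true_fold_change"]:
            raise ValueError("TruthTable columns must be "
                             "['status', 'true_fold_change']")
        bad = ~t["status"].isin(["up", "down", "null"])
        if bad.any():
            raise ValueError(f"TruthTable has invalid status values: "
                             f"{sorted(t['status'][bad].unique())}")
        fc = t["true_fold_change"]
        if ((t["status"] == "up") & ~(fc > 1)).any():
            raise ValueError("TruthTable: up genes must have fold change > 1")
        if ((t["status"] == "down") & ~(fc < 1)).any():
            raise ValueError("TruthTable: down genes must have fold change < 1")
        if ((t["status"] == "null") & (fc != 1)).any():
            raise ValueError("TruthTable: null genes must have fold change = 1")

    def genes_with_status(self, status: str) -> set[str]:
        return set(self.table.index[self.table["status"] == status])

    @property
    def up_genes(self) -> set[str]:
        return self.genes_with_status("up")

    @property
    def down_genes(self) -> set[str]:
        return self.genes_with_status("down")

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_table(path) -> TruthTable:
    # keep_default_na: the literal status string "null" must survive parsing
    t = pd.read_csv(path, sep="\t", index_col="gene_id",
                    keep_default_na=False)
    t["true_fold_change"] = t["true_fold_change"].astype(float)
    tt = TruthTable(t[["status", "true_fold_change"]])
    tt.validate()
    return tt


@dataclass
class CountMatrix:
    """Gene x sample count matrix with per-sample genotype/pooled metadata.

    ``counts``: DataFrame indexed by unique gene ids, one column per sample.
    ``sample_meta``: DataFrame indexed by sample id with columns ``genotype``
    (``wt``/``mut``) and ``pooled`` (bool).

    Simulated and serialized matrices hold nonnegative integers; analysis
    matrices may carry nonnegative reals (an expectation-mode pooled column
    is an expected-count profile, not a draw).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self, strict_int: bool = False) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("CountMatrix gene_ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("CountMatrix sample_ids must be unique")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("CountMatrix sample ids must match sample_meta "
                             "rows, in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("CountMatrix contains negative entries")
        bad = ~self.sample_meta["genotype"].isin([WT, MUT])
        if bad.any():
            raise ValueError("CountMatrix genotype must be 'wt' or 'mut'")
        if strict_int:
            arr = self.counts.to_numpy()
            if not np.array_equal(arr, np.floor(arr)):
                raise ValueError("CountMatrix counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, genotype: str, pooled: bool | None = None) -> list[str]:
        m = self.sample_meta["genotype"] == genotype
        if pooled is not None:
            m &= self.sample_meta["pooled"].astype(bool) == pooled
        return list(self.sample_meta.index[m])

    def with_sample(self, sample_id: str, values: Sequence[float] | pd.Series,
                    genotype: str, pooled: bool = True) -> "CountMatrix":
        """Return a new matrix with one extra sample column appended."""
        if sample_id in self.counts.columns:
            raise ValueError(f"duplicate sample id {sample_id!r}")
        col = pd.Series(np.asarray(values), index=self.counts.index,
                        name=sample_id)
        counts = pd.concat([self.counts, col], axis=1)
        meta = pd.concat([
            self.sample_meta,
            pd.DataFrame({"genotype": [genotype], "pooled": [pooled]},
                         index=[sample_id]),
        ])
        return CountMatrix(counts, meta)


def write_count_matrix(matrix: CountMatrix, counts_path, meta_path) -> None:
    """Write the tab-separated dialect: counts table + sample metadata table."""
    counts = matrix.counts
    arr = counts.to_numpy()
    if np.array_equal(arr, np.floor(arr)):
        counts = counts.astype(np.int64)
    counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    meta = matrix.sample_meta.copy()
    meta["pooled"] = meta["pooled"].astype(int)
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_count_matrix(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    meta["pooled"] = meta["pooled"].astype(bool)
    cm = CountMatrix(counts, meta.loc[counts.columns])
    cm.validate()
    return cm


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneParams:
    """Gene-level biology shared by every sample drawn from one experiment:
    baseline relative expression and the planted truth."""

    base_means: np.ndarray  # baseline relative expression, wild type
    truth: TruthTable

    @property
    def mut_means(self) -> np.ndarray:
        return self.base_means * self.truth.table["true_fold_change"].to_numpy()


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def draw_gene_params(config: SimulationConfig) -> GeneParams:
    """Draw baseline means and planted fold changes for one transcriptome.

    Uses the first child of the config's seed sequence, so the gene-level
    biology can be reused across experiments that share a master seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    n = config.n_genes
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)

    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    if n_up + n_down > n:  # rounding pushed past n
        n_down = n - n_up
    status = np.array(["null"] * n, dtype=object)
    affected = rng.choice(n, size=n_up + n_down, replace=False)
    status[affected[:n_up]] = "up"
    status[affected[n_up:]] = "down"

    fc = np.ones(n)
    log_lo, log_hi = np.log(config.fc_low), np.log(config.fc_high)
    if n_up:
        fc[affected[:n_up]] = np.exp(rng.uniform(log_lo, log_hi, n_up))
    if n_down:
        fc[affected[n_up:]] = 1.0 / np.exp(rng.uniform(log_lo, log_hi, n_down))

    truth = TruthTable(pd.DataFrame(
        {"status": status, "true_fold_change": fc}, index=_gene_ids(n)))
    truth.validate()
    return GeneParams(base_means=base, truth=truth)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial draw with variance mean + dispersion*mean**2."""
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(
    config: SimulationConfig,
    gene_params: GeneParams | None = None,
) -> tuple[CountMatrix, TruthTable]:
    """Simulate one two-genotype experiment with individually sequenced samples.

    Per-gene baseline means are drawn log-normally; mutant means are the
    baseline times the planted true fold change. For each sample the gene
    means are rescaled to sum to ``library_size`` and counts are drawn
    negative-binomially with variance ``m + dispersion*m**2``. Deterministic
    given the config (seed included).

    ``gene_params`` lets a caller reuse one transcriptome (baseline + truth)
    across several simulated experiments; by default it is drawn from the
    config's own seed.
    """
    config.validate()
    if gene_params is None:
        gene_params = draw_gene_params(config)
    if len(gene_params.base_means) != config.n_genes:
        raise ValueError("gene_params size does not match config.n_genes")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    genes = list(gene_params.truth.table.index)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype, n_reps, means in (
        (WT, config.replicates_wt, gene_params.base_means),
        (MUT, config.replicates_mut, gene_params.mut_means),
    ):
        scaled = means / means.sum() * config.library_size
        for i in range(n_reps):
            sid = f"{genotype}_{i + 1}"
            cols[sid] = _nb_draw(rng, scaled, config.dispersion)
            meta_rows.append((sid, genotype, False))

    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        {"genotype": [g for _, g, _ in meta_rows],
         "pooled": [p for _, _, p in meta_rows]},
        index=[s for s, _, _ in meta_rows])
    cm = CountMatrix(counts, meta)
    cm.validate(strict_int=True)
    return cm, gene_params.truth


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_replicates(
    matrix: CountMatrix,
    sample_subset: Iterable[str],
    pooled_library_size: int,
    mode: PoolingMode = "expectation",
    seed: int | None = None,
) -> pd.Series:
    """Mix equal RNA masses from a subset of samples into one pooled column.

    Each replicate column is first converted to relative abundance (divided
    by its column sum) so every replicate contributes equal mass regardless
    of its sequencing depth; the pooled profile is the unweighted mean of
    those proportion vectors. In ``expectation`` mode the returned column is
    that profile scaled to ``pooled_library_size`` (real-valued, noise free);
    in ``multinomial`` mode it is a single multinomial draw of
    ``pooled_library_size`` trials from the profile, deterministic given
    ``seed``.
    """
    subset = list(sample_subset)
    if not subset:
        raise ValueError("pool_replicates: sample_subset is empty")
    missing = [s for s in subset if s not in matrix.counts.columns]
    if missing:
        raise ValueError(f"pool_replicates: unknown sample ids {missing}")
    if pooled_library_size <= 0:
        raise ValueError("pool_replicates: pooled_library_size must be "
                         "strictly positive")

    sub = matrix.counts[subset].to_numpy(dtype=float)
    totals = sub.sum(axis=0)
    zero = [subset[j] for j in np.nonzero(totals == 0)[0]]
    if zero:
        raise ValueError(f"pool_replicates: sample(s) {zero} have zero total "
                         "counts; relative abundance undefined")

    props = sub / totals  # column-wise proportions
    profile = props.sum(axis=1) / len(subset)

    if mode == "expectation":
        values = profile * pooled_library_size
    elif mode == "multinomial":
        rng = np.random.default_rng(seed)
        values = rng.multinomial(pooled_library_size, profile / profile.sum())
    else:
        raise ValueError(f"pool_replicates: unknown mode {mode!r}; expected "
                         "'expectation' or 'multinomial'")
    return pd.Series(values, index=matrix.counts.index, name="pooled")
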