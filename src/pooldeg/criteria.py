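"""DEG-calling criteria: ratio thresholds, SD thresholds, their conjunction,
and a significance route (per-gene Welch t + Benjamini-Hochberg).

The fold-change criteria call a gene when the ratio of the mutant mean to the
wild-type mean strictly exceeds a threshold (a "150% increase" threshold
means ratio > 1.5). The SD criteria call a gene when the difference of means,
expressed in units of the wild-type replicate standard deviation, strictly
exceeds a multiplier. Combined criteria require both. The FDR route is a
transparent stand-in for a full differential-expression pipeline: a Welch
two-sample t-test on log2(CPM + 1) per gene, Benjamini-Hochberg adjusted,
called at adjusted p <= alpha with the sign matching the requested direction.

Zero-denominator conventions (stated, not silent):

* ``mean_wt = 0`` with ``mean_mut > 0`` — the ratio is treated as +inf, so
  the gene is called by any ratio threshold; both means zero is never called.
* ``sd_wt = 0`` — the gene is called by an SD criterion iff the mean moved
  in the requested direction at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, GroupSummary, group_summary

__all__ = [
    "CriterionSpec",
    "DEGCallResult",
    "parse_criterion",
    "CRITERION_TOKEN_EXAMPLES",
    "call_by_ratio",
    "call_by_stdev",
    "call_combined",
    "call_by_fdr",
    "call_criterion",
    "bh_adjust",
]

Direction = Literal["up", "down"]

#: canonical tokens accepted by :func:`parse_criterion`
CRITERION_TOKEN_EXAMPLES = (
    "ratio:5.0", "ratio:2.0", "ratio:1.5", "stdev:3", "stdev:2",
    "ratio+stdev:1.5,3", "ratio+stdev:1.5,2", "fdr:0.05",
)


@dataclass(frozen=True)
class CriterionSpec:
    """One DEG-calling rule. Only the fields relevant to ``kind`` are used."""

    kind: Literal["ratio", "stdev", "ratio_and_stdev", "fdr"]
    ratio_threshold: float | None = None
    stdev_multiplier: float | None = None
    alpha: float | None = None
    direction: Direction = "up"

    def __post_init__(self):
        if self.kind not in ("ratio", "stdev", "ratio_and_stdev", "fdr"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got "
                             f"{self.direction!r}")
        if self.kind in ("ratio", "ratio_and_stdev"):
            if self.ratio_threshold is None or self.ratio_threshold <= 0:
                raise ValueError("ratio_threshold must be strictly positive")
        if self.kind in ("stdev", "ratio_and_stdev"):
            if self.stdev_multiplier is None or self.stdev_multiplier <= 0:
                raise ValueError("stdev_multiplier must be strictly positive")
        if self.kind == "fdr":
            if self.alpha is None or not (0 < self.alpha < 1):
                raise ValueError("alpha must lie in (0, 1)")

    @property
    def token(self) -> str:
        if self.kind == "ratio":
            return f"ratio:{self.ratio_threshold:g}"
        if self.kind == "stdev":
            return f"stdev:{self.stdev_multiplier:g}"
        if self.kind == "ratio_and_stdev":
            return (f"ratio+stdev:{self.ratio_threshold:g},"
                    f"{self.stdev_multiplier:g}")
        return f"fdr:{self.alpha:g}"


def parse_criterion(token: str, direction: Direction = "up") -> CriterionSpec:
    """Parse a criterion token such as ``ratio:1.5``, ``stdev:2``,
    ``ratio+stdev:1.5,2`` or ``fdr:0.05``."""
    try:
        kind, _, arg = token.partition(":")
        kind = kind.strip()
        if kind == "ratio":
            return CriterionSpec("ratio", ratio_threshold=float(arg),
                                 direction=direction)
        if kind == "stdev":
            return CriterionSpec("stdev", stdev_multiplier=float(arg),
                                 direction=direction)
        if kind == "ratio+stdev":
            t, k = (float(x) for x in arg.split(","))
            return CriterionSpec("ratio_and_stdev", ratio_threshold=t,
                                 stdev_multiplier=k, direction=direction)
        if kind == "fdr":
            return CriterionSpec("fdr", alpha=float(arg), direction=direction)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ValueError) and "must" in str(exc):
            raise
    raise ValueError(
        f"unknown criterion token {token!r}; expected one of the forms "
        f"{', '.join(CRITERION_TOKEN_EXAMPLES)}")


@dataclass
class DEGCallResult:
    """Outcome of applying one criterion to a gene universe.

    ``scores`` is indexed by gene id with columns ``ratio``
    (mean_mut/mean_wt), ``sd_units`` ((mean_mut - mean_wt)/sd_wt), ``p_adj``
    (NaN except for the FDR route) and boolean ``called``.
    """

    criterion: CriterionSpec
    scores: pd.DataFrame

    @property
    def called_genes(self) -> set[str]:
        return set(self.scores.index[self.scores["called"]])

    @property
    def n_called(self) -> int:
        return int(self.scores["called"].sum())

    def verify(self) -> bool:
        """Re-evaluate the criterion on the recorded scores (self-consistency)."""
        expected = _evaluate(self.criterion, self.scores)
        return bool((expected == self.scores["called"].to_numpy()).all())

    def write(self, list_path=None, table_path=None) -> None:
        if list_path is not None:
            with open(list_path, "w") as fh:
                for g in self.scores.index[self.scores["called"]]:
                    fh.write(f"{g}\n")
        if table_path is not None:
            out = self.scores.copy()
            out["called"] = out["called"].astype(int)
            out.to_csv(table_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# score computation and evaluation
# ---------------------------------------------------------------------------

def _base_scores(summary: GroupSummary) -> pd.DataFrame:
    mw = summary.table["mean_wt"].to_numpy(dtype=float)
    mm = summary.table["mean_mut"].to_numpy(dtype=float)
    sd = summary.table["sd_wt"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mm / mw
        sd_units = (mm - mw) / sd
    # mean_wt = 0: ratio is +inf if the mutant expresses at all, undefined
    # (NaN, never called) if both means are zero — numpy already yields this.
    # sd_wt = 0: sign of the mean difference decides; equal means -> 0.
    tie = (sd == 0) & (mm == mw)
    sd_units[tie] = 0.0

    return pd.DataFrame(
        {"ratio": ratio, "sd_units": sd_units,
         "p_adj": np.full(len(mm), np.nan), "called": False},
        index=summary.table.index)


def _evaluate(spec: CriterionSpec, scores: pd.DataFrame) -> np.ndarray:
    """Boolean call vector for ``spec`` given recorded per-gene scores."""
    ratio = scores["ratio"].to_numpy(dtype=float)
    sd_units = scores["sd_units"].to_numpy(dtype=float)
    up = spec.direction == "up"

    def ratio_pass() -> np.ndarray:
        if up:
            with np.errstate(invalid="ignore"):
                return ratio > spec.ratio_threshold
        # down direction: wild type over mutant, with the mirrored
        # conventions (mut 0 / wt > 0 -> inf; 0/0 stays NaN).
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / ratio
            return inv > spec.ratio_threshold

    def sd_pass() -> np.ndarray:
        z = sd_units if up else -sd_units
        with np.errstate(invalid="ignore"):
            return z > spec.stdev_multiplier

    if spec.kind == "ratio":
        return ratio_pass()
    if spec.kind == "stdev":
        return sd_pass()
    if spec.kind == "ratio_and_stdev":
        return ratio_pass() & sd_pass()
    if spec.kind == "fdr":
        p = scores["p_adj"].to_numpy(dtype=float)
        direction_ok = sd_units > 0 if up else sd_units < 0
        with np.errstate(invalid="ignore"):
            return (p <= spec.alpha) & direction_ok
    raise AssertionError(spec.kind)


def _call(summary: GroupSummary, spec: CriterionSpec) -> DEGCallResult:
    if len(summary.table) == 0:
        raise ValueError("empty GroupSummary")
    scores = _base_scores(summary)
    scores["called"] = _evaluate(spec, scores)
    return DEGCallResult(spec, scores)


def call_by_ratio(summary: GroupSummary, threshold: float,
                  direction: Direction = "up") -> DEGCallResult:
    """Call genes whose mutant/wild-type mean ratio strictly exceeds
    ``threshold`` (direction ``down`` uses wild-type/mutant)."""
    return _call(summary, CriterionSpec("ratio", ratio_threshold=threshold,
                                        direction=direction))


def call_by_stdev(summary: GroupSummary, k: float,
                  direction: Direction = "up") -> DEGCallResult:
    """Call genes whose mean difference strictly exceeds ``k`` wild-type
    standard deviations in the requested direction."""
    return _call(summary, CriterionSpec("stdev", stdev_multiplier=k,
                                        direction=direction))


def call_combined(summary: GroupSummary, threshold: float, k: float,
                  direction: Direction = "up") -> DEGCallResult:
    """Call genes satisfying both the ratio and the SD criterion; the called
    set is exactly the intersection of the two constituent calls."""
    return _call(summary, CriterionSpec(
        "ratio_and_stdev", ratio_threshold=threshold, stdev_multiplier=k,
        direction=direction))


# ---------------------------------------------------------------------------
# significance route
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Rejection at level alpha corresponds to adjusted value <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_by_fdr(matrix: ExpressionMatrix, alpha: float = 0.05,
                direction: Direction = "up") -> DEGCallResult:
    """Significance route: per-gene Welch t on log2(CPM+1), two-sided p,
    Benjamini-Hochberg across genes; called iff adjusted p <= alpha and the
    mean difference matches ``direction``.

    Only individually sequenced samples enter the test (a pooled library has
    no replicate variance); at least two are required per genotype.
    """
    spec = CriterionSpec("fdr", alpha=alpha, direction=direction)
    wt = matrix.samples_of("wt", pooled=False)
    mut = matrix.samples_of("mut", pooled=False)
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError(
            "call_by_fdr: need >= 2 individually sequenced samples per "
            f"genotype, got {len(wt)} wt and {len(mut)} mut")

    log_wt = np.log2(matrix.values[wt].to_numpy() + 1.0)
    log_mut = np.log2(matrix.values[mut].to_numpy() + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(log_mut, log_wt, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties carry no evidence

    # summary restricted to the tested (individual) columns, so the recorded
    # scores and the direction check describe exactly what was tested
    sub = ExpressionMatrix(matrix.values[wt + mut],
                           matrix.sample_meta.loc[wt + mut])
    scores = _base_scores(group_summary(sub))
    scores["p_adj"] = bh_adjust(p)
    scores["called"] = _evaluate(spec, scores)
    return DEGCallResult(spec, scores)


def call_criterion(spec: CriterionSpec, summary: GroupSummary | None = None,
                   matrix: ExpressionMatrix | None = None) -> DEGCallResult:
    """Dispatch a :class:`CriterionSpec`: summary-based kinds need
    ``summary``; the FDR kind needs the full ``matrix``."""
    if spec.kind == "fdr":
        if matrix is None:
            raise ValueError("fdr criterion requires an ExpressionMatrix")
        return call_by_fdr(matrix, spec.alpha, spec.direction)
    if summary is None:
        if matrix is None:
            raise ValueError(f"{spec.kind} criterion requires a GroupSummary")
        summary = group_summary(matrix)
    return _call(summary, spec)
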