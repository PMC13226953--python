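"""Within-participant task-effect statistics with FDR control.

Speech elicitation prompts systematically shift connectedness features
(mean and variance of adjacent-word similarity) even within the same
diagnostic group, so apparent diagnostic effects can be confounded by
task composition.  This module quantifies such task effects with paired
Wilcoxon signed-rank tests, run separately per group and per feature, and
controls the family-wise false discovery rate with the Benjamini-Hochberg
step-up procedure.

The Wilcoxon statistic is W = min(W+, W-), the smaller of the positive-
and negative-difference rank sums.  Zero differences are dropped
(Wilcoxon's exclusion method) and tied absolute differences receive
mid-ranks.  For n <= 25 retained differences the two-sided p-value is
exact, computed over the full 2^n sign-assignment distribution of W+ (by
dynamic programming over the integer-doubled rank sums, so mid-ranks are
handled exactly); for larger n a normal approximation with tie and
continuity corrections is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_LIMIT = 25


class DegenerateSampleError(ValueError):
    """All paired differences are zero; the test is undefined."""


@dataclass
class PairedSample:
    participant_ids: list[str]
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if not (len(self.participant_ids) == len(self.values_a) == len(self.values_b)):
            raise ValueError("paired sample arrays must be aligned")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    pvalue: float
    n_used: int  # nonzero differences
    n_zero: int
    method: str  # "exact" | "normal"


def _signed_rank_parts(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0.0]
    n_zero = len(diffs) - len(nz)
    if len(nz) == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(nz))  # mid-ranks for ties
    return nz, ranks, n_zero


def _exact_w_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled W+ value over all sign patterns.

    Ranks are mid-ranks, so 2*rank is an exact integer; the distribution
    of 2*W+ is built by polynomial convolution over the n ranks.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    max_sum = int(doubled.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    paired: PairedSample | Sequence[float],
    values_b: Sequence[float] | None = None,
    *,
    method: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test.

    Accepts a :class:`PairedSample`, a difference array, or two aligned
    value arrays.  ``method`` is ``auto`` (exact for n <= 25), ``exact``
    or ``normal``.
    """
    if isinstance(paired, PairedSample):
        diffs = paired.differences
    elif values_b is not None:
        diffs = np.asarray(paired, dtype=float) - np.asarray(values_b, dtype=float)
    else:
        diffs = np.asarray(paired, dtype=float)
    nz, ranks, n_zero = _signed_rank_parts(diffs)
    n = len(nz)
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    w = min(w_plus, w_minus)

    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "normal"
    if method == "exact":
        counts = _exact_w_distribution(ranks)
        total = counts.sum()  # == 2^n
        d2 = int(round(2.0 * w_plus))
        p_le = counts[: d2 + 1].sum() / total
        p_ge = counts[d2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif method == "normal":
        mu = n * (n + 1) / 4.0
        # tie correction over groups of tied absolute differences
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            raise DegenerateSampleError("zero variance (all differences tied to zero rank)")
        z = (w - mu + 0.5) / sigma  # continuity correction toward the mean
        p = min(1.0, 2.0 * sps.norm.cdf(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(statistic=w, pvalue=float(p), n_used=n, n_zero=n_zero, method=method)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (adjusted p-values, rejection mask at ``alpha``) in the input
    order.  adjusted p_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha


# ---------------------------------------------------------------------------
# task-effect analysis


@dataclass
class TaskEffectResult:
    table: pd.DataFrame  # group, feature, n_pairs, n_excluded, W, p, p_adj, reject
    summaries: pd.DataFrame  # group, task, feature, quartiles for plotting
    alpha: float


def task_effect_analysis(
    task_table: pd.DataFrame,
    features: Sequence[str] = ("wordAvg", "wordVar"),
    tasks: tuple[str, str] = ("AboutYourself", "HowsItGoing"),
    groups: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TaskEffectResult:
    """Paired task-effect tests per group x feature with BH correction.

    ``task_table`` is the tidy per-task-instance feature table.  For each
    group and feature, participants contributing both tasks form the
    paired sample (others are excluded and counted); the BH family is the
    full group x feature grid.  Groups with fewer than 2 complete pairs
    are skipped with a warning.
    """
    task_a, task_b = tasks
    if groups is None:
        groups = sorted(task_table["group"].unique())
    rows: list[dict] = []
    for group in groups:
        sub = task_table[task_table["group"] == group]
        a = sub[sub["task_id"] == task_a].set_index("participant_id")
        b = sub[sub["task_id"] == task_b].set_index("participant_id")
        common = a.index.intersection(b.index)
        n_excluded = len(set(a.index).symmetric_difference(b.index))
        for feat in features:
            if feat not in task_table.columns:
                raise ValueError(f"feature {feat!r} not in task table")
            va = a.loc[common, feat].to_numpy(dtype=float)
            vb = b.loc[common, feat].to_numpy(dtype=float)
            ok = ~(np.isnan(va) | np.isnan(vb))
            n_pairs = int(ok.sum())
            excluded = n_excluded + int((~ok).sum())
            if n_pairs < 2:
                logger.warning(
                    "group %s, feature %s: only %d complete pairs; skipped",
                    group, feat, n_pairs,
                )
                rows.append(
                    {"group": group, "feature": feat, "n_pairs": n_pairs,
                     "n_excluded": excluded, "W": np.nan, "p": np.nan}
                )
                continue
            try:
                res = wilcoxon_signed_rank(
                    PairedSample(list(common[ok]), va[ok], vb[ok])
                )
                rows.append(
                    {"group": group, "feature": feat, "n_pairs": n_pairs,
                     "n_excluded": excluded, "W": res.statistic, "p": res.pvalue}
                )
            except DegenerateSampleError:
                rows.append(
                    {"group": group, "feature": feat, "n_pairs": n_pairs,
                     "n_excluded": excluded, "W": np.nan, "p": np.nan}
                )
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["p_adj"] = np.nan
    table["reject"] = False
    if tested.any():
        adj, rej = bh_adjust(table.loc[tested, "p"].to_numpy(), alpha)
        table.loc[tested, "p_adj"] = adj
        table.loc[tested, "reject"] = rej

    sum_rows = []
    for group in groups:
        for task in tasks:
            sub = task_table[(task_table["group"] == group) & (task_table["task_id"] == task)]
            for feat in features:
                vals = sub[feat].dropna()
                if vals.empty:
                    continue
                q1, q2, q3 = np.percentile(vals, [25, 50, 75])
                sum_rows.append(
                    {"group": group, "task": task, "feature": feat, "n": len(vals),
                     "mean": float(vals.mean()), "q1": q1, "median": q2, "q3": q3}
                )
    summaries = pd.DataFrame(sum_rows)
    return TaskEffectResult(table=table, summaries=summaries, alpha=alpha)
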