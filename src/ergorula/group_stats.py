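"""Nonparametric comparison of subtask groups.

With eight participants, each contributing one mean grand score per
subtask group and side, inference is rank-based:

* a Friedman omnibus test of the subtask effect (participants are the
  blocks, groups the treatments), then
* pairwise two-sided Wilcoxon signed-rank post hocs on the paired
  participant means, with the exact null distribution (enumeration over
  sign assignments) for n <= 25, zero differences dropped.

Following the original analysis convention, the pairwise p-values are
compared raw against alpha (no multiplicity correction) when counting,
per group, how many other groups differ significantly; Holm correction
is available behind a flag.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class IncompleteBlocksError(ValueError):
    """A participant x group cell is missing; Friedman needs complete blocks."""


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Participants x subtask-groups matrix of mean grand scores (one side)."""

    values: np.ndarray
    participant_ids: tuple[str, ...]
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape != (len(self.participant_ids), len(self.group_labels)):
            raise ValueError(
                f"values shape {v.shape} does not match {len(self.participant_ids)} "
                f"participants x {len(self.group_labels)} groups"
            )
        if np.isnan(v).any():
            rows, cols = np.nonzero(np.isnan(v))
            cells = [
                f"({self.participant_ids[r]}, {self.group_labels[c]})"
                for r, c in zip(rows, cols)
            ]
            raise IncompleteBlocksError(f"missing cell(s): {', '.join(cells)}")
        if v.size and (v.min() < 1 or v.max() > 7):
            raise ValueError("mean grand scores must lie in [1, 7]")

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    @property
    def k(self) -> int:
        return len(self.group_labels)


@dataclasses.dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p_value: float


@dataclasses.dataclass(frozen=True)
class GroupStatsResult:
    """Omnibus + post-hoc summary for one side.

    ``pairwise_p`` is a symmetric k x k frame with NaN on the diagonal;
    ``degenerate`` flags pairs whose paired differences were all zero
    (p recorded as 1).  ``sig_counts[g]`` counts pairwise comparisons
    involving group ``g`` with p < alpha — a significant pair increments
    both its groups.
    """

    chi2: float
    df: int
    p_value: float
    pairwise_p: pd.DataFrame
    degenerate: pd.DataFrame
    alpha: float
    sig_counts: pd.Series


def friedman_test(matrix: ScoreMatrix) -> FriedmanResult:
    """Friedman rank test of the group effect across participant blocks.

    Average ranks for ties with the standard tie correction; df = k - 1;
    p from the chi-square distribution.  Perfectly concordant blocks give
    the closed-form statistic n(k - 1); all-equal blocks give 0.
    """
    if matrix.n < 2:
        raise ValueError("Friedman test needs at least 2 participant blocks")
    if matrix.k < 3:
        raise ValueError(
            "Friedman test needs at least 3 groups; for 2 groups use the "
            "Wilcoxon signed-rank test directly"
        )
    if np.all(matrix.values == matrix.values[:, :1]):
        # scipy rejects the fully tied degenerate case; the statistic is 0
        return FriedmanResult(chi2=0.0, df=matrix.k - 1, p_value=1.0)
    chi2, p = stats.friedmanchisquare(*(matrix.values[:, j] for j in range(matrix.k)))
    return FriedmanResult(chi2=float(chi2), df=matrix.k - 1, p_value=float(p))


def exact_wilcoxon_p(x: np.ndarray, y: np.ndarray, max_exact_n: int = 25) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (classic convention); absolute
    differences are ranked with average ranks.  For n <= ``max_exact_n``
    non-zero pairs the null distribution of the positive rank sum W+ is
    enumerated exactly over the 2^n equiprobable sign assignments
    (convolution over doubled ranks, so tied average ranks stay exact);
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).  Larger n falls back to
    the normal approximation.

    Returns ``(p, degenerate)`` where ``degenerate`` marks the all-zero
    case (p recorded as 1).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, True
    if n > max_exact_n:
        p = stats.wilcoxon(d, zero_method="wilcox", method="approx").pvalue
        return float(p), False
    r = stats.rankdata(np.abs(d))
    w2 = int(round(2.0 * r[d > 0].sum()))
    r2 = np.rint(2.0 * r).astype(np.int64)  # doubled ranks are integers even with ties
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for rr in r2:
        shifted = np.zeros_like(counts)
        shifted[rr:] = counts[: total + 1 - rr]
        counts += shifted
    counts /= 2.0**n
    cdf_le = counts[: w2 + 1].sum()
    cdf_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge))), False


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def wilcoxon_posthoc(
    matrix: ScoreMatrix,
    alpha: float = 0.05,
    require_omnibus: bool = True,
    holm: bool = False,
) -> GroupStatsResult:
    """Pairwise Wilcoxon post hocs with per-group significance counts.

    ``require_omnibus`` (default) first runs the Friedman test and raises
    if it is not significant at ``alpha``; post hocs are only meaningful
    after a significant omnibus.  ``holm`` applies the Holm step-down
    correction to the pairwise p-values before counting.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    fr = friedman_test(matrix)
    if require_omnibus and fr.p_value >= alpha:
        raise ValueError(
            f"Friedman omnibus not significant (p = {fr.p_value:.4g} >= {alpha}); "
            "pairwise post hocs not justified"
        )
    if matrix.n < 6:
        logger.warning(
            "n = %d participants: a two-sided exact signed-rank test cannot "
            "reach p < 0.05", matrix.n,
        )
    k = matrix.k
    labels = list(matrix.group_labels)
    pmat = np.full((k, k), np.nan)
    dmat = np.zeros((k, k), dtype=bool)
    pairs: list[tuple[int, int]] = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pvals = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        p, degen = exact_wilcoxon_p(matrix.values[:, i], matrix.values[:, j])
        pvals[idx] = p
        dmat[i, j] = dmat[j, i] = degen
    if holm:
        pvals = _holm(pvals)
    for (i, j), p in zip(pairs, pvals):
        pmat[i, j] = pmat[j, i] = p
    sig = pd.Series(
        np.nansum(np.where(np.isnan(pmat), np.inf, pmat) < alpha, axis=1).astype(int),
        index=labels,
        name="sig_count",
    )
    return GroupStatsResult(
        chi2=fr.chi2,
        df=fr.df,
        p_value=fr.p_value,
        pairwise_p=pd.DataFrame(pmat, index=labels, columns=labels),
        degenerate=pd.DataFrame(dmat, index=labels, columns=labels),
        alpha=alpha,
        sig_counts=sig,
    )


def score_matrix_from_means(
    means: pd.DataFrame,
    drop_incomplete_groups: bool = False,
) -> ScoreMatrix:
    """Build a :class:`ScoreMatrix` from a tidy frame of participant means.

    ``means`` has columns (participant, group, value), one row per cell.
    Missing cells are a hard error by default (the design assumes every
    participant performed every group); ``drop_incomplete_groups``
    instead drops groups not observed for all participants.
    """
    wide = means.pivot(index="participant", columns="group", values="value")
    if drop_incomplete_groups:
        dropped = wide.columns[wide.isna().any()].tolist()
        if dropped:
            logger.warning("dropping incomplete group(s): %s", dropped)
        wide = wide.dropna(axis=1)
    return ScoreMatrix(
        values=wide.to_numpy(),
        participant_ids=tuple(str(i) for i in wide.index),
        group_labels=tuple(str(c) for c in wide.columns),
    )
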