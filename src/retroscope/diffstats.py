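"""Paired pre/post induction statistics.

The headline statistic is per subject the percentage of pre-induction
expression relative to post-induction expression,

    pct_i = 100 * RPKM_pre,i / RPKM_post,i,

summarised as mean +/- sample SD and tested with a one-sample two-tailed
Student's t against 100 (the no-change null). An alternative paired t-test
on log2 RPKM ratios is provided; unlike the percentage statistic, the
log-ratio's null expectation is exactly zero under no change, which makes
it the calibration-correct choice for type-I-error studies (the ratio of
two equally-noisy positive measurements has expectation above 1).

Elements or loci are ranked by log2 fold change of group-mean expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class PairedChange:
    """Per-subject pre/post percentages with the group-level test."""

    pct: pd.Series  # subject -> 100 * pre / post
    mean_pct: float
    sd_pct: float
    n: int
    t_statistic: float  # NaN when the pct vector has zero variance
    p_value: float
    significant: bool


def _one_sample_t(values: np.ndarray, null: float) -> tuple[float, float, float, float]:
    """Mean, sample SD, t and two-tailed p against ``null``.

    Zero variance is reported as t = NaN, p = 1 (no evidence against the
    null) rather than an error.
    """
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return mean, sd, float("nan"), 1.0
    t = (mean - null) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return mean, sd, t, p


def _match_subjects(pre: pd.Series, post: pd.Series) -> tuple[pd.Series, pd.Series]:
    pre = pd.Series(pre, dtype=float)
    post = pd.Series(post, dtype=float)
    if set(pre.index) != set(post.index):
        raise ValueError("pre and post subjects do not match")
    post = post.reindex(pre.index)
    return pre, post


def paired_percentage(
    pre: pd.Series, post: pd.Series, pseudocount: float = 0.0
) -> PairedChange:
    """Per-subject pre/post percentage plus the group mean, SD and t-test.

    ``pre`` and ``post`` are subject-indexed expression values (RPKM) at
    the two timepoints. Requires n >= 2 and strictly positive post values
    (after adding ``pseudocount``).
    """
    pre, post = _match_subjects(pre, post)
    if len(pre) < 2:
        raise ValueError("paired statistics need at least 2 subjects")
    denom = post + pseudocount
    bad = denom[denom <= 0]
    if not bad.empty:
        raise ValueError(
            f"non-positive post expression for subject(s) {list(bad.index)}"
        )
    pct = 100.0 * (pre + pseudocount) / denom
    mean, sd, t, p = _one_sample_t(pct.to_numpy(), 100.0)
    return PairedChange(
        pct=pct,
        mean_pct=mean,
        sd_pct=sd,
        n=len(pct),
        t_statistic=t,
        p_value=p,
        significant=p < ALPHA,
    )


def paired_log_ttest(
    pre: pd.Series, post: pd.Series, pseudocount: float = 0.0
) -> tuple[float, float]:
    """Paired two-tailed t-test on per-subject log2(post/pre) ratios.

    Returns (t, p). The null (mean log-ratio 0) holds exactly when pre and
    post are exchangeable, so this flavor is used for null-calibration
    experiments.
    """
    pre, post = _match_subjects(pre, post)
    if len(pre) < 2:
        raise ValueError("paired statistics need at least 2 subjects")
    num = post + pseudocount
    den = pre + pseudocount
    if (num <= 0).any() or (den <= 0).any():
        raise ValueError("log ratio needs strictly positive expression values")
    logratio = np.log2(num.to_numpy() / den.to_numpy())
    _, _, t, p = _one_sample_t(logratio, 0.0)
    return t, p


def rank_induction(
    expr_pre: pd.DataFrame,
    expr_post: pd.DataFrame,
    level: str = "element",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Rank items (elements or loci) by induction.

    ``expr_pre`` / ``expr_post`` are item x subject matrices with matching
    axes. The score is log2((mean_post + pseudocount)/(mean_pre +
    pseudocount)), sorted descending; ties (and equal infinities) break
    lexicographically by item name. Items with a zero denominator and no
    pseudocount get +inf and sort first among positives.

    Returns a frame indexed by item with columns mean_pre, mean_post,
    log2fc, rank (1-based).
    """
    if level not in ("element", "locus"):
        raise ValueError(f"unknown ranking level {level!r}")
    if set(expr_pre.index) != set(expr_post.index):
        raise ValueError("pre and post items do not match")
    if set(expr_pre.columns) != set(expr_post.columns):
        raise ValueError("pre and post subjects do not match")
    expr_post = expr_post.reindex(index=expr_pre.index, columns=expr_pre.columns)
    mean_pre = expr_pre.mean(axis=1) + pseudocount
    mean_post = expr_post.mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_post.to_numpy() / mean_pre.to_numpy())
    out = pd.DataFrame(
        {
            "mean_pre": mean_pre - pseudocount,
            "mean_post": mean_post - pseudocount,
            "log2fc": log2fc,
        },
        index=expr_pre.index,
    )
    out = out.sort_index().sort_values("log2fc", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
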