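"""Small-sample paired statistics and report tables.

Paired baseline-vs-after comparisons use the Wilcoxon signed-rank test.
The default p-value is the asymptotic normal approximation *without*
continuity correction:

    T = min(W+, W-),  z = (T - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)

with mid-ranks for tied |differences| and zero differences dropped.  An
exact sign-flip enumeration (feasible for n <= 15) is available with
``method="exact"``; for n = 7 uniformly signed differences the asymptotic
p is 0.018 while the exact p is 2/128 ~ 0.016.

Correlation screening uses the Pearson coefficient with p-values from the
t distribution on n - 2 degrees of freedom, t = r sqrt(n-2) / sqrt(1-r^2).
Both one-sided (tail in the direction of the observed r) and two-sided
p-values are reported; a Spearman rank alternative is provided explicitly.

Group descriptives are mean +- SE (SD/sqrt(n), SD with ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PairingError, StatisticsError

_EXACT_N_MAX = 15


@dataclass
class PairedComparisonResult:
    metric_name: str
    mean_pre: float
    se_pre: float
    mean_post: float
    se_post: float
    n: int
    w_statistic: float
    z_value: float
    p_two_sided: float
    method: str = "asymptotic"


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    n: int
    t_value: float
    p_one_sided: float
    p_two_sided: float
    degenerate: bool = False


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def wilcoxon_paired(
    pre, post, metric_name: str = "", method: str = "asymptotic"
) -> PairedComparisonResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (n reduced); ties in |d| get mid-ranks.
    ``method="exact"`` enumerates all sign assignments of the observed ranks
    (n <= 15).  Raises :class:`StatisticsError` when all differences vanish.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise StatisticsError("pre and post must be 1-D arrays of equal length")
    mean_pre, se_pre = float(np.mean(pre)), _se(pre)
    mean_post, se_post = float(np.mean(post)), _se(post)

    d = post - pre
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise StatisticsError("all paired differences are zero: test undefined")
    if n < 5:
        raise StatisticsError(f"need >= 5 nonzero differences, got {n}")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    t_stat = min(w_plus, w_minus)

    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (t_stat - mu) / sigma

    if method == "asymptotic":
        p = float(2.0 * sps.norm.sf(abs(z)))
    elif method == "exact":
        if n > _EXACT_N_MAX:
            raise StatisticsError(f"exact enumeration limited to n <= {_EXACT_N_MAX}")
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        total = ranks.sum()
        # two-sided: both tails of the symmetric sign-flip null
        p = float(
            (np.sum(sums <= t_stat) + np.sum(sums >= total - t_stat)) / len(sums)
        )
        p = min(p, 1.0)
    else:
        raise StatisticsError(f"unknown method {method!r}")
    return PairedComparisonResult(
        metric_name=metric_name,
        mean_pre=mean_pre,
        se_pre=se_pre,
        mean_post=mean_post,
        se_post=se_post,
        n=n,
        w_statistic=t_stat,
        z_value=float(z),
        p_two_sided=min(p, 1.0),
        method=method,
    )


def _p_from_r(r: float, n: int) -> tuple[float, float, float, bool]:
    """(t, p_one_sided, p_two_sided, degenerate) from a correlation and n."""
    df = n - 2
    if abs(r) >= 1.0:
        return float("inf") * np.sign(r), 0.0, 0.0, True
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p_one = float(sps.t.sf(abs(t), df))
    return float(t), p_one, min(2.0 * p_one, 1.0), False


def correlation_from_r(r: float, n: int, x_name: str = "", y_name: str = "") -> CorrelationResult:
    """Build a :class:`CorrelationResult` from a known coefficient and n."""
    if n < 3:
        raise StatisticsError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise StatisticsError(f"correlation must lie in [-1, 1], got {r}")
    t, p_one, p_two, degenerate = _p_from_r(r, n)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, r=float(r), n=n,
        t_value=t, p_one_sided=p_one, p_two_sided=p_two, degenerate=degenerate,
    )


def pearson_correlation(x, y, x_name: str = "", y_name: str = "") -> CorrelationResult:
    """Pearson correlation with t-distribution p-values (one- and two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise StatisticsError(f"need n >= 3 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatisticsError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticsError("zero variance in correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    return correlation_from_r(r, n, x_name=x_name, y_name=y_name)


def spearman_correlation(x, y, x_name: str = "", y_name: str = "") -> CorrelationResult:
    """Rank (Spearman) alternative: Pearson on the ranks of x and y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pearson_correlation(
        sps.rankdata(x), sps.rankdata(y), x_name=x_name, y_name=y_name
    )


def build_report(
    metrics: pd.DataFrame,
    pre_label: str = "baseline",
    post_label: str = "after_evar",
    correlation_target: str | None = None,
    correlation_predictors: list[str] | None = None,
    method: str = "asymptotic",
) -> dict[str, pd.DataFrame]:
    """Paired-comparison and correlation tables from a per-subject table.

    ``metrics`` must be tidy: one row per subject/condition with columns
    ``subject_id``, ``condition`` and numeric metric columns.  Returns
    ``{"paired": ..., "correlations": ...}`` (the latter only when a
    ``correlation_target`` is given; correlations use the post-condition
    rows).  Values are mean +- SE with the paired two-sided p.
    """
    for col in ("subject_id", "condition"):
        if col not in metrics.columns:
            raise PairingError(f"metrics table lacks a {col!r} column")
    pre_df = metrics[metrics["condition"] == pre_label].set_index("subject_id")
    post_df = metrics[metrics["condition"] == post_label].set_index("subject_id")
    missing_post = sorted(set(pre_df.index) - set(post_df.index))
    missing_pre = sorted(set(post_df.index) - set(pre_df.index))
    if missing_post or missing_pre:
        raise PairingError(
            f"unpaired subjects: missing {post_label} for {missing_post}, "
            f"missing {pre_label} for {missing_pre}"
        )
    subjects = sorted(pre_df.index)
    if len(subjects) < 2:
        raise PairingError(f"need >= 2 paired subjects, got {len(subjects)}")
    pre_df = pre_df.loc[subjects]
    post_df = post_df.loc[subjects]

    metric_cols = [
        c for c in metrics.columns
        if c not in ("subject_id", "condition")
        and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    rows = []
    for col in metric_cols:
        pre_v = pre_df[col].to_numpy(dtype=float)
        post_v = post_df[col].to_numpy(dtype=float)
        if np.isnan(pre_v).any() or np.isnan(post_v).any():
            continue
        try:
            res = wilcoxon_paired(pre_v, post_v, metric_name=col, method=method)
            p = res.p_two_sided
        except StatisticsError:
            p = float("nan")
        rows.append(
            {
                "metric": col,
                f"mean_{pre_label}": float(np.mean(pre_v)),
                f"se_{pre_label}": _se(pre_v),
                f"mean_{post_label}": float(np.mean(post_v)),
                f"se_{post_label}": _se(post_v),
                "p_value": p,
            }
        )
    report = {"paired": pd.DataFrame(rows)}

    if correlation_target is not None:
        predictors = correlation_predictors or [
            c for c in metric_cols if c != correlation_target
        ]
        corr_rows = []
        for col in predictors:
            x = post_df[col].to_numpy(dtype=float)
            y = post_df[correlation_target].to_numpy(dtype=float)
            try:
                c = pearson_correlation(x, y, x_name=col, y_name=correlation_target)
                corr_rows.append(
                    {"parameter": col, "R": c.r, "p_value": c.p_one_sided}
                )
            except StatisticsError:
                corr_rows.append(
                    {"parameter": col, "R": float("nan"), "p_value": float("nan")}
                )
        report["correlations"] = pd.DataFrame(corr_rows)
    return report
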