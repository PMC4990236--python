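"""Cohort statistics for subjects x timepoints tables.

The canonical container is a *wide* pandas DataFrame: one row per subject,
one column per timepoint label (e.g. BL, VF10, VF16), holding any scalar
measure (minute-mean AMSA, a derived Fick quantity, ...).  Missing entries
are handled by listwise subject exclusion for the repeated-measures ANOVA
and pairwise-complete deletion for correlations; both report the n used.

The repeated-measures ANOVA is the classical one-way within-subject
decomposition without sphericity correction (a Greenhouse-Geisser epsilon
can be requested), matching the convention of the desktop statistics
packages this analysis style comes from, with Holm-Sidak step-down
adjustment for the pairwise families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RMAnovaResult",
    "PairwiseResult",
    "CorrResult",
    "descriptives",
    "rm_anova",
    "holm_sidak",
    "pairwise_vs_reference",
    "pearson",
    "baseline_variability_correlations",
    "simple_linregress",
    "LinregressResult",
    "rm_anova_null_rejection_rate",
]

_SS_TOL = 1e-12  # relative tolerance for declaring a sum of squares zero


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    n_subjects: int
    n_timepoints: int
    degenerate: bool = False
    excluded_subjects: tuple = ()
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass(frozen=True)
class PairwiseResult:
    comparison: str
    raw_p: float
    adjusted_p: float
    step_alpha: float
    significant: bool          # step-down decision at the requested alpha
    significant_05: bool       # adjusted p <= 0.05
    significant_001: bool      # adjusted p <= 0.001


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class LinregressResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint mean, SD (n-1 denominator), SEM = SD/sqrt(n), and n.

    Timepoints with a single observation get a mean but missing SD/SEM.
    """
    n = table.notna().sum(axis=0)
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    sem = sd / np.sqrt(n)
    out = pd.DataFrame({"mean": mean, "sd": sd, "sem": sem, "n": n})
    out.index.name = "timepoint"
    return out


def _complete_cases(table: pd.DataFrame) -> tuple[np.ndarray, tuple]:
    complete = table.notna().all(axis=1)
    excluded = tuple(table.index[~complete])
    return table.loc[complete].to_numpy(dtype=float), excluded


def rm_anova(
    table: pd.DataFrame | np.ndarray, gg_correction: bool = False
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x timepoints table.

    Classical decomposition: SS_time (df k-1) against the subject-by-time
    residual SS_error = SS_within - SS_time (df (n-1)(k-1)),
    F = MS_time / MS_error, p from the F distribution.  Subjects with any
    missing timepoint are excluded listwise and reported.

    Zero time variance gives F = 0, p = 1; zero residual variance with
    nonzero time variance gives an infinite F with p = 0 and the result
    flagged degenerate.  ``gg_correction`` adds a Greenhouse-Geisser
    epsilon and corrected p alongside the uncorrected ones.
    """
    if isinstance(table, pd.DataFrame):
        x, excluded = _complete_cases(table)
    else:
        x = np.asarray(table, dtype=float)
        excluded = ()
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 complete subjects and >= 2 timepoints, got {n}x{k}")

    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_time = n * np.sum((col_means - grand) ** 2)
    ss_within = np.sum((x - row_means[:, None]) ** 2)
    ss_error = ss_within - ss_time
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)

    scale = max(np.sum((x - grand) ** 2), 1.0)
    degenerate = False
    if ss_time <= _SS_TOL * scale:
        f_stat, p = 0.0, 1.0
    elif ss_error <= _SS_TOL * scale:
        f_stat, p, degenerate = float("inf"), 0.0, True
    else:
        f_stat = (ss_time / df_effect) / (ss_error / df_error)
        p = float(sps.f.sf(f_stat, df_effect, df_error))

    eps = p_gg = None
    if gg_correction and np.isfinite(f_stat) and f_stat > 0:
        eps = _gg_epsilon(x)
        p_gg = float(sps.f.sf(f_stat, df_effect * eps, df_error * eps))

    return RMAnovaResult(
        F=f_stat,
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        n_subjects=n,
        n_timepoints=k,
        degenerate=degenerate,
        excluded_subjects=excluded,
        gg_epsilon=eps,
        p_gg=p_gg,
    )


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon of a subjects x timepoints array."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False, ddof=1)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def holm_sidak(
    raw_ps, alpha: float = 0.05, labels=None
) -> list[PairwiseResult]:
    """Holm-Sidak step-down multiple-comparison adjustment.

    The i-th smallest of m p-values is tested at 1 - (1 - alpha)^(1/(m-i+1));
    once one comparison fails, all larger ones fail.  Adjusted p-values are
    1 - (1 - p)^(m-i+1), made monotone nondecreasing and capped at 1.
    Results are returned in the input order.
    """
    ps = np.asarray(raw_ps, dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    if labels is None:
        labels = [f"comparison {i + 1}" for i in range(m)]
    order = np.argsort(ps, kind="stable")
    step_alpha = np.empty(m)
    adj = np.empty(m)
    significant = np.empty(m, dtype=bool)
    still_rejecting = True
    running_max = 0.0
    for rank, idx in enumerate(order):  # rank 0-based, i = rank + 1
        remaining = m - rank
        a_i = 1.0 - (1.0 - alpha) ** (1.0 / remaining)
        adj_i = min(1.0, 1.0 - (1.0 - ps[idx]) ** remaining)
        running_max = max(running_max, adj_i)
        step_alpha[idx] = a_i
        adj[idx] = running_max
        still_rejecting = still_rejecting and ps[idx] <= a_i
        significant[idx] = still_rejecting
    return [
        PairwiseResult(
            comparison=str(labels[i]),
            raw_p=float(ps[i]),
            adjusted_p=float(adj[i]),
            step_alpha=float(step_alpha[i]),
            significant=bool(significant[i]),
            significant_05=bool(adj[i] <= 0.05),
            significant_001=bool(adj[i] <= 0.001),
        )
        for i in range(m)
    ]


def pairwise_vs_reference(
    table: pd.DataFrame, reference: str, alpha: float = 0.05
) -> list[PairwiseResult]:
    """Paired t-tests of every timepoint against ``reference``, Holm-Sidak adjusted.

    This is the "a vs BL / b vs VF10" comparison-family style: one family
    per reference column.
    """
    if reference not in table.columns:
        raise KeyError(f"reference timepoint {reference!r} not in table")
    others = [c for c in table.columns if c != reference]
    raw = []
    for c in others:
        pair = table[[reference, c]].dropna()
        t_res = sps.ttest_rel(pair[c], pair[reference])
        raw.append(float(t_res.pvalue))
    labels = [f"{c} vs {reference}" for c in others]
    return holm_sidak(raw, alpha=alpha, labels=labels)


def _paired_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> CorrResult:
    """Pearson correlation with a two-sided t-based p-value on n-2 df.

    Uses pairwise-complete cases; requires n >= 3 and nonzero variance in
    both inputs ("constant input" otherwise).
    """
    xv, yv = _paired_complete(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError("constant input")
    res = sps.pearsonr(xv, yv)
    return CorrResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def baseline_variability_correlations(
    minute_table: pd.DataFrame, anchor: str, targets
) -> pd.DataFrame:
    """Correlate one anchor timepoint against several targets, row-robustly.

    One Pearson row per target; a failing row (constant input, too few
    pairs) is recorded with its error message instead of aborting the rest.
    """
    if anchor not in minute_table.columns:
        raise KeyError(f"anchor {anchor!r} not in table")
    rows = []
    for tgt in targets:
        row = {"target": tgt, "r": np.nan, "p": np.nan, "n": 0, "error": ""}
        try:
            if tgt not in minute_table.columns:
                raise KeyError(f"target {tgt!r} not in table")
            res = pearson(minute_table[anchor], minute_table[tgt])
            row.update(r=res.r, p=res.p, n=res.n)
        except (ValueError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def simple_linregress(x, y) -> LinregressResult:
    """Ordinary least squares y = a + b x; slope p from t on n-2 df."""
    xv, yv = _paired_complete(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.var(xv) == 0:
        raise ValueError("constant input")
    if np.var(yv) == 0:  # flat response: zero slope, zero correlation
        return LinregressResult(
            slope=0.0, intercept=float(yv.mean()), r=0.0, p=1.0, n=n
        )
    res = sps.linregress(xv, yv)
    return LinregressResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=n,
    )


def rm_anova_null_rejection_rate(
    n_subjects: int = 16,
    n_timepoints: int = 4,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the RM-ANOVA under i.i.d. normal nulls.

    Vectorised across replicates; returns the fraction of replicates with
    p < alpha.  Under the null this should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n_subjects, n_timepoints))
    col_means = x.mean(axis=1)
    row_means = x.mean(axis=2)
    grand = x.mean(axis=(1, 2))
    ss_time = n_subjects * np.sum((col_means - grand[:, None]) ** 2, axis=1)
    ss_within = np.sum((x - row_means[:, :, None]) ** 2, axis=(1, 2))
    ss_error = ss_within - ss_time
    df_e = n_timepoints - 1
    df_r = (n_subjects - 1) * (n_timepoints - 1)
    f_stat = (ss_time / df_e) / (ss_error / df_r)
    p = sps.f.sf(f_stat, df_e, df_r)
    return float(np.mean(p < alpha))
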