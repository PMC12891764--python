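"""Cohort statistics protocol: summaries, outlier screening, rank tests.

Implements the nonparametric protocol used to characterize a healthy
cohort:

* descriptive summaries — mean, sample SD, Q1-Q3 (linear-interpolation
  quantiles), and coefficient of variation CV% = SD/mean * 100;
* one-pass 3xIQR outlier exclusion on the three core parameters
  (Ratio-Area, Ratio-SV, resistance), with quartiles computed on the
  pre-exclusion table;
* Wilcoxon rank-sum comparison of unpaired groups with midranks,
  tie-corrected variance, continuity correction, and effect size
  r = Z / sqrt(n_total), where n_total is the number of analyzed subjects;
* Spearman rank correlations and a pairwise-complete correlation matrix
  with significance stars at 0.05 / 0.01 / 0.001.

Values are never rounded internally; rounding (2 dp for r, integer percent
for CV) happens only in the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "TestResult",
    "OutlierRule",
    "summarize",
    "exclude_outliers",
    "wilcoxon_rank_sum",
    "wilcoxon_exact_p",
    "effect_size_r",
    "spearman",
    "correlation_matrix",
    "cohort_report",
]

CORE_PARAMETERS = ("ratio_area", "ratio_sv", "resistance")


@dataclass
class SummaryStats:
    mean: float
    sd: float
    q1: float
    q3: float
    cv_pct: float | None  # None when the mean is zero

    def rounded(self) -> dict:
        """Presentation form: CV as integer percent."""
        return {
            "mean": self.mean,
            "sd": self.sd,
            "q1": self.q1,
            "q3": self.q3,
            "cv_pct": None if self.cv_pct is None else int(round(self.cv_pct)),
        }


@dataclass
class TestResult:
    z_value: float
    p_value: float
    effect_r: float
    n_total: int


@dataclass(frozen=True)
class OutlierRule:
    k: float = 3.0
    columns: tuple[str, ...] = CORE_PARAMETERS

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("IQR multiplier must be positive")


def summarize(values) -> SummaryStats:
    """Mean, sample SD (n-1), linear-interpolation quartiles, CV%."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values to summarize")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    q1, q3 = (float(v) for v in np.quantile(x, [0.25, 0.75]))
    cv = None if mean == 0 else sd / abs(mean) * 100.0
    return SummaryStats(mean, sd, q1, q3, cv)


def exclude_outliers(
    table: pd.DataFrame, rule: OutlierRule = OutlierRule()
) -> tuple[pd.DataFrame, list[dict]]:
    """Single screening pass over the core parameters.

    A row is excluded iff any screened value lies below Q1 - k*IQR or above
    Q3 + k*IQR, with quartiles computed on *all* rows before any exclusion
    (so the pass is idempotent by construction).  When IQR = 0 the bounds
    collapse to [Q1, Q3] and any deviation, however small, is excluded.
    Returns the kept table and a log of exclusions with the offending
    column.
    """
    bounds = {}
    for col in rule.columns:
        if col not in table.columns:
            raise KeyError(f"screened column {col!r} missing from table")
        q1, q3 = np.nanquantile(table[col].astype(float), [0.25, 0.75])
        iqr = q3 - q1
        bounds[col] = (q1 - rule.k * iqr, q3 + rule.k * iqr)
    excluded: list[dict] = []
    drop = []
    for idx, row in table.iterrows():
        for col in rule.columns:
            v = float(row[col])
            lo, hi = bounds[col]
            if np.isfinite(v) and (v < lo or v > hi):
                excluded.append(
                    {"id": row.get("id", idx), "column": col, "value": v, "bounds": (lo, hi)}
                )
                drop.append(idx)
                break
    return table.drop(index=drop), excluded


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def wilcoxon_rank_sum(group_a, group_b, continuity: bool = True) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) Z with ties and continuity correction.

    Z is the deviation of group A's rank sum from its null expectation, in
    null SD units; negative Z means group A tends to rank lower.  Two-tailed
    p from the normal approximation; effect size r = Z / sqrt(n_a + n_b).
    """
    a = np.asarray(pd.Series(group_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(group_b).dropna(), dtype=float)
    na, nb = len(a), len(b)
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    n = na + nb
    ranks = stats.rankdata(pooled)
    w = float(ranks[:na].sum())
    expect = na * (n + 1) / 2.0
    var = na * nb / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return TestResult(0.0, 1.0, 0.0, n)
    d = w - expect
    if continuity:
        d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    return TestResult(float(z), p, float(z / np.sqrt(n)), n)


def effect_size_r(z_value: float, n_total: int) -> float:
    """r = Z / sqrt(n); the worked-example arithmetic used in reports."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return float(z_value / np.sqrt(n_total))


def wilcoxon_exact_p(group_a, group_b) -> float:
    """Exact two-tailed p by enumeration of all rank assignments.

    Independent oracle for small groups (n_a + n_b <= ~14): enumerates
    every C(n, n_a) allocation of the pooled midranks to group A and counts
    allocations whose |rank-sum deviation| is at least the observed one.
    """
    from itertools import combinations

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, n = len(a), len(pooled)
    expect = na * (n + 1) / 2.0
    obs = abs(ranks[:na].sum() - expect)
    hits = total = 0
    for comb in combinations(range(n), na):
        total += 1
        if abs(ranks[list(comb)].sum() - expect) >= obs - 1e-9:
            hits += 1
    return hits / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on midranks) with two-tailed t-approximation p.

    Returns ``(nan, nan)`` when either vector has zero variance.
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 complete pairs")
    if df["x"].nunique() < 2 or df["y"].nunique() < 2:
        return float("nan"), float("nan")
    res = stats.spearmanr(df["x"], df["y"])
    return float(res.statistic), float(res.pvalue)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Symmetric Spearman rho / p / significance-star matrices.

    Pairwise-complete rows; entries with fewer than 4 complete pairs are
    left missing.
    """
    k = len(columns)
    rho = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    pmat = pd.DataFrame(np.full((k, k), np.nan), index=columns, columns=columns)
    smat = pd.DataFrame([[""] * k for _ in range(k)], index=columns, columns=columns)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[columns[i], columns[j]]].dropna()
            if len(pair) < 4:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r, p = spearman(pair[columns[i]], pair[columns[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
            smat.iloc[i, j] = smat.iloc[j, i] = _stars(p)
    return rho, pmat, smat


def cohort_report(
    table: pd.DataFrame,
    columns: list[str],
    sex_column: str = "sex",
) -> dict:
    """Table-1-style report: total/male/female summaries + sex comparisons.

    Effect sizes use the number of analyzed subjects as n.  CV is rounded
    to integer percent and r to 2 dp only here, at presentation time.
    """
    males = table[table[sex_column] == "male"]
    females = table[table[sex_column] == "female"]
    report: dict = {
        "n_total": int(len(table)),
        "n_male": int(len(males)),
        "n_female": int(len(females)),
        "parameters": {},
    }
    for col in columns:
        block = {
            "total": summarize(table[col]).rounded(),
            "male": summarize(males[col]).rounded() if len(males) >= 2 else None,
            "female": summarize(females[col]).rounded() if len(females) >= 2 else None,
        }
        if len(males) >= 3 and len(females) >= 3:
            t = wilcoxon_rank_sum(males[col], females[col])
            block["male_vs_female"] = {
                "z_value": t.z_value,
                "p_value": t.p_value,
                "effect_r": round(t.effect_r, 2),
                "n_total": t.n_total,
            }
        report["parameters"][col] = block
    return report
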