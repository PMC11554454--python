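"""Group-level statistics for microstate features and clinical scores.

Implements the statistical layer of a two-group clinical comparison:
pooled-variance two-sample t-tests (computable from raw vectors or from
published mean +/- sd summaries), Pearson chi-square tests on 2x2
contingency tables (no continuity correction), Pearson correlation with
clinical scores, and Benjamini-Hochberg false-discovery-rate adjustment
across the 24 microstate features.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .temporal import FEATURE_NAMES


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- sd summary of n observations, as printed in clinical tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("summary requires n >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _as_summary(x) -> SummaryStat:
    if isinstance(x, SummaryStat):
        return x
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("raw sample must be a 1-D vector with n >= 2")
    return SummaryStat(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def t_test_pooled(a, b) -> TTestResult:
    """Student's pooled-variance two-sample t-test (two-sided).

    Accepts raw vectors or :class:`SummaryStat` summaries; both routes
    give identical statistics.  With zero pooled variance and equal
    means the statistic is 0.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    df = sa.n + sb.n - 2
    pooled_var = ((sa.n - 1) * sa.sd ** 2 + (sb.n - 1) * sb.sd ** 2) / df
    se = np.sqrt(pooled_var * (1.0 / sa.n + 1.0 / sb.n))
    if se == 0:
        t = 0.0 if sa.mean == sb.mean else np.inf * np.sign(sa.mean - sb.mean)
    else:
        t = (sa.mean - sb.mean) / se
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TTestResult(float(t), float(df), p)


def t_test_welch(a, b) -> TTestResult:
    """Welch's unequal-variance variant, for sensitivity checks."""
    sa, sb = _as_summary(a), _as_summary(b)
    va, vb = sa.sd ** 2 / sa.n, sb.sd ** 2 / sb.n
    se = np.sqrt(va + vb)
    if se == 0:
        return TTestResult(0.0, float(sa.n + sb.n - 2), 1.0)
    t = (sa.mean - sb.mean) / se
    df = (va + vb) ** 2 / (va ** 2 / (sa.n - 1) + vb ** 2 / (sb.n - 1))
    return TTestResult(float(t), float(df), float(2.0 * sps.t.sf(abs(t), df)))


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 count table, without Yates correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(chi2), int(df), float(p))


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t distribution (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a nonempty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_FEATURE_FAMILY = {
    name: ("Duration" if name.startswith("Duration")
           else "Occurrence" if name.startswith("Occurrence")
           else "Contribution" if name.startswith("Contribution")
           else "Transition")
    for name in FEATURE_NAMES
}


def compare_cohorts(features_a: pd.DataFrame, features_b: pd.DataFrame,
                    features: Sequence[str] = tuple(FEATURE_NAMES),
                    alpha: float = 0.05,
                    fdr_family: str = "all") -> pd.DataFrame:
    """Per-feature pooled t-tests between two cohorts with FDR adjustment.

    ``fdr_family='all'`` corrects across the full feature list at once;
    ``'per_type'`` corrects within each parameter family (durations,
    occurrences, contributions, transitions) separately.
    """
    if features_a.empty or features_b.empty:
        raise ValueError("both cohorts must be nonempty")
    missing = [f for f in features if f not in features_a.columns
               or f not in features_b.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    rows = []
    for name in features:
        res = t_test_pooled(features_a[name].to_numpy(),
                            features_b[name].to_numpy())
        rows.append({
            "parameter": name,
            "family": _FEATURE_FAMILY.get(name, "Other"),
            "mean_a": features_a[name].mean(), "sd_a": features_a[name].std(ddof=1),
            "mean_b": features_b[name].mean(), "sd_b": features_b[name].std(ddof=1),
            "t": res.t, "df": res.df, "p": res.p,
        })
    table = pd.DataFrame(rows)
    if fdr_family == "all":
        table["p_fdr"] = fdr_bh(table["p"].to_numpy())
    elif fdr_family == "per_type":
        table["p_fdr"] = np.nan
        for _fam, idx in table.groupby("family").groups.items():
            table.loc[idx, "p_fdr"] = fdr_bh(table.loc[idx, "p"].to_numpy())
    else:
        raise ValueError("fdr_family must be 'all' or 'per_type'")
    table["significant"] = table["p_fdr"] < alpha
    return table


def correlate_with_scores(features: pd.DataFrame, scores: Sequence[float],
                          feature_names: Sequence[str] = tuple(FEATURE_NAMES),
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each microstate feature with a clinical score."""
    scores = np.asarray(scores, dtype=float)
    rows = []
    for name in feature_names:
        res = pearson_corr(features[name].to_numpy(), scores)
        rows.append({"parameter": name, "r": res.r, "p": res.p, "n": res.n})
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < alpha
    return table
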