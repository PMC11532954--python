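"""Expression-level and expression-variability statistics.

Works on a genes x samples fpkm matrix with per-sample metadata (tissue,
normal/tumor condition, patient pairing key). Expression levels are compared
on log2(fpkm + 1); coefficients of variation are computed on linear fpkm by
default (the log transform is a display convention, not part of the CV
definition), switchable via ``log_scale``.

Two CV flavours mirror the two questions asked of tumor/normal cohorts:

* indiv-CV — per gene, 100 * SD / mean across individual patients of one
  condition: how much a gene's expression varies across people.
* g-CV — per sample, 100 * SD / mean across a defined gene set: how dispersed
  the transcriptome is within one person.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

CONDITIONS = ("normal", "tumor")

#: minimum complete normal/tumor pairs for a paired CV comparison
MIN_PAIRS = 15


@dataclass
class ExpressionMatrix:
    """fpkm values (genes x samples) plus per-sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``tissue``,
    ``condition`` (normal/tumor) and ``patient_id``; paired samples share
    ``patient_id`` across conditions.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("fpkm values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        return list(meta.index[meta["condition"] == condition])

    def condition_values(self, condition: str) -> pd.DataFrame:
        cols = self.samples_in(condition)
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return self.values[cols]


def log_mean_expression(
    m: ExpressionMatrix, samples: Sequence[str] | None = None
) -> pd.Series:
    """Per-gene mean of log2(fpkm + 1) over the selected samples (default all)."""
    cols = list(samples) if samples is not None else list(m.values.columns)
    if not cols:
        raise ValueError("empty sample selection")
    return np.log2(m.values[cols] + 1.0).mean(axis=1)


@dataclass
class GroupCompareResult:
    median_with: float
    median_without: float
    p_value: float
    method: str


def group_compare(
    values_with: Sequence[float], values_without: Sequence[float]
) -> GroupCompareResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    Exact enumeration when both groups have <= 12 untied observations,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(values_with, dtype=float)
    y = np.asarray(values_without, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("group_compare: all observations tied; p = 1")
        return GroupCompareResult(float(np.median(x)), float(np.median(y)), 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 12 and len(y) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupCompareResult(
        float(np.median(x)), float(np.median(y)), float(res.pvalue), method
    )


def tumor_normal_log2fc(m: ExpressionMatrix) -> pd.Series:
    """Per-gene log2((mean tumor fpkm + 1) / (mean normal fpkm + 1)).

    Means are taken over all samples of each condition; swapping condition
    labels negates every value.
    """
    mean_t = m.condition_values("tumor").mean(axis=1)
    mean_n = m.condition_values("normal").mean(axis=1)
    return np.log2((mean_t + 1.0) / (mean_n + 1.0))


@dataclass
class SetContrastResult:
    mean_with: float
    mean_without: float
    p_value: float


def log2fc_set_contrast(
    log2fc: pd.Series, genes_with: Iterable[str], genes_without: Iterable[str]
) -> SetContrastResult:
    """Welch two-sample t test contrasting per-gene log2FC between gene sets."""
    a = log2fc.loc[[g for g in genes_with if g in log2fc.index]].to_numpy()
    b = log2fc.loc[[g for g in genes_without if g in log2fc.index]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both gene sets need >= 2 genes present in the matrix")
    res = sps.ttest_ind(a, b, equal_var=False)
    return SetContrastResult(float(a.mean()), float(b.mean()), float(res.pvalue))


@dataclass
class CVResult:
    """Coefficients of variation (percent) per unit, with zero-mean exclusions.

    ``cv`` is indexed by gene id (indiv-CV) or sample id (g-CV); units whose
    mean expression is zero carry no CV and are only counted in ``n_excluded``.
    """

    cv: pd.Series
    n_excluded: int


def _cv_percent(values: np.ndarray, axis: int, log_scale: bool) -> np.ndarray:
    v = np.log2(values + 1.0) if log_scale else values
    mean = v.mean(axis=axis)
    sd = v.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, 100.0 * sd / mean, np.nan)


def indiv_cv(
    m: ExpressionMatrix, condition: str, log_scale: bool = False
) -> CVResult:
    """Per-gene CV (100*SD/mean, sample SD) across patients of one condition."""
    vals = m.condition_values(condition)
    if vals.shape[1] < 2:
        raise ValueError(f"condition {condition!r} needs >= 2 samples for a CV")
    cv = _cv_percent(vals.to_numpy(dtype=float), axis=1, log_scale=log_scale)
    s = pd.Series(cv, index=vals.index)
    excluded = int(s.isna().sum())
    return CVResult(s.dropna(), excluded)


def g_cv(
    m: ExpressionMatrix, gene_set: Iterable[str], log_scale: bool = False
) -> CVResult:
    """Per-sample CV across the genes of ``gene_set`` (the transcriptome spread
    within each individual sample)."""
    genes = [g for g in gene_set if g in m.values.index]
    if not genes:
        raise ValueError("empty gene set (no ids present in the matrix)")
    vals = m.values.loc[genes]
    cv = _cv_percent(vals.to_numpy(dtype=float), axis=0, log_scale=log_scale)
    s = pd.Series(cv, index=vals.columns)
    excluded = int(s.isna().sum())
    return CVResult(s.dropna(), excluded)


@dataclass
class PairedTestResult:
    p_value: float
    mean_difference: float  # tumor - normal
    direction: str  # "increase", "decrease" or "none"
    n_pairs: int
    degenerate: bool = False


def paired_condition_test(
    cv_normal: pd.Series | Sequence[float],
    cv_tumor: pd.Series | Sequence[float],
    pairing: Sequence[tuple[str, str]] | None = None,
    min_pairs: int = MIN_PAIRS,
) -> PairedTestResult:
    """Two-sided paired t test of tumor vs normal CVs over complete pairs.

    ``pairing`` lists (normal_id, tumor_id) index pairs; without it the two
    series are aligned positionally. Cohorts with fewer than ``min_pairs``
    complete pairs are refused, mirroring the >= 15 matched-pairs inclusion
    rule for paired tumor/normal comparisons.
    """
    if pairing is not None:
        cn = pd.Series(cv_normal)
        ct = pd.Series(cv_tumor)
        pairs = [(n, t) for n, t in pairing if n in cn.index and t in ct.index]
        normal = np.asarray([cn[n] for n, _ in pairs], dtype=float)
        tumor = np.asarray([ct[t] for _, t in pairs], dtype=float)
    else:
        normal = np.asarray(cv_normal, dtype=float)
        tumor = np.asarray(cv_tumor, dtype=float)
        if len(normal) != len(tumor):
            raise ValueError("unpaired inputs of different length")
    n = len(normal)
    if n < min_pairs:
        raise ValueError(
            f"only {n} complete normal/tumor pairs; the inclusion rule requires "
            f"at least {min_pairs} matched pairs"
        )
    diff = tumor - normal
    mean_diff = float(diff.mean())
    direction = "increase" if mean_diff > 0 else "decrease" if mean_diff < 0 else "none"
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return PairedTestResult(1.0, 0.0, "none", n)
        logger.warning("paired_condition_test: zero-variance non-zero differences; p undefined")
        return PairedTestResult(float("nan"), mean_diff, direction, n, degenerate=True)
    res = sps.ttest_rel(tumor, normal)
    return PairedTestResult(float(res.pvalue), mean_diff, direction, n)


def boxplot_summary(values: Sequence[float]) -> dict[str, float]:
    """Median/quartiles with IQR*1.5 whiskers (the figure-legend convention)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if inside.size else float(q1),
        "whisker_high": float(inside.max()) if inside.size else float(q3),
    }
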