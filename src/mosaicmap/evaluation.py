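"""Strategy-comparison layer.

Every strategy (a GM metric x correction method x smoothing-or-parcellation
setting) reduces each patient to one burden scalar; the strategy's clinical
validity is the Pearson correlation of that scalar with lesion volume (LV)
and with the EDSS disability score across patients.  This module provides
those correlations, the summary-statistic demographic tests (Welch t from
printed group summaries, Yates-corrected chi-square on a 2x2 sex table),
and the comparison harness: one-way ANOVAs over the correlation values for
three hypotheses (outcome LV vs EDSS; approach; smoothing/parcellation
none vs any), with Tukey HSD follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "StrategyRecord",
    "SummaryStats",
    "pearson_r",
    "welch_t_from_summary",
    "yates_chi2",
    "oneway_anova",
    "tukey_hsd",
    "compare_strategies",
]


@dataclass
class StrategyRecord:
    """One row of the strategy table: outcome (LV/EDSS), metric label
    (CT, VBM, MAP, ...), correction label, smoothing sigma or parcellation
    count, and the achieved Pearson r."""

    outcome: str
    metric: str
    correction: str
    smoothing_or_parcellation: float
    r: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"correlation r={self.r} outside [-1, 1]")


@dataclass
class SummaryStats:
    """A printed group summary: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"summary needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"negative SD {self.sd}")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("length mismatch")
    if x.size < 3:
        raise ValidationError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def welch_t_from_summary(a: SummaryStats, b: SummaryStats) -> dict:
    """Welch two-sample t-test from group summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), Welch-
    Satterthwaite df, two-sided p.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValidationError("both SDs are zero; t undefined")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def yates_chi2(table: np.ndarray) -> dict:
    """Chi-square test with Yates continuity correction on a 2x2 table.

    chi2 = sum (|O - E| - 0.5)^2 / E with the correction term floored at 0
    when |O - E| < 0.5; df = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValidationError("negative cell counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero margin in contingency table")
    res = stats.chi2_contingency(table, correction=True)
    return {"chi2": float(res.statistic), "df": 1, "p": float(res.pvalue)}


def _split_groups(values: np.ndarray, groups: Sequence) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValidationError("values and groups lengths differ")
    labels = pd.unique(groups)
    return [values[groups == g] for g in labels], labels


def oneway_anova(values: np.ndarray, groups: Sequence) -> dict:
    """Standard one-way ANOVA decomposition: F with (k-1, n-k) df."""
    samples, labels = _split_groups(values, groups)
    k = len(samples)
    if k < 2:
        raise ValidationError("need >= 2 groups")
    n = sum(s.size for s in samples)
    if n - k < 1:
        raise ValidationError("zero within-group degrees of freedom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warning when F = 0
        F, p = stats.f_oneway(*samples)
    if not np.isfinite(F):  # all values identical in every group
        F, p = 0.0, 1.0
    return {"F": float(F), "df_between": k - 1, "df_within": n - k, "p": float(p)}


def tukey_hsd(values: np.ndarray, groups: Sequence, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p)."""
    samples, labels = _split_groups(values, groups)
    if len(samples) < 2:
        raise ValidationError("need >= 2 groups")
    n = sum(s.size for s in samples)
    if n - len(samples) < 1:
        raise ValidationError("zero within-group degrees of freedom")
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append({
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": float(min(1.0, res.pvalue[i, j])),
                "significant": bool(res.pvalue[i, j] <= alpha),
            })
    return pd.DataFrame(rows)


def _records_frame(records: Iterable) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([
            r.__dict__ if isinstance(r, StrategyRecord) else dict(r) for r in records
        ])
    needed = {"outcome", "metric", "correction", "smoothing_or_parcellation", "r"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"strategy records missing fields: {sorted(missing)}")
    return df


def compare_strategies(records: Iterable, alpha: float = 0.05) -> dict:
    """The three-hypothesis comparison of strategies on their r values.

    1. outcome: are correlations with LV and EDSS different? (skipped with a
       warning if only one outcome is present);
    2. approach: does the GM metric (MAP vs each standard metric) matter?
       Tukey HSD follows a significant ANOVA;
    3. smoothing/parcellation: none (0) vs any (> 0), tested separately
       within the standard approaches and within MAP.

    Returns a dict of ANOVA results plus a ranked table in the strategy-table
    layout (sorted by r, descending).
    """
    df = _records_frame(records)

    report: dict = {"ranked": df.sort_values("r", ascending=False).reset_index(drop=True)}

    # (1) outcome factor
    outcomes = df["outcome"].unique()
    if len(outcomes) < 2:
        warnings.warn(f"only one outcome present ({outcomes.tolist()}); "
                      "outcome hypothesis skipped")
        report["outcome_anova"] = None
    else:
        report["outcome_anova"] = oneway_anova(df["r"].to_numpy(), df["outcome"])
        means = df.groupby("outcome")["r"].mean()
        report["outcome_means"] = means.to_dict()

    # (2) approach factor (metric labels; MAP must be contrasted with >= 1 standard)
    metrics = df["metric"].unique().tolist()
    if "MAP" not in metrics or len(metrics) < 2:
        raise ValidationError(
            f"approach comparison needs MAP plus >= 1 standard metric; got {metrics}"
        )
    report["approach_anova"] = oneway_anova(df["r"].to_numpy(), df["metric"])
    if report["approach_anova"]["p"] <= alpha:
        report["approach_tukey"] = tukey_hsd(df["r"].to_numpy(), df["metric"], alpha)
    else:
        report["approach_tukey"] = None

    # (3) smoothing (standard) / parcellation (MAP): none vs any
    def none_vs_any(sub: pd.DataFrame, label: str):
        levels = (sub["smoothing_or_parcellation"] > 0)
        if levels.nunique() < 2:
            warnings.warn(f"{label}: only one level present; skipped")
            return None
        return oneway_anova(sub["r"].to_numpy(),
                            np.where(levels, "any", "none"))

    report["smoothing_anova"] = none_vs_any(df[df["metric"] != "MAP"], "smoothing")
    report["parcellation_anova"] = none_vs_any(df[df["metric"] == "MAP"], "parcellation")
    return report
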