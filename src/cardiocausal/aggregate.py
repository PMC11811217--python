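"""Subject-level aggregation of beat series and significance screening.

Beat-by-beat features are time series; collapsing each of the 205 features
to six statistical metrics per subject - standard deviation, range, mean,
quartile deviation, coefficient of variation, median - retains the temporal
variability information while producing one fixed-length summary row per
subject (the 205 x 6 feature matrix).

Screening then keeps, per metric, only the features that differ
significantly between hypertensive and normotensive subjects (two-sample
test, default Mann-Whitney U), ranked by ascending p-value and capped at
50 - the input size causal graph construction can afford.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METRICS",
    "SubjectFeatureSummary",
    "ScreenResult",
    "aggregate_subject",
    "aggregate_cohort",
    "screen_features",
    "summary_column",
]

log = logging.getLogger(__name__)

METRICS: tuple[str, ...] = ("sd", "range", "mean", "qd", "cv", "median")

#: |mean| below which the coefficient of variation is undefined
CV_MEAN_EPS = 1e-9


def summary_column(metric: str, feature: str) -> str:
    """Column id of a metric-qualified feature, e.g. ``sd__f052``."""
    return f"{metric}__{feature}"


def split_summary_column(col: str) -> tuple[str, str]:
    metric, feature = col.split("__", 1)
    return metric, feature


@dataclass
class SubjectFeatureSummary:
    """205 x 6 statistical summary of one subject's valid beats."""

    subject_id: str
    metrics: pd.DataFrame  # index: feature column id; columns: METRICS
    n_valid_beats: int
    label: int


def _metric_table(values: pd.DataFrame) -> pd.DataFrame:
    """Six metrics per column of a beats x features frame (NaN-aware)."""
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
        rng = np.nanmax(arr, axis=0) - np.nanmin(arr, axis=0)
        q1 = np.nanquantile(arr, 0.25, axis=0)  # linear-interpolation quantiles
        q3 = np.nanquantile(arr, 0.75, axis=0)
        med = np.nanmedian(arr, axis=0)
    qd = (q3 - q1) / 2.0
    cv = np.divide(
        sd, mean, out=np.full_like(sd, np.nan), where=np.abs(mean) > CV_MEAN_EPS
    )
    return pd.DataFrame(
        {"sd": sd, "range": rng, "mean": mean, "qd": qd, "cv": cv, "median": med},
        index=values.columns,
    )


def aggregate_subject(
    beats: pd.DataFrame,
    subject_id: str,
    label: int,
    min_beats: int = 10,
) -> SubjectFeatureSummary:
    """Collapse one subject's valid-beat feature rows to the 205 x 6 table.

    SD uses the sample (n-1) denominator; the quartile deviation is
    (Q3 - Q1)/2 with linear-interpolation quantiles; CV = SD/mean is left
    missing where the mean is (near) zero.  Subjects with fewer than
    ``min_beats`` beats are rejected.
    """
    feats = beats[[c for c in beats.columns if c.startswith("f")]]
    if len(feats) < min_beats:
        raise ValueError(
            f"subject {subject_id}: only {len(feats)} valid beats "
            f"(minimum {min_beats})"
        )
    return SubjectFeatureSummary(
        subject_id=subject_id,
        metrics=_metric_table(feats),
        n_valid_beats=len(feats),
        label=int(label),
    )


def aggregate_cohort(
    beat_table: pd.DataFrame,
    labels: pd.Series,
    min_beats: int = 10,
) -> pd.DataFrame:
    """Wide per-subject summary matrix for a tidy beat-feature table.

    Returns one row per retained subject with columns ``metric__fNNN`` plus
    ``label`` and ``n_valid_beats``; under-sampled subjects are dropped with
    a log entry.
    """
    rows = []
    for sid, sub in beat_table.groupby("subject_id", sort=True):
        try:
            summ = aggregate_subject(sub, str(sid), int(labels.loc[sid]), min_beats)
        except ValueError as err:
            log.warning("excluding subject: %s", err)
            continue
        row: dict = {"subject_id": summ.subject_id, "label": summ.label,
                     "n_valid_beats": summ.n_valid_beats}
        for metric in METRICS:
            for feat, val in summ.metrics[metric].items():
                row[summary_column(metric, feat)] = val
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


@dataclass
class ScreenResult:
    """Outcome of significance screening under one statistical metric."""

    metric: str
    alpha: float
    cap: int
    p_values: pd.Series  # per tested feature column
    retained: list[str] = field(default_factory=list)  # ascending p, <= cap

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "feature": self.p_values.index,
                "p": self.p_values.values,
                "retained": [f in set(self.retained) for f in self.p_values.index],
            }
        )


def screen_features(
    summaries: pd.DataFrame,
    labels: pd.Series,
    metric: str,
    alpha: float = 0.05,
    cap: int = 50,
    test: str = "mannwhitney",
    fdr: bool = False,
) -> ScreenResult:
    """Two-sample screen of every feature under one metric.

    Parameters
    ----------
    summaries:
        Wide summary matrix (rows: subjects, columns ``metric__fNNN``).
    labels:
        Binary series aligned to ``summaries``' index; both classes required
        with at least three subjects each.
    test:
        ``"mannwhitney"`` (exact for small tie-free groups, normal
        approximation with tie correction otherwise) or ``"ttest"`` (Welch).
    fdr:
        Apply Benjamini-Hochberg correction to the p-values before the
        alpha cut.

    Features with degenerate (constant or all-missing) group values are
    excluded.  Survivors are ranked by ascending p and truncated to ``cap``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if test not in ("mannwhitney", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    y = labels.loc[summaries.index].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present for screening")
    if min((y == c).sum() for c in classes) < 3:
        raise ValueError("need at least 3 subjects per class")
    cols = [c for c in summaries.columns if c.startswith(f"{metric}__")]
    pvals: dict[str, float] = {}
    for col in cols:
        v = summaries[col].to_numpy(dtype=float)
        g1 = v[(y == 1) & np.isfinite(v)]
        g0 = v[(y == 0) & np.isfinite(v)]
        if len(g1) < 3 or len(g0) < 3 or (np.ptp(np.concatenate([g0, g1])) == 0):
            pvals[col] = np.nan  # degenerate: excluded
            continue
        if test == "mannwhitney":
            res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method="auto")
        else:
            res = stats.ttest_ind(g1, g0, equal_var=False)
        pvals[col] = float(res.pvalue)
    p = pd.Series(pvals, name="p")
    p_eff = p.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        finite = p.dropna()
        adj = multipletests(finite.values, method="fdr_bh")[1]
        p_eff.loc[finite.index] = adj
    survivors = p_eff[(p_eff < alpha) & p_eff.notna()].sort_values(kind="mergesort")
    retained = list(survivors.index[:cap])
    return ScreenResult(metric=metric, alpha=alpha, cap=cap, p_values=p, retained=retained)
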