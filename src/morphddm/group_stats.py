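"""Group-level statistics on fitted DDM metrics.

Covers the dimensional analysis (Pearson correlations between each
computational metric and child-/parent-rated anxiety and irritability,
Bonferroni corrected over the emitted family), the diagnostic analysis
(one-way ANOVA across primary-diagnosis groups with Bonferroni-corrected
pooled-SD post hoc pairwise t tests), and the age--sensitivity replication
(patients only; healthy participants are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "pearson_bonferroni",
    "metric_clinical_correlations",
    "oneway_anova",
    "pairwise_t_bonferroni",
    "replicate_age_sensitivity",
]

#: Default metric columns for the correlation table.
DEFAULT_METRICS = ("sensitivity", "perceptual_bias")
#: Default clinical columns (measure x informant).
DEFAULT_MEASURES = ("scared_child", "scared_parent", "ari_child", "ari_parent")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with Bonferroni adjustment over a stated family."""

    r: float
    df: int
    p_raw: float
    p_adj: float
    n_family: int
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def pearson_bonferroni(x, y, n_family: int = 1) -> CorrelationResult:
    """Pearson r on pairwise-complete observations, with ``p_adj =
    min(1, p_raw * n_family)``.

    Raises on a constant column (undefined correlation) or fewer than 3
    complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), df=n - 2, p_raw=float(p), p_adj=_bonferroni(p, n_family),
        n_family=n_family, n=n,
    )


def metric_clinical_correlations(
    cohort: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    measures: Sequence[str] = DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Metric x clinical-measure correlation table (one row per cell).

    The Bonferroni family is the full set of emitted cells
    (``len(metrics) * len(measures)``); the family size is reported in the
    table so the correction is auditable.  Deletion is pairwise-complete.
    """
    n_family = len(metrics) * len(measures)
    rows = []
    for metric in metrics:
        for measure in measures:
            res = pearson_bonferroni(cohort[metric], cohort[measure], n_family)
            rows.append({
                "metric": metric, "measure": measure,
                "r": res.r, "df": res.df, "n": res.n,
                "p_raw": res.p_raw, "p_adj": res.p_adj, "n_family": res.n_family,
            })
    return pd.DataFrame(rows)


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[str(g)] = values[groups == g]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in out.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return out


def oneway_anova(values, groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df1, df2, p).

    Between/within sums-of-squares decomposition with ``df1 = k - 1``,
    ``df2 = N - k``.  Listwise deletion of non-finite values.  All values
    identical makes F the degenerate 0/0, returned as NaN with p = NaN.
    """
    by_group = _group_arrays(values, groups)
    all_vals = np.concatenate(list(by_group.values()))
    k = len(by_group)
    n_tot = len(all_vals)
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in by_group.values())
    df1, df2 = k - 1, n_tot - k
    if ss_within == 0 and ss_between == 0:
        return np.nan, df1, df2, np.nan  # flagged degenerate: no variance at all
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        return np.inf, df1, df2, 0.0
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def pairwise_t_bonferroni(
    values, groups, pooled: bool = True
) -> pd.DataFrame:
    """All pairwise two-sample t tests between groups, Bonferroni corrected
    over the ``k*(k-1)/2`` pairs.

    ``pooled=True`` (the classical post hoc convention) uses the common
    within-group SD from the ANOVA decomposition with ``df = N - k``;
    ``pooled=False`` gives Welch tests with Satterthwaite df.
    """
    by_group = _group_arrays(values, groups)
    names = list(by_group)
    k = len(names)
    m = k * (k - 1) // 2
    n_tot = sum(len(v) for v in by_group.values())
    ms_within = (
        sum(float(np.sum((v - v.mean()) ** 2)) for v in by_group.values())
        / (n_tot - k)
    )
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = by_group[names[i]], by_group[names[j]]
            diff = a.mean() - b.mean()
            if pooled:
                se = np.sqrt(ms_within * (1.0 / len(a) + 1.0 / len(b)))
                df = n_tot - k
            else:
                va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
                se = np.sqrt(va + vb)
                df = (va + vb) ** 2 / (
                    va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
                )
            t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                "t": float(t), "df": float(df),
                "p_raw": p, "p_adj": _bonferroni(p, m), "n_comparisons": m,
            })
    return pd.DataFrame(rows)


def replicate_age_sensitivity(
    cohort: pd.DataFrame,
    healthy_label: str = "Healthy",
    n_family: int = 1,
) -> CorrelationResult:
    """Age--sensitivity Pearson correlation in the patient subsample.

    Healthy participants are excluded before computing the correlation (the
    replication concerns patients only); the reported ``n`` reflects the
    retained rows.
    """
    if "diagnosis" not in cohort.columns:
        raise ValueError("cohort must carry a 'diagnosis' column")
    patients = cohort[cohort["diagnosis"] != healthy_label]
    if len(patients) < 3:
        raise ValueError("need at least 3 patient rows")
    return pearson_bonferroni(patients["age"], patients["sensitivity"], n_family)
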