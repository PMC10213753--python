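"""Cohort summaries and nonparametric comparison of segmentation arms.

Per-case Dice/HD/FD records are summarized per group by the median
(accompanied by the standard deviation, explicitly labeled — published
"median ± value" tables rarely define the ±).  Arms are compared with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test: exact enumeration of all
rank assignments for small tie-free samples (n1 + n2 ≤ 12), a normal
approximation with tie and continuity correction otherwise.  Multiple
comparisons use Bonferroni's threshold alpha / m; with the conventional
alpha = 0.05 and m = 6 comparisons this is the familiar 0.008 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd

from .metrics import MetricRecord

METRIC_NAMES = ("dice", "hausdorff", "frechet")
EXACT_LIMIT = 12


@dataclass
class CohortSummary:
    comparison: str
    region: str
    metric: str
    median: float
    dispersion: float  # standard deviation, labeled explicitly
    n: int


@dataclass
class ComparisonReport:
    rows: pd.DataFrame
    alpha: float
    m: int
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.threshold = bonferroni_threshold(self.alpha, self.m)


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        if isinstance(r, MetricRecord):
            rows.append(
                {
                    "case_id": r.case_id,
                    "region": r.region,
                    "comparison": r.comparison,
                    "dice": r.dice,
                    "hausdorff": r.hausdorff,
                    "frechet": r.frechet,
                    "n_slices_evaluated": r.n_slices_evaluated,
                }
            )
        else:
            rows.append(dict(r))
    return pd.DataFrame(rows)


def summarize_cohort(records, group_keys=("comparison", "region")) -> list[CohortSummary]:
    """Median and dispersion of each metric per group of records."""
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    group_keys = [k for k in group_keys if k in df.columns]
    out = []
    grouped = df.groupby(group_keys, sort=True, dropna=False) if group_keys else [((), df)]
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(group_keys, key))
        for metric in METRIC_NAMES:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            # distances can be NaN for every case of a group (e.g. an empty
            # prediction has no boundary): summarize as NaN rather than fail
            out.append(
                CohortSummary(
                    comparison=str(info.get("comparison", "")),
                    region=str(info.get("region", "")),
                    metric=metric,
                    median=float(np.median(vals)) if len(vals) else float("nan"),
                    dispersion=float(np.std(vals)) if len(vals) else float("nan"),
                    n=int(len(vals)),
                )
            )
    return out


def ranksum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of all C(n1+n2, n1) rank assignments when
    n1 + n2 <= 12 and there are no ties; otherwise the normal approximation
    with tie correction and a 0.5 continuity correction.  Symmetric in
    (a, b).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    if has_ties:  # midranks
        sorted_vals = pooled[order]
        i = 0
        while i < n:
            j = i
            while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n + 1) / 2.0

    if n <= EXACT_LIMIT and not has_ties:
        ranks_all = np.arange(1, n + 1)
        dev = abs(w - mean_w)
        count = sum(
            1
            for idx in combinations(range(n), n1)
            if abs(ranks_all[list(idx)].sum() - mean_w) >= dev - 1e-9
        )
        return count / comb(n, n1)

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 1.0
    z = max(abs(w - mean_w) - 0.5, 0.0) / sqrt(var_w)
    return min(erfc(z / sqrt(2.0)), 1.0)


def bonferroni_threshold(alpha: float, m: int) -> float:
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def compare_models(records_a, records_b, alpha: float = 0.05, m: int = 6,
                   label_a: str = "a", label_b: str = "b") -> ComparisonReport:
    """Per region and metric: summaries of both arms, rank-sum p-value and a
    Bonferroni significance flag at threshold alpha / m."""
    df_a = records_to_frame(records_a)
    df_b = records_to_frame(records_b)
    regions_a = sorted(df_a["region"].unique())
    regions_b = sorted(df_b["region"].unique())
    if regions_a != regions_b:
        raise ValueError(f"region sets differ: {regions_a} vs {regions_b}")
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for region in regions_a:
        sa = df_a[df_a["region"] == region]
        sb = df_b[df_b["region"] == region]
        for metric in METRIC_NAMES:
            va = sa[metric].to_numpy(dtype=float)
            vb = sb[metric].to_numpy(dtype=float)
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            # an arm can have no finite distances (all predictions empty);
            # the comparison is then undefined rather than an error
            p = ranksum_test(va, vb) if len(va) and len(vb) else float("nan")
            rows.append(
                {
                    "region": region,
                    "metric": metric,
                    f"median_{label_a}": float(np.median(va)) if len(va) else float("nan"),
                    f"sd_{label_a}": float(np.std(va)) if len(va) else float("nan"),
                    f"n_{label_a}": len(va),
                    f"median_{label_b}": float(np.median(vb)) if len(vb) else float("nan"),
                    f"sd_{label_b}": float(np.std(vb)) if len(vb) else float("nan"),
                    f"n_{label_b}": len(vb),
                    "p_value": p,
                    "significant": bool(p < threshold) if np.isfinite(p) else False,
                }
            )
    return ComparisonReport(rows=pd.DataFrame(rows), alpha=alpha, m=m)
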