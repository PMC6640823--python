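"""Cohort statistics: AMC-vs-MI group comparisons.

The unit of analysis is the animal: the 3 positions x 3 repeats acquired
per region of interest (ROI) are averaged to one value per animal before
testing, avoiding pseudo-replication.  Groups are compared with Welch's
unequal-variance t-test, corrected for multiple comparisons with the
step-down Holm-Sidak procedure, and effect sizes are reported as Cohen's d
(pooled-SD standardised mean difference).

Sign convention: t and d are computed as MI minus AMC, so a positive value
means the MI group is larger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "aggregate_animal",
    "welch_t",
    "welch_t_from_stats",
    "holm_sidak_adjust",
    "cohen_d",
    "cohen_d_from_stats",
    "stars",
    "compare_groups",
]

log = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class ComparisonResult:
    parameter: str
    roi: str
    week: int
    n_amc: int
    n_mi: int
    mean_amc: float
    sd_amc: float
    mean_mi: float
    sd_mi: float
    t_stat: float
    df_welch: float
    p_raw: float
    p_adj: float
    cohen_d: float
    stars: str


def aggregate_animal(values) -> float:
    """Mean of the per-measurement values of one animal/ROI/parameter."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no measurements to aggregate")
    return float(arr.mean())


def welch_t_from_stats(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> tuple[float, float, float]:
    """Welch's t-test from summary statistics -> (t, df, two-sided p)."""
    if n_x < 2 or n_y < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = sd_x**2 / n_x, sd_y**2 / n_y
    se2 = vx + vy
    if se2 == 0:
        if mean_x == mean_y:
            return 0.0, float(n_x + n_y - 2), 1.0
        t = np.inf if mean_x > mean_y else -np.inf
        return float(t), float(n_x + n_y - 2), 0.0
    t = (mean_x - mean_y) / np.sqrt(se2)
    df = se2**2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test -> (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, in the original order.

    Sorted ascending, p_adj(i) = 1 - (1 - p_(i))^(m - i + 1) with
    monotonicity enforced down the sorted list and capping at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)
    adj = 1.0 - (1.0 - p[order]) ** exponents
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def cohen_d_from_stats(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> float:
    if n_x < 2 or n_y < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(
        ((n_x - 1) * sd_x**2 + (n_y - 1) * sd_y**2) / (n_x + n_y - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((mean_x - mean_y) / pooled)


def cohen_d(x, y) -> float:
    """Cohen's d standardised mean difference with pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return cohen_d_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def stars(p_adj: float) -> str:
    """Significance notation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for thr, s in STAR_THRESHOLDS:
        if p_adj < thr:
            return s
    return "ns"


def compare_groups(
    records: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "roi_parameter",
) -> pd.DataFrame:
    """AMC-vs-MI comparisons at every (parameter, ROI, week).

    ``records`` is a tidy long table with columns animal_id, group
    (AMC/MI), week, roi, parameter, value; repeated measurements per animal
    (position/repeat) are averaged to animal level first.

    ``family`` controls the Holm-Sidak family:
      - "roi_parameter": the comparisons across weeks of one parameter
        within one ROI (default; m = number of weeks present)
      - "all": one family over every comparison
      - "none": no adjustment
    Comparisons with a missing group or n < 2 are skipped with a warning.
    """
    required = {"animal_id", "group", "week", "roi", "parameter", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if family not in ("roi_parameter", "all", "none"):
        raise ValueError(f"unknown family policy {family!r}")

    per_animal = (
        records.groupby(
            ["parameter", "roi", "week", "group", "animal_id"], sort=True
        )["value"]
        .mean()
        .reset_index()
    )
    rows: list[ComparisonResult] = []
    for (param, roi, week), sub in per_animal.groupby(
        ["parameter", "roi", "week"], sort=True
    ):
        x = sub.loc[sub["group"] == "MI", "value"].to_numpy()
        y = sub.loc[sub["group"] == "AMC", "value"].to_numpy()
        if x.size < 2 or y.size < 2:
            log.warning(
                "skipping %s/%s week %s: AMC n=%d, MI n=%d",
                param, roi, week, y.size, x.size,
            )
            continue
        t, df, p = welch_t(x, y)
        rows.append(
            ComparisonResult(
                parameter=param, roi=roi, week=int(week),
                n_amc=int(y.size), n_mi=int(x.size),
                mean_amc=float(y.mean()), sd_amc=float(y.std(ddof=1)),
                mean_mi=float(x.mean()), sd_mi=float(x.std(ddof=1)),
                t_stat=t, df_welch=df, p_raw=p, p_adj=np.nan,
                cohen_d=cohen_d(x, y), stars="",
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    if out.empty:
        return out
    if family == "none":
        out["p_adj"] = out["p_raw"]
    elif family == "all":
        out["p_adj"] = holm_sidak_adjust(out["p_raw"].to_numpy())
    else:
        for _, idx in out.groupby(["roi", "parameter"]).groups.items():
            out.loc[idx, "p_adj"] = holm_sidak_adjust(
                out.loc[idx, "p_raw"].to_numpy()
            )
    out["stars"] = [stars(p) for p in out["p_adj"]]
    return out.sort_values(["parameter", "roi", "week"]).reset_index(drop=True)
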