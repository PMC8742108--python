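"""Group-difference and clinicopathological-association statistics.

Covers the testing layer of a marker study: median (range) summaries per
group, normal-approximation rank-sum Z with midranks and tie correction,
tie-corrected Kruskal-Wallis H, Welch t / one-way ANOVA association of a
marker with a clinical covariate, and the two-tailed p = 2(1 - Phi(|Z|))
arithmetic that pairs a printed Z value with its p.  No multiplicity
correction is applied anywhere; each comparison stands on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    statistic_name: str
    statistic: float
    p_value: float
    summaries: pd.DataFrame  # one row per group/level

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def summarize_median_range(
    values_by_group: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Per-group (median, min, max, n); midpoint median convention for even n."""
    rows = {}
    for g, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
        rows[g] = {
            "median": float(np.median(arr)),
            "min": float(arr.min()),
            "max": float(arr.max()),
            "n": int(arr.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def two_tailed_p_from_z(z):
    """p = 2 (1 - Phi(|z|)), the two-tailed normal tail for a printed Z."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    p = 2.0 * sps.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def ranksum_z(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparisonResult:
    """Normal-approximation Wilcoxon rank-sum Z with midranks and tie correction.

    Z > 0 when group_a tends to exceed group_b; swapping the groups flips
    the sign.  p via ``two_tailed_p_from_z``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    r_a = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var <= 0 else (r_a - mu) / np.sqrt(var)
    return GroupComparisonResult(
        "ranksum_Z",
        float(z),
        two_tailed_p_from_z(z),
        summarize_median_range({"a": a, "b": b}),
    )


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparisonResult:
    """Unequal-variance two-sample t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 samples")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        t, p = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparisonResult(
        "t", float(t), float(p), summarize_median_range({"a": a, "b": b})
    )


def kruskal_wallis(
    values_by_group: Mapping[str, Sequence[float]]
) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H; chi-square p on |groups| - 1 df."""
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(v.size == 0 for v in groups.values()):
        raise ValueError(">= 2 non-empty groups required")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups.values())
    return GroupComparisonResult(
        "kruskal_wallis_H", float(h), float(p), summarize_median_range(groups)
    )


def covariate_association(
    table: pd.DataFrame, marker: str, covariate: str
) -> GroupComparisonResult:
    """Association of a marker with a clinical covariate.

    Two levels: unequal-variance t; three or more: one-way ANOVA F.
    Levels with fewer than 2 samples are dropped with a warning.  The
    summaries report per-level mean and SD.
    """
    sub = table[[marker, covariate]].dropna()
    levels: dict[str, np.ndarray] = {}
    for level, chunk in sub.groupby(covariate, observed=True):
        vals = chunk[marker].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(
                f"covariate {covariate!r} level {level!r} has < 2 samples; dropped",
                stacklevel=2,
            )
            continue
        levels[str(level)] = vals
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} needs >= 2 usable levels")

    summaries = pd.DataFrame(
        {
            level: {
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "n": int(v.size),
            }
            for level, v in levels.items()
        }
    ).T
    arrays = list(levels.values())
    if len(arrays) == 2:
        res = welch_t(arrays[0], arrays[1])
        return GroupComparisonResult("t", res.statistic, res.p_value, summaries)
    if np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*arrays)
        if np.isnan(f):
            f, p = 0.0, 1.0
    return GroupComparisonResult("F_anova", float(f), float(p), summaries)


def marker_group_stats(table: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    """Kruskal-Wallis across the four cohort groups plus median (range) per marker.

    One tidy row per marker, mirroring a per-protein summary table.
    """
    rows = []
    for m in markers:
        by_group = {
            g: chunk[m].to_numpy(dtype=float)
            for g, chunk in table.groupby("group", observed=True)
            if len(chunk)
        }
        res = kruskal_wallis(by_group)
        row = {"marker": m, "H": res.statistic, "p": res.p_value}
        for g, s in res.summaries.iterrows():
            row[f"{g}_median"] = s["median"]
            row[f"{g}_min"] = s["min"]
            row[f"{g}_max"] = s["max"]
            row[f"{g}_n"] = s["n"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")
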