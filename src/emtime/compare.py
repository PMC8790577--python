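"""Per-marker contrasts between EMT groups.

For every TIME marker within a cohort this module computes the
"landscape" statistics behind the heatmap-style summaries:

* delta median — median(EMT-high) − median(EMT-low), in the marker's
  native units;
* two-sample Kolmogorov–Smirnov test of EMT-high vs EMT-low;
* one-way ANOVA across the three EMT groups;
* Spearman rank correlation of the marker with the continuous EMT score.

Markers with insufficient or degenerate data carry explicit missing
fields in their :class:`ContrastResult` rather than being dropped.
P-values are reported raw (no multiple-testing correction by default,
matching the p<0.05/0.01/0.001 banding convention); Benjamini–Hochberg
across a landscape is available via :func:`adjust_landscape_bh`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import (EMTScoreTable, GroupAssignment, GROUP_HIGH,
                      GROUP_INTERMEDIATE, GROUP_LOW)
from .signatures import TimeMarkerTable

__all__ = [
    "ContrastResult",
    "ks_two_sample",
    "anova_one_way",
    "correlate_with_emt",
    "build_landscape",
    "landscape_frame",
    "adjust_landscape_bh",
    "p_to_band",
]

_EXACT_KS_LIMIT = 10_000  # n*m at or below this -> exact KS p-value


@dataclass(frozen=True)
class ContrastResult:
    """All group-contrast statistics for one marker in one cohort.

    Fields are NaN where the underlying test could not be run (e.g. a
    constant marker has no defined rank correlation); ``notes`` records
    why.
    """

    cohort_id: str
    marker: str
    category: str
    delta_median: float
    ks_stat: float
    ks_p: float
    anova_f: float
    anova_p: float
    corr_rho: float
    corr_p: float
    n_high: int
    n_int: int
    n_low: int
    notes: str = ""


def ks_two_sample(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum over t of |ECDF_x(t) − ECDF_y(t)|.  With
    ``method="auto"`` the p-value is exact when n·m ≤ 10,000 and from the
    asymptotic Kolmogorov distribution otherwise; ``"exact"`` and
    ``"asymp"`` force either branch.  Each vector needs ≥ 3 non-missing
    values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"KS test needs >= 3 values per group, have {len(x)} and {len(y)}"
        )
    if method == "auto":
        method = "exact" if len(x) * len(y) <= _EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def anova_one_way(*groups) -> tuple[float, float]:
    """Standard fixed-effects one-way ANOVA F test, df (k−1, N−k).

    Each group needs ≥ 2 values; an all-constant input (zero pooled
    within-group variance) leaves F undefined and raises.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[~np.isnan(a)] for a in arrs]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    sizes = [len(a) for a in arrs]
    if min(sizes) < 2:
        raise ValueError(f"every group needs >= 2 values, sizes are {sizes}")
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within <= 0.0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def correlate_with_emt(scores: EMTScoreTable, marker_values: pd.Series,
                       method: str = "spearman") -> tuple[float, float]:
    """Correlation of a marker with the continuous EMT score.

    Spearman rank correlation by default (robust to the heavy right tails
    of enrichment scores), with the asymptotic t-approximation p-value;
    ``method="pearson"`` is available.  Pairs with a missing value on
    either side are excluded; ≥ 4 complete pairs are required and a
    constant marker is an error ("degenerate marker").
    """
    paired = pd.concat([scores.score, marker_values], axis=1, join="inner").dropna()
    if len(paired) < 4:
        raise ValueError(f"need >= 4 paired observations, have {len(paired)}")
    s, m = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
    if np.all(m == m[0]):
        raise ValueError("degenerate marker: constant across samples")
    if method == "spearman":
        rho, p = stats.spearmanr(s, m)
    elif method == "pearson":
        rho, p = stats.pearsonr(s, m)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


def p_to_band(p: float) -> str:
    """Map a p-value to its significance band: ``***`` p<0.001, ``**``
    0.001≤p<0.01, ``*`` 0.01≤p<0.05, ``NS`` otherwise."""
    if isinstance(p, float) and math.isnan(p):
        return "NA"
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def build_landscape(time: TimeMarkerTable, groups: GroupAssignment,
                    scores: EMTScoreTable) -> list[ContrastResult]:
    """Contrast every marker between EMT groups; one result per marker.

    Markers whose data cannot support a given test get NaN for that
    statistic and a note; no marker is silently omitted.
    """
    shared = [s for s in time.samples if s in set(groups.samples)]
    if not shared:
        raise ValueError("no samples shared between marker table and groups")
    grp = groups.group.loc[shared]
    idx = {g: grp.index[grp == g] for g in (GROUP_HIGH, GROUP_INTERMEDIATE, GROUP_LOW)}

    results: list[ContrastResult] = []
    for marker in time.markers:
        row = time.values.loc[marker, shared]
        hi = row.loc[idx[GROUP_HIGH]].dropna().to_numpy(dtype=float)
        md = row.loc[idx[GROUP_INTERMEDIATE]].dropna().to_numpy(dtype=float)
        lo = row.loc[idx[GROUP_LOW]].dropna().to_numpy(dtype=float)
        notes = []

        delta = (float(np.median(hi)) - float(np.median(lo))
                 if len(hi) and len(lo) else float("nan"))
        if not (len(hi) and len(lo)):
            notes.append("empty high or low group")

        try:
            ks_d, ks_p = ks_two_sample(hi, lo)
        except ValueError as e:
            ks_d = ks_p = float("nan")
            notes.append(f"KS: {e}")
        try:
            f, anova_p = anova_one_way(hi, md, lo)
        except ValueError as e:
            f = anova_p = float("nan")
            notes.append(f"ANOVA: {e}")
        try:
            rho, corr_p = correlate_with_emt(scores, row)
        except ValueError as e:
            rho = corr_p = float("nan")
            notes.append(f"correlation: {e}")

        results.append(ContrastResult(
            cohort_id=scores.cohort_id,
            marker=marker,
            category=str(time.category.loc[marker]),
            delta_median=delta,
            ks_stat=ks_d, ks_p=ks_p,
            anova_f=f, anova_p=anova_p,
            corr_rho=rho, corr_p=corr_p,
            n_high=len(hi), n_int=len(md), n_low=len(lo),
            notes="; ".join(notes),
        ))
    return results


def landscape_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate contrast results with significance bands, one row per marker."""
    df = pd.DataFrame([vars(r) for r in results]).set_index("marker")
    for col in ("ks_p", "anova_p", "corr_p"):
        df[col.replace("_p", "_band")] = df[col].map(p_to_band)
    return df


def adjust_landscape_bh(results: list[ContrastResult]) -> list[ContrastResult]:
    """Benjamini–Hochberg adjust KS, ANOVA and correlation p-values across
    the markers of one landscape (optional; raw p is the default report)."""
    out = [vars(r).copy() for r in results]
    for field_name in ("ks_p", "anova_p", "corr_p"):
        ps = np.array([r[field_name] for r in out], dtype=float)
        ok = ~np.isnan(ps)
        if ok.sum():
            adj = stats.false_discovery_control(ps[ok], method="bh")
            ps[ok] = adj
        for r, p in zip(out, ps):
            r[field_name] = float(p)
    return [ContrastResult(**r) for r in out]
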