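"""Multivariate views of the EMT–TIME landscape.

Two profile matrices feed this module:

* the **median profile matrix** — one row per (cohort, EMT group), one
  column per TIME marker, each cell the group median of that marker; PCA
  of this matrix shows whether a cohort's three EMT groups share a
  microenvironment or diverge;
* the **delta profile matrix** — one row per cohort, each cell
  median(high) − median(low); PCA plus K-means with silhouette-selected K
  classifies cancers by how inhibitory their EMT-high microenvironment is
  relative to EMT-low.

Markers live on incommensurate scales (enrichment scores vs z-scores), so
columns are standardized before PCA by default; raw-covariance PCA is one
flag away.  "High expression" for the conditional-probability table is
value ≥ the pooled median by default (configurable to any quantile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .scoring import (GroupAssignment, GROUP_HIGH, GROUP_INTERMEDIATE,
                      GROUP_LOW)
from .signatures import TimeMarkerTable

__all__ = [
    "PCAResult",
    "ClusterResult",
    "ConditionalProbRow",
    "build_median_profiles",
    "build_delta_profiles",
    "run_pca",
    "top_contributors",
    "conditional_prob_high",
    "conditional_prob_frame",
    "kmeans_with_silhouette",
]

GROUP_ORDER = (GROUP_LOW, GROUP_INTERMEDIATE, GROUP_HIGH)


@dataclass
class PCAResult:
    """Scores, loadings, explained variance and marker contributions.

    ``contributions_pct[m, c]`` is 100·loading²/Σloading² — marker m's
    share of component c; each component's contributions sum to 100%, and
    explained-variance percentages sum to 100% over all components.
    """

    scores: pd.DataFrame            # rows x components
    loadings: pd.DataFrame          # markers x components
    explained_variance_pct: pd.Series
    contributions_pct: pd.DataFrame  # markers x components


@dataclass
class ClusterResult:
    k_optimal: int
    assignments: pd.Series           # cohort -> cluster label (at k_optimal)
    silhouette_by_k: dict[int, float]
    inertia_by_k: dict[int, float]


@dataclass(frozen=True)
class ConditionalProbRow:
    marker: str
    group: str
    p_high_given_group: float
    n_high: int
    n_group: int
    threshold_used: float


def build_median_profiles(
    tables: dict[str, TimeMarkerTable],
    groups: dict[str, GroupAssignment],
) -> pd.DataFrame:
    """Per-group marker medians: rows (cohort, group), columns markers.

    Every cohort must have all three EMT groups populated; medians are
    pairwise-complete (NaN cells only where a marker is entirely missing
    in a group).
    """
    rows = {}
    for cohort in tables:
        tab, grp = tables[cohort], groups[cohort]
        shared = [s for s in tab.samples if s in set(grp.samples)]
        g = grp.group.loc[shared]
        for label in GROUP_ORDER:
            members = g.index[g == label]
            if len(members) == 0:
                raise ValueError(f"cohort {cohort}: EMT group {label!r} is empty")
            rows[(cohort, label)] = tab.values[list(members)].median(
                axis=1, skipna=True)
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["cohort", "group"])
    return out


def build_delta_profiles(
    tables: dict[str, TimeMarkerTable],
    groups: dict[str, GroupAssignment],
) -> pd.DataFrame:
    """Per-cohort high-minus-low median differences (cohorts x markers)."""
    med = build_median_profiles(tables, groups)
    hi = med.xs(GROUP_HIGH, level="group")
    lo = med.xs(GROUP_LOW, level="group")
    return hi - lo


def run_pca(matrix: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA via SVD of the column-centered (optionally unit-scaled) matrix.

    Rows with missing cells are dropped with a warning; constant columns
    are left centered-at-zero when standardizing (they carry no variance
    either way).  A matrix with zero total variance is an error.
    """
    X = matrix.dropna(axis=0, how="any")
    if X.shape[0] < len(matrix):
        import logging
        logging.getLogger("emtime").warning(
            "PCA: dropped %d row(s) with missing cells", len(matrix) - X.shape[0])
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"PCA needs >= 2 complete rows and >= 2 columns, "
                         f"have shape {X.shape}")
    arr = X.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    if standardize:
        sd = arr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        arr = arr / sd
    if not np.any(arr):
        raise ValueError("matrix has zero variance after centering")
    pca = PCA(n_components=min(arr.shape), svd_solver="full")
    scores = pca.fit_transform(arr)
    comp_names = [f"PC{i+1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_.T, index=X.columns, columns=comp_names)
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=loadings,
        explained_variance_pct=pd.Series(
            100.0 * pca.explained_variance_ratio_, index=comp_names),
        contributions_pct=contrib,
    )


def top_contributors(pca: PCAResult, n: int, component: str = "PC1") -> list[str]:
    """Markers ranked by contribution to a component, ties alphabetical."""
    if n <= 0:
        raise ValueError("n must be positive")
    contrib = pca.contributions_pct[component]
    if n > len(contrib):
        raise ValueError(f"n={n} exceeds {len(contrib)} markers")
    order = sorted(contrib.index, key=lambda m: (-contrib[m], m))
    return order[:n]


def conditional_prob_high(
    marker_values: pd.Series,
    groups: GroupAssignment,
    threshold: float | None = None,
    quantile: float = 0.5,
) -> list[ConditionalProbRow]:
    """P(marker "high" | EMT group) for each group.

    "High" means value ≥ threshold; the default threshold is the pooled
    quantile (median) over all group-assigned samples with data.  The
    probabilities obey the law of total probability by construction:
    Σ_g P(high|g)·P(g) equals the overall high fraction.
    """
    shared = [s for s in marker_values.index if s in set(groups.samples)]
    vals = marker_values.loc[shared].dropna()
    if threshold is None:
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        threshold = float(np.quantile(vals.to_numpy(), quantile, method="linear"))
    rows = []
    for label in GROUP_ORDER:
        members = [s for s in groups.members(label) if s in vals.index]
        if not members:
            raise ValueError(f"EMT group {label!r} has no samples with data")
        v = vals.loc[members]
        n_high = int((v >= threshold).sum())
        rows.append(ConditionalProbRow(
            marker=str(marker_values.name), group=label,
            p_high_given_group=n_high / len(members),
            n_high=n_high, n_group=len(members),
            threshold_used=threshold,
        ))
    return rows


def conditional_prob_frame(rows: list[ConditionalProbRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def kmeans_with_silhouette(
    matrix: pd.DataFrame,
    k_range: range = range(2, 9),
    restarts: int = 50,
    seed: int = 17,
    standardize: bool = True,
) -> ClusterResult:
    """K-means over a K range; the mean silhouette width picks K.

    Euclidean Lloyd iterations (tolerance 1e-8), best of ``restarts``
    initializations, deterministic given ``seed``.  K values must satisfy
    2 ≤ K ≤ n_rows − 1 so the silhouette is defined.
    """
    if min(k_range) < 2:
        raise ValueError("k_range minimum must be >= 2")
    X = matrix.dropna(axis=0, how="any")
    arr = X.to_numpy(dtype=float)
    if standardize:
        arr = arr - arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        arr = arr / sd
    ks = [k for k in k_range if k <= len(X) - 1]
    if not ks:
        raise ValueError(
            f"no K in {list(k_range)} fits {len(X)} rows (need K <= n-1)")
    sil: dict[int, float] = {}
    inertia: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                    algorithm="lloyd", tol=1e-8)
        labels = km.fit_predict(arr)
        sil[k] = float(silhouette_score(arr, labels, metric="euclidean"))
        inertia[k] = float(km.inertia_)
        labels_by_k[k] = labels
    # argmax on silhouette; ties favour the smaller K
    k_opt = max(sorted(sil), key=lambda k: (sil[k], -k))
    return ClusterResult(
        k_optimal=k_opt,
        assignments=pd.Series(labels_by_k[k_opt], index=X.index, name="cluster"),
        silhouette_by_k=sil,
        inertia_by_k=inertia,
    )
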