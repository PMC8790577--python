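"""EMT scoring and quartile stratification.

The EMT score of a tumor sample is the mean z-score of the mesenchymal
marker genes minus the mean z-score of the epithelial marker genes,
computed over the canonical 16-marker panel (3 epithelial: CDH1, DSP,
TJP1; 13 mesenchymal: VIM, CDH2, FOXC2, SNAI1, SNAI2, TWIST1, GSC, FN1,
ITGB6, MMP2, MMP3, MMP9, SOX10).  Within each cohort, samples in the top
quartile of the score are EMT-high ("mesenchymal"), the bottom quartile
EMT-low ("epithelial"), and the middle half EMT-intermediate.

Quantiles use linear interpolation between order statistics (type 7).
Group membership itself is decided by a deterministic rank-and-cut rule
(see :func:`stratify_by_emt`) so that boundary ties are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("emtime")

__all__ = [
    "MarkerPanel",
    "EMTScoreTable",
    "GroupAssignment",
    "ScoreSummary",
    "EligibilityVerdict",
    "CohortIneligibleError",
    "compute_emt_score",
    "check_cohort_eligibility",
    "stratify_by_emt",
    "summarize_distribution",
    "GROUP_HIGH",
    "GROUP_INTERMEDIATE",
    "GROUP_LOW",
]

GROUP_HIGH = "high"
GROUP_INTERMEDIATE = "intermediate"
GROUP_LOW = "low"

EPITHELIAL_DEFAULT = ("CDH1", "DSP", "TJP1")
MESENCHYMAL_DEFAULT = (
    "VIM", "CDH2", "FOXC2", "SNAI1", "SNAI2", "TWIST1", "GSC",
    "FN1", "ITGB6", "MMP2", "MMP3", "MMP9", "SOX10",
)


class CohortIneligibleError(ValueError):
    """Raised when a cohort cannot be scored at all (no usable panel genes)."""


@dataclass(frozen=True)
class MarkerPanel:
    """Epithelial and mesenchymal gene lists defining the EMT score."""

    epithelial: tuple[str, ...] = EPITHELIAL_DEFAULT
    mesenchymal: tuple[str, ...] = MESENCHYMAL_DEFAULT

    def __post_init__(self) -> None:
        if not self.epithelial or not self.mesenchymal:
            raise ValueError("both marker lists must be non-empty")
        overlap = set(self.epithelial) & set(self.mesenchymal)
        if overlap:
            raise ValueError(f"marker lists overlap: {sorted(overlap)}")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.epithelial + self.mesenchymal


@dataclass
class EMTScoreTable:
    """Per-sample EMT scores for one cohort.

    ``score`` is NaN for samples lacking any usable gene on either side
    of the panel; ``n_epi_used`` / ``n_mes_used`` count the panel genes
    present in the matrix at all.
    """

    cohort_id: str
    score: pd.Series  # index = samples, values = EMT score
    n_epi_used: int
    n_mes_used: int

    @property
    def samples(self) -> list[str]:
        return list(self.score.index)


@dataclass
class GroupAssignment:
    """EMT group label per sample plus the two quartile cut points used."""

    group: pd.Series  # index = samples, values in {high, intermediate, low}
    boundaries: tuple[float, float]  # (q1, q3) of the scores

    @property
    def samples(self) -> list[str]:
        return list(self.group.index)

    def members(self, label: str) -> list[str]:
        return list(self.group.index[self.group == label])

    def counts(self) -> dict[str, int]:
        return {g: int((self.group == g).sum())
                for g in (GROUP_HIGH, GROUP_INTERMEDIATE, GROUP_LOW)}


@dataclass(frozen=True)
class ScoreSummary:
    cohort_id: str
    median: float
    quartile1: float
    quartile3: float

    @property
    def iqr(self) -> float:
        return self.quartile3 - self.quartile1


@dataclass(frozen=True)
class EligibilityVerdict:
    cohort_id: str
    eligible: bool
    reasons: tuple[str, ...] = ()


def compute_emt_score(expr: ExpressionMatrix, panel: MarkerPanel | None = None) -> EMTScoreTable:
    """Score = mean(mesenchymal z) - mean(epithelial z), per sample.

    Panel genes absent from the matrix are dropped with a logged warning;
    within each sample the means run over the non-missing panel genes
    present.  Raises :class:`CohortIneligibleError` if either side of the
    panel has no usable gene.
    """
    panel = panel or MarkerPanel()
    epi = [g for g in panel.epithelial if g in expr.values.index]
    mes = [g for g in panel.mesenchymal if g in expr.values.index]
    for side, present, wanted in (("epithelial", epi, panel.epithelial),
                                  ("mesenchymal", mes, panel.mesenchymal)):
        absent = sorted(set(wanted) - set(present))
        if absent:
            logger.warning("%s: %s panel gene(s) absent: %s",
                           expr.cohort_id, side, absent)
    if not epi or not mes:
        raise CohortIneligibleError(
            f"{expr.cohort_id}: no usable "
            f"{'epithelial' if not epi else 'mesenchymal'} panel gene"
        )
    mes_mean = expr.values.loc[mes].mean(axis=0, skipna=True)
    epi_mean = expr.values.loc[epi].mean(axis=0, skipna=True)
    score = (mes_mean - epi_mean).astype(float)
    n_missing = int(score.isna().sum())
    if n_missing:
        logger.warning("%s: %d sample(s) with no usable panel gene on one side; "
                       "score set missing", expr.cohort_id, n_missing)
    return EMTScoreTable(expr.cohort_id, score, len(epi), len(mes))


def check_cohort_eligibility(
    expr: ExpressionMatrix,
    panel: MarkerPanel | None = None,
    min_samples: int = 100,
    required_genes: tuple[str, ...] | None = None,
) -> EligibilityVerdict:
    """Decide whether a cohort enters the analysis.

    Ineligible when the sample count is <= ``min_samples`` (cohorts need
    n > 100 by default) or when any required panel gene is entirely absent
    from the matrix.  By default all epithelial markers are required —
    a cohort missing CDH1 outright cannot be scored comparably (the
    thyroid cohort was dropped from the source study for exactly this).
    """
    panel = panel or MarkerPanel()
    if required_genes is None:
        required_genes = panel.epithelial
    reasons = []
    if expr.n_samples <= min_samples:
        reasons.append(f"n <= {min_samples} (have {expr.n_samples})")
    for g in required_genes:
        if g not in expr.values.index:
            reasons.append(f"required epithelial marker absent: {g}")
    return EligibilityVerdict(expr.cohort_id, not reasons, tuple(reasons))


def _type7_quartiles(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def stratify_by_emt(scores: EMTScoreTable) -> GroupAssignment:
    """Assign each scored sample to EMT-high / -intermediate / -low.

    Samples are ranked by (score, stable input index) and cut at ranks
    floor(n/4) and ceil(3n/4): the lowest floor(n/4) are "low", those
    above ceil(3n/4) are "high", the rest "intermediate".  With distinct
    scores and n divisible by 4 this is exactly n/4 / n/2 / n/4 and agrees
    with the 25th/75th-percentile thresholds; ties are broken by input
    order so group sizes stay reproducible.  Samples with a missing score
    are excluded with a warning.  Requires >= 8 scored samples.
    """
    s = scores.score.dropna()
    n_dropped = len(scores.score) - len(s)
    if n_dropped:
        logger.warning("%s: %d unscored sample(s) excluded from stratification",
                       scores.cohort_id, n_dropped)
    n = len(s)
    if n < 8:
        raise ValueError(f"need >= 8 scored samples to stratify, have {n}")
    # stable sort: ties keep input order
    order = np.argsort(s.to_numpy(), kind="stable")
    n_low = int(np.floor(0.25 * n))
    cut_high = int(np.ceil(0.75 * n))  # high = ranks strictly above this
    labels = np.full(n, GROUP_INTERMEDIATE, dtype=object)
    labels[order[:n_low]] = GROUP_LOW
    labels[order[cut_high:]] = GROUP_HIGH
    q1, q3 = _type7_quartiles(s.to_numpy())
    return GroupAssignment(pd.Series(labels, index=s.index, name="group"), (q1, q3))


def summarize_distribution(scores: EMTScoreTable) -> ScoreSummary:
    """Median and quartiles of a cohort's score distribution (type-7)."""
    s = scores.score.dropna().to_numpy()
    if len(s) < 2:
        raise ValueError(f"need >= 2 scores to summarize, have {len(s)}")
    q1, q3 = _type7_quartiles(s)
    return ScoreSummary(scores.cohort_id, float(np.median(s)), q1, q3)
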