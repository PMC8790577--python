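"""Synthetic multi-cohort generator with known ground truth.

Every pipeline stage is testable without downloads: the generator
emulates the statistical structure of a z-scored pan-cancer cohort —
a latent per-sample EMT axis, panel genes and TIME markers coupled to
it linearly, an enrichment table correlated with it, and survival times
whose hazard depends on the EMT group.

Model, per cohort:

* latent axis            a_s ~ Normal(0, emt_axis_sd);
* mesenchymal panel gene z = +a_s + Normal(0, noise_sd), epithelial gene
  z = −a_s + noise; marker gene z = baseline + β·a_s + noise; genes are
  then re-standardized to mean 0 / SD 1 across the cohort;
* immune-cell enrichment = softplus(baseline + β·a_s + noise), so scores
  stay non-negative like xCell output;
* survival: exponential event times with hazard
  h0 · HR^(1, 0.5, 0 for EMT-high / -intermediate / -low), groups taken
  from the pipeline's own quartile stratification of the generated
  expression; censored subjects get a uniform fraction of their event
  time.  The exponents make hazards monotone across the three groups
  with a high-vs-low ratio equal to the configured value.

All randomness flows from the config seed; the same seed reproduces the
bundle bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClinicalTable, EnrichmentTable, ExpressionMatrix, GeneSet
from .scoring import (GROUP_HIGH, GROUP_INTERMEDIATE, GROUP_LOW, MarkerPanel,
                      compute_emt_score, stratify_by_emt)
from .signatures import (CHECKPOINT_GENES, CYTOKINE_GENES, IMMUNE_CELL_TYPES,
                         default_signatures, resolve_symbol)

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "GroundTruth",
    "CohortBundle",
    "default_marker_specs",
    "default_signature_couplings",
    "generate_cohort",
    "generate_multicohort",
]


@dataclass(frozen=True)
class MarkerSpec:
    """One TIME marker's coupling β to the latent EMT axis and baseline."""

    name: str
    category: str  # immune_cell / checkpoint / cytokine
    coupling: float
    baseline: float = 0.0


def default_marker_specs() -> list[MarkerSpec]:
    """Default couplings for the 17+17+17 marker panel.

    Signs and rough magnitudes mirror the pan-cancer picture the pipeline
    is designed to detect: macrophage/Th1/monocyte enrichment, most
    checkpoint molecules and the suppressive cytokines TGFB1/IL10 rise
    with the EMT axis; IL3/IL4/IL5/IFNA1 and PD-L1 are null; Tregs and
    CD8+ T cells decline mildly.
    """
    cell = {
        "B-cells": -0.2, "CD4+ T-cells": 0.0, "CD8+ T-cells": -0.3,
        "Th1 cells": 0.8, "Th2 cells": 0.0, "Tregs": -0.4, "NK cells": 0.0,
        "Monocytes": 0.6, "Macrophages": 1.0, "Macrophages M1": 0.5,
        "Macrophages M2": 0.7, "DC": 0.3, "cDC": 0.2, "pDC": 0.0,
        "Neutrophils": 0.2, "Eosinophils": 0.0, "Mast cells": 0.3,
    }
    checkpoint = {
        "PD1": 0.5, "PD-L1": 0.0, "PD-L2": 0.5, "CTLA4": 0.5, "LAG3": 0.6,
        "KIR": 0.2, "TIM3": 0.8, "VISTA": 0.5, "NOX2": 0.4, "SIGLEC5": 0.5,
        "SIGLEC7": 1.0, "SIGLEC15": 0.3, "FASLG": 0.3, "ICOS": 0.5,
        "GITR": 0.3, "TNFRSF4": 0.8, "TNFRSF9": 0.5,
    }
    cytokine = {
        "IFNA1": 0.0, "IFNB1": 0.0, "IFNG": 0.3, "TNFA": 0.3, "TGFB1": 1.0,
        "IL1A": 0.3, "IL1B": 0.4, "IL2": 0.0, "IL3": 0.0, "IL4": 0.0,
        "IL5": 0.0, "IL6": 0.5, "CXCL8": 0.5, "IL10": 0.8, "IL12A": 0.3,
        "IL12B": 0.2, "STAT6": 0.0,
    }
    specs = [MarkerSpec(n, "immune_cell", cell[n], baseline=1.0)
             for n in IMMUNE_CELL_TYPES]
    specs += [MarkerSpec(n, "checkpoint", checkpoint[n])
              for n in CHECKPOINT_GENES]
    specs += [MarkerSpec(n, "cytokine", cytokine[n])
              for n in CYTOKINE_GENES]
    return specs


def default_signature_couplings() -> dict[str, float]:
    """Per-signature coupling of member genes to the EMT axis."""
    return {
        "IFNG_6gene": 0.4, "Inflammatory_13gene": 0.8,
        "Exhausted_CD8_9gene": 0.7, "Exhausted_CD8_3gene": 0.6,
        "Activated_stroma": 0.9, "Hypoxia": 0.5,
        "Cytolytic_activity": 0.2, "TAM": 0.8,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    cohort_id: str = "SYN"
    n_samples: int = 400
    seed: int = 0
    emt_axis_sd: float = 1.0
    noise_sd: float = 1.0
    marker_specs: tuple[MarkerSpec, ...] = field(
        default_factory=lambda: tuple(default_marker_specs()))
    signature_couplings: dict[str, float] = field(
        default_factory=default_signature_couplings)
    hazard_ratio_high_vs_low: float = 2.0
    baseline_hazard_per_day: float = 1.0 / 1000.0
    censoring_rate: float = 0.3
    n_background_genes: int = 50
    panel: MarkerPanel = field(default_factory=MarkerPanel)

    def __post_init__(self) -> None:
        if self.emt_axis_sd <= 0 or self.noise_sd < 0:
            raise ValueError("emt_axis_sd must be > 0 and noise_sd >= 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ValueError("hazard ratio must be > 0")
        if self.n_samples < 8:
            raise ValueError("need >= 8 samples per cohort")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    axis: pd.Series                    # per-sample latent EMT position
    marker_coupling: pd.Series         # per-marker true β (TIME markers)
    gene_coupling: pd.Series           # per-gene true β (expression rows)
    group: pd.Series                   # EMT group used for the hazard
    hazard_ratio: float
    baseline_hazard_per_day: float
    archetype: int | None = None       # cohort's true cluster (multicohort)


@dataclass
class CohortBundle:
    config: SimulationConfig
    expression: ExpressionMatrix
    enrichment: EnrichmentTable
    clinical: ClinicalTable
    truth: GroundTruth


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


_HAZARD_EXP = {GROUP_HIGH: 1.0, GROUP_INTERMEDIATE: 0.5, GROUP_LOW: 0.0}


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate one cohort: expression, enrichment, clinical + ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"{config.cohort_id}-{i:04d}" for i in range(n)]
    a = rng.normal(0.0, config.emt_axis_sd, size=n)

    # gene -> coupling map: panel genes, marker genes, signature genes
    gene_beta: dict[str, float] = {}
    for g in config.panel.mesenchymal:
        gene_beta[g] = 1.0
    for g in config.panel.epithelial:
        gene_beta[g] = -1.0
    for spec in config.marker_specs:
        if spec.category in ("checkpoint", "cytokine"):
            gene_beta.setdefault(resolve_symbol(spec.name), spec.coupling)
    for gs in default_signatures():
        beta = config.signature_couplings.get(gs.name, 0.0)
        for g in sorted(gs.genes):
            gene_beta.setdefault(g, beta)
    for i in range(config.n_background_genes):
        gene_beta[f"BG{i:04d}"] = 0.0

    genes = list(gene_beta)
    betas = np.array([gene_beta[g] for g in genes])
    noise = rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    raw = betas[:, None] * a[None, :] + noise
    # re-standardize per gene across the cohort (GDAC-style z-scores)
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (raw - mu) / sd
    expr = ExpressionMatrix(config.cohort_id,
                            pd.DataFrame(z, index=genes, columns=samples))

    cell_specs = [s for s in config.marker_specs if s.category == "immune_cell"]
    enr_noise = rng.normal(0.0, config.noise_sd, size=(len(cell_specs), n))
    enr = _softplus(
        np.array([s.baseline for s in cell_specs])[:, None]
        + np.array([s.coupling for s in cell_specs])[:, None] * a[None, :]
        + enr_noise)
    enrich = EnrichmentTable(pd.DataFrame(
        enr, index=[s.name for s in cell_specs], columns=samples))

    # survival hazard follows the pipeline's own EMT grouping
    groups = stratify_by_emt(compute_emt_score(expr, config.panel)).group
    expo = np.array([_HAZARD_EXP[groups.loc[s]] for s in samples])
    hr = config.hazard_ratio_high_vs_low

    def _endpoint(hazard_scale: float) -> tuple[np.ndarray, np.ndarray]:
        hazard = config.baseline_hazard_per_day * hazard_scale * hr**expo
        t_event = rng.exponential(1.0 / hazard)
        censored = rng.random(n) < config.censoring_rate
        t_obs = np.where(censored, rng.random(n) * t_event, t_event)
        return t_obs, (~censored).astype(float)

    os_t, os_e = _endpoint(1.0)
    pfi_t, pfi_e = _endpoint(1.5)  # progression occurs before death on average
    clinical = ClinicalTable(pd.DataFrame(
        {"os_time": os_t, "os_event": os_e,
         "pfi_time": pfi_t, "pfi_event": pfi_e},
        index=pd.Index(samples, name="sample")))

    truth = GroundTruth(
        axis=pd.Series(a, index=samples, name="emt_axis"),
        marker_coupling=pd.Series(
            {s.name: s.coupling for s in config.marker_specs}),
        gene_coupling=pd.Series(gene_beta),
        group=groups,
        hazard_ratio=hr,
        baseline_hazard_per_day=config.baseline_hazard_per_day,
    )
    return CohortBundle(config, expr, enrich, clinical, truth)


def generate_multicohort(
    n_cohorts: int = 22,
    seed: int = 0,
    archetype_scales: tuple[float, ...] = (1.0, 0.0),
    n_samples: int = 400,
    coupling_jitter_sd: float = 0.05,
    base_config: SimulationConfig | None = None,
) -> tuple[dict[str, CohortBundle], pd.Series]:
    """Generate cohorts drawn from >= 2 planted archetypes.

    Each archetype multiplies every default marker coupling by one entry
    of ``archetype_scales`` (e.g. ``(1.0, 0.0)`` plants one cluster of
    cohorts whose EMT-high microenvironment is strongly shifted and one
    whose markers are decoupled — the two-cluster structure the delta-
    profile K-means is expected to recover).  Cohorts alternate between
    archetypes; couplings get a small per-cohort Gaussian jitter.

    Returns the bundles keyed by cohort ID plus the true archetype
    membership per cohort.
    """
    if len(archetype_scales) < 2:
        raise ValueError("need >= 2 archetypes")
    base = base_config or SimulationConfig(n_samples=n_samples)
    rng = np.random.default_rng(seed)
    bundles: dict[str, CohortBundle] = {}
    membership = {}
    for i in range(n_cohorts):
        arch = i % len(archetype_scales)
        scale = archetype_scales[arch]
        specs = tuple(
            replace(s, coupling=scale * s.coupling
                    + rng.normal(0.0, coupling_jitter_sd))
            for s in base.marker_specs)
        sig = {k: scale * v + rng.normal(0.0, coupling_jitter_sd)
               for k, v in base.signature_couplings.items()}
        cid = f"SYN{i:02d}"
        cfg = replace(base, cohort_id=cid, n_samples=n_samples,
                      marker_specs=specs, signature_couplings=sig,
                      seed=int(rng.integers(0, 2**31 - 1)))
        bundle = generate_cohort(cfg)
        bundle.truth.archetype = arch
        bundles[cid] = bundle
        membership[cid] = arch
    return bundles, pd.Series(membership, name="archetype")
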