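"""File-based pipeline: simulate -> score -> contrast -> cluster -> survive.

Each stage reads its inputs from disk (either user-supplied cohort TSVs or
the outputs of the ``simulate`` stage) and writes its outputs before the
next stage starts, so any single stage can be re-run from the manifest and
reproduce its files exactly.  All floats are written with ``%.10g`` so a
seeded run is byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as eio
from .cluster import (build_delta_profiles, build_median_profiles,
                      conditional_prob_frame, conditional_prob_high,
                      kmeans_with_silhouette, run_pca, top_contributors)
from .compare import build_landscape, landscape_frame
from .scoring import (EMTScoreTable, GroupAssignment, MarkerPanel,
                      check_cohort_eligibility, compute_emt_score,
                      stratify_by_emt, summarize_distribution,
                      GROUP_HIGH, GROUP_LOW)
from .signatures import TimeMarkerTable, assemble_time_table, default_signatures, score_signatures
from .simulate import SimulationConfig, generate_multicohort
from .survival import km_estimate, logrank_test

logger = logging.getLogger("emtime")

_FLOAT_FMT = "%.10g"

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline",
           "stage_simulate", "stage_score", "stage_contrast",
           "stage_cluster", "stage_survive"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cohort."""


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run needs, loadable from one YAML file."""

    output_dir: str
    seed: int = 0
    # simulate stage (ignored when explicit cohort paths are given)
    n_cohorts: int = 6
    n_samples: int = 200
    archetype_scales: tuple[float, ...] = (1.0, 0.0)
    # explicit inputs: {cohort_id: {expression, enrichment, clinical}}
    cohorts: dict[str, dict[str, str]] = dataclasses.field(default_factory=dict)
    signatures_gmt: str | None = None
    min_samples: int = 100
    kmeans_seed: int = 17
    kmeans_restarts: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        if "archetype_scales" in raw:
            raw["archetype_scales"] = tuple(raw["archetype_scales"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.signatures_gmt and not Path(self.signatures_gmt).exists():
            raise ConfigError(f"signatures GMT not found: {self.signatures_gmt}")
        for cid, paths in self.cohorts.items():
            for key in ("expression", "enrichment", "clinical"):
                if key not in paths:
                    raise ConfigError(f"cohort {cid}: missing {key} path")
                if not Path(paths[key]).exists():
                    raise ConfigError(
                        f"cohort {cid}: {key} file not found: {paths[key]}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    @property
    def out(self) -> Path:
        return Path(self.output_dir)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _cohort_paths(cfg: RunConfig) -> dict[str, dict[str, Path]]:
    if cfg.cohorts:
        return {cid: {k: Path(v) for k, v in paths.items()}
                for cid, paths in cfg.cohorts.items()}
    inputs = cfg.out / "inputs"
    paths = {}
    for f in sorted(inputs.glob("expression_*.tsv")):
        cid = f.stem.removeprefix("expression_")
        paths[cid] = {
            "expression": f,
            "enrichment": inputs / f"enrichment_{cid}.tsv",
            "clinical": inputs / f"clinical_{cid}.tsv",
        }
    if not paths:
        raise ConfigError(
            "no cohort inputs: give explicit cohort paths or run simulate first")
    return paths


def _gene_sets(cfg: RunConfig):
    if cfg.signatures_gmt:
        return eio.read_gmt(cfg.signatures_gmt)
    return default_signatures()


def _load_scores(cfg: RunConfig, cid: str) -> tuple[EMTScoreTable, GroupAssignment]:
    path = cfg.out / "scores" / f"emt_scores_{cid}.tsv"
    if not path.exists():
        raise StageError(f"stage needs scores for cohort {cid}; run score first")
    df = pd.read_csv(path, sep="\t", index_col="sample")
    scores = EMTScoreTable(cid, df["score"].astype(float),
                           int(df["n_epi_used"].iloc[0]),
                           int(df["n_mes_used"].iloc[0]))
    labeled = df["group"].dropna()
    q1, q3 = np.quantile(df["score"].dropna().to_numpy(), [0.25, 0.75],
                         method="linear")
    groups = GroupAssignment(labeled, (float(q1), float(q3)))
    return scores, groups


def _read_time_markers(path: Path) -> TimeMarkerTable:
    df = pd.read_csv(path, sep="\t", index_col="marker")
    category = df.pop("category")
    return TimeMarkerTable(df.astype(float), category)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA", **kw)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> list[Path]:
    """Generate a seeded multicohort bundle and write it as pipeline inputs."""
    out = cfg.out / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    bundles, membership = generate_multicohort(
        n_cohorts=cfg.n_cohorts, seed=cfg.seed,
        archetype_scales=cfg.archetype_scales, n_samples=cfg.n_samples)
    written = []
    truth = {"archetype": membership.to_dict()}
    for cid, b in bundles.items():
        eio.write_expression_matrix(b.expression, out / f"expression_{cid}.tsv")
        eio.write_enrichment_table(b.enrichment, out / f"enrichment_{cid}.tsv")
        eio.write_clinical(b.clinical, out / f"clinical_{cid}.tsv")
        truth[cid] = {
            "axis": {s: round(v, 10) for s, v in b.truth.axis.items()},
            "marker_coupling": {m: round(v, 10)
                                for m, v in b.truth.marker_coupling.items()},
            "hazard_ratio": b.truth.hazard_ratio,
        }
        written += [out / f"{k}_{cid}.tsv"
                    for k in ("expression", "enrichment", "clinical")]
    tpath = out / "ground_truth.json"
    tpath.write_text(json.dumps(truth, sort_keys=True, indent=1))
    return written + [tpath]


def stage_score(cfg: RunConfig) -> list[Path]:
    """EMT scores, quartile groups and distribution summaries per cohort."""
    panel = MarkerPanel()
    out = cfg.out / "scores"
    written = []
    summaries = []
    for cid, paths in _cohort_paths(cfg).items():
        try:
            expr = eio.read_expression_matrix(paths["expression"], cid)
            verdict = check_cohort_eligibility(expr, panel,
                                               min_samples=cfg.min_samples)
            if not verdict.eligible:
                logger.warning("cohort %s ineligible: %s", cid,
                               "; ".join(verdict.reasons))
                continue
            scores = compute_emt_score(expr, panel)
            groups = stratify_by_emt(scores)
            summ = summarize_distribution(scores)
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise StageError(f"score stage failed for cohort {cid}: {e}") from e
        df = pd.DataFrame({
            "score": scores.score,
            "group": groups.group.reindex(scores.score.index),
            "n_epi_used": scores.n_epi_used,
            "n_mes_used": scores.n_mes_used,
        })
        df.index.name = "sample"
        p = out / f"emt_scores_{cid}.tsv"
        _write(df, p)
        written.append(p)
        summaries.append({"cohort": cid, "median": summ.median,
                          "quartile1": summ.quartile1,
                          "quartile3": summ.quartile3, "iqr": summ.iqr,
                          "n": len(scores.score.dropna())})
    if not summaries:
        raise StageError("score stage: no eligible cohorts")
    sp = out / "score_summary.tsv"
    _write(pd.DataFrame(summaries).set_index("cohort"), sp)
    return written + [sp]


def stage_contrast(cfg: RunConfig) -> list[Path]:
    """TIME marker tables and per-marker group-contrast landscapes."""
    gene_sets = _gene_sets(cfg)
    out = cfg.out / "contrast"
    written = []
    for cid, paths in _cohort_paths(cfg).items():
        spath = cfg.out / "scores" / f"emt_scores_{cid}.tsv"
        if not spath.exists():
            continue  # cohort was ineligible at score stage
        try:
            expr = eio.read_expression_matrix(paths["expression"], cid)
            enrich = eio.read_enrichment_table(paths["enrichment"])
            scores, groups = _load_scores(cfg, cid)
            sigs = score_signatures(expr, gene_sets)
            time_tab = assemble_time_table(enrich, expr, sig_scores=sigs)
            results = build_landscape(time_tab, groups, scores)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"contrast stage failed for cohort {cid}: {e}") from e
        tm = out / f"time_markers_{cid}.tsv"
        _write(time_tab.to_frame(), tm, index_label="marker")
        lp = out / f"landscape_{cid}.tsv"
        _write(landscape_frame(results), lp)
        written += [tm, lp]
    if not written:
        raise StageError("contrast stage: no cohorts to process")
    return written


def stage_cluster(cfg: RunConfig) -> list[Path]:
    """PCA of group-median profiles, conditional probabilities of the top
    PCA contributors, and silhouette-selected K-means on delta profiles."""
    out = cfg.out / "cluster"
    tables, groups, scores = {}, {}, {}
    for f in sorted((cfg.out / "contrast").glob("time_markers_*.tsv")):
        cid = f.stem.removeprefix("time_markers_")
        tables[cid] = _read_time_markers(f)
        scores[cid], groups[cid] = _load_scores(cfg, cid)
    if not tables:
        raise StageError("cluster stage: no time-marker tables; run contrast")
    try:
        med = build_median_profiles(tables, groups)
        pca_med = run_pca(med, standardize=True)
        top4 = top_contributors(pca_med, n=min(4, med.shape[1]))
        cp_rows = []
        for cid in tables:
            for marker in top4:
                cp_rows += conditional_prob_high(
                    tables[cid].values.loc[marker], groups[cid])
        cp = conditional_prob_frame(cp_rows)
        cp.insert(0, "cohort", np.repeat(list(tables), 3 * len(top4)))
        delta = build_delta_profiles(tables, groups)
        pca_delta = run_pca(delta, standardize=True)
        kmax = min(8, len(delta) - 1)
        if kmax < 2:
            raise ValueError(f"need >= 3 cohorts for clustering, have {len(delta)}")
        clusters = kmeans_with_silhouette(
            delta, k_range=range(2, kmax + 1),
            restarts=cfg.kmeans_restarts, seed=cfg.kmeans_seed)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"cluster stage failed: {e}") from e

    files = {
        "pca_group_scores.tsv": pca_med.scores,
        "pca_group_contributions.tsv": pca_med.contributions_pct,
        "pca_group_variance.tsv": pca_med.explained_variance_pct.to_frame("pct"),
        "pca_delta_scores.tsv": pca_delta.scores,
        "pca_delta_contributions.tsv": pca_delta.contributions_pct,
        "conditional_probs.tsv": cp.set_index("cohort"),
        "clusters.tsv": clusters.assignments.to_frame(),
        "silhouette_by_k.tsv": pd.Series(
            clusters.silhouette_by_k, name="mean_silhouette")
            .rename_axis("k").to_frame(),
    }
    written = []
    for name, df in files.items():
        p = out / name
        _write(df, p)
        written.append(p)
    (out / "k_optimal.json").write_text(
        json.dumps({"k_optimal": clusters.k_optimal}, sort_keys=True))
    return written + [out / "k_optimal.json"]


def stage_survive(cfg: RunConfig) -> list[Path]:
    """KM curves per EMT group and log-rank tests, per cohort and endpoint."""
    out = cfg.out / "survival"
    written = []
    for cid, paths in _cohort_paths(cfg).items():
        spath = cfg.out / "scores" / f"emt_scores_{cid}.tsv"
        if not spath.exists():
            continue
        try:
            clin = eio.read_clinical(paths["clinical"])
            _, groups = _load_scores(cfg, cid)
            lr_rows = []
            for endpoint in ("os", "pfi"):
                ep = clin.endpoint(endpoint)
                shared = [s for s in groups.samples if s in ep.index]
                g = groups.group.loc[shared]
                km_rows = []
                times, events = {}, {}
                for label in sorted(g.unique()):
                    members = g.index[g == label]
                    t = ep.loc[members, "time"].to_numpy()
                    e = ep.loc[members, "event"].to_numpy()
                    times[label], events[label] = t, e
                    curve = km_estimate(t, e)
                    km_rows.append(pd.DataFrame({
                        "group": label, "time": curve.event_times,
                        "survival": curve.survival_prob,
                        "at_risk": curve.at_risk}))
                kp = out / f"km_{cid}_{endpoint}.tsv"
                _write(pd.concat(km_rows, ignore_index=True), kp, index=False)
                written.append(kp)
                res3 = logrank_test(times, events)
                lr_rows.append({"endpoint": endpoint, "comparison": "3-group",
                                "chi2": res3.chi2, "df": res3.df, "p": res3.p})
                hl = {k: times[k] for k in (GROUP_HIGH, GROUP_LOW)}
                hle = {k: events[k] for k in (GROUP_HIGH, GROUP_LOW)}
                res2 = logrank_test(hl, hle)
                lr_rows.append({"endpoint": endpoint,
                                "comparison": "high-vs-low",
                                "chi2": res2.chi2, "df": res2.df, "p": res2.p})
        except Exception as e:  # noqa: BLE001
            raise StageError(f"survive stage failed for cohort {cid}: {e}") from e
        lp = out / f"logrank_{cid}.tsv"
        _write(pd.DataFrame(lr_rows).set_index("endpoint"), lp)
        written.append(lp)
    if not written:
        raise StageError("survive stage: no cohorts to process")
    return written


_STAGES = {
    "simulate": stage_simulate,
    "score": stage_score,
    "contrast": stage_contrast,
    "cluster": stage_cluster,
    "survive": stage_survive,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the stages in order and write a replayable manifest.

    With no explicit cohort paths the ``simulate`` stage runs first; the
    manifest records the config hash, seed, package version and a sha256
    per output file, so two runs with the same config+seed produce
    identical manifests.
    """
    cfg.validate()
    if stages is None:
        stages = (["simulate"] if not cfg.cohorts else []) + \
            ["score", "contrast", "cluster", "survive"]
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    cfg.out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    for name in stages:
        logger.info("stage %s ...", name)
        files = _STAGES[name](cfg)
        manifest["stages"][name] = {
            str(p.relative_to(cfg.out)): _sha256(p) for p in sorted(files)}
    (cfg.out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
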