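"""Gene-signature scoring and assembly of the unified TIME marker table.

A signature score is the unweighted mean z-score of the signature's member
genes present in the expression matrix, per sample — the same aggregation
the EMT score uses for each side of its panel, so a one-gene signature
reduces exactly to that gene's z-score row.

The TIME (tumor immune microenvironment) marker table unifies, per sample:
immune-cell enrichment scores (consumed from an xCell-style table),
checkpoint-gene z-scores, cytokine-gene z-scores, and signature scores.
The default panels are 17 immune cell types, 17 checkpoint molecules and
17 cytokines; checkpoint/cytokine names common in the literature (PD1,
TIM3, TNFA, ...) are resolved to official HGNC symbols through an editable
alias table.

The packaged default signature gene lists in ``data/signatures_synthetic.gmt``
are synthetic stand-ins — representative published memberships for the
named signatures, not an authoritative curation — and can be replaced by
any GMT file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import EnrichmentTable, ExpressionMatrix, GeneSet, read_gmt

logger = logging.getLogger("emtime")

__all__ = [
    "SignatureScoreTable",
    "TimeMarkerTable",
    "score_signature",
    "score_signatures",
    "assemble_time_table",
    "default_signatures",
    "resolve_symbol",
    "CHECKPOINT_GENES",
    "CYTOKINE_GENES",
    "IMMUNE_CELL_TYPES",
    "GENE_ALIASES",
    "CATEGORIES",
]

CATEGORIES = ("immune_cell", "checkpoint", "cytokine", "signature")

#: 17 immune checkpoint molecules, by their common literature names.
CHECKPOINT_GENES = (
    "PD1", "PD-L1", "PD-L2", "CTLA4", "LAG3", "KIR", "TIM3", "VISTA",
    "NOX2", "SIGLEC5", "SIGLEC7", "SIGLEC15", "FASLG", "ICOS", "GITR",
    "TNFRSF4", "TNFRSF9",
)

#: 17 cytokine molecules.
CYTOKINE_GENES = (
    "IFNA1", "IFNB1", "IFNG", "TNFA", "TGFB1", "IL1A", "IL1B", "IL2",
    "IL3", "IL4", "IL5", "IL6", "CXCL8", "IL10", "IL12A", "IL12B", "STAT6",
)

#: 17 immune cell types expected in the enrichment table.
IMMUNE_CELL_TYPES = (
    "B-cells", "CD4+ T-cells", "CD8+ T-cells", "Th1 cells", "Th2 cells",
    "Tregs", "NK cells", "Monocytes", "Macrophages", "Macrophages M1",
    "Macrophages M2", "DC", "cDC", "pDC", "Neutrophils", "Eosinophils",
    "Mast cells",
)

#: Common-name -> official-symbol aliases; editable, applied when a marker
#: name is looked up in the expression matrix.
GENE_ALIASES: dict[str, str] = {
    "PD1": "PDCD1",
    "PD-L1": "CD274",
    "PD-L2": "PDCD1LG2",
    "TIM3": "HAVCR2",
    "GITR": "TNFRSF18",
    "TNFA": "TNF",
    "KIR": "KIR3DL1",
    "VISTA": "VSIR",
    "NOX2": "CYBB",
}


def resolve_symbol(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map a common marker name to its official gene symbol (identity if none)."""
    table = GENE_ALIASES if aliases is None else aliases
    return table.get(name, name)


@dataclass
class SignatureScoreTable:
    """Per-sample mean-z scores, one row per signature (signatures x samples)."""

    values: pd.DataFrame
    genes_used: dict[str, int]  # signature -> number of member genes found

    @property
    def signatures(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TimeMarkerTable:
    """Unified per-sample TIME marker values (markers x samples).

    ``category`` labels each marker row as immune_cell, checkpoint,
    cytokine or signature.  Values keep their native scale (enrichment
    score, z-score, or signature mean-z).
    """

    values: pd.DataFrame
    category: pd.Series  # index = marker names

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker names across categories: {dup}")
        if not self.values.index.equals(self.category.index):
            raise ValueError("category index must match marker rows")
        bad = set(self.category) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown marker categories: {sorted(bad)}")

    @property
    def markers(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "category", self.category)
        return out


def default_signatures() -> list[GeneSet]:
    """The packaged synthetic stand-in signature gene sets (see module docs)."""
    ref = resources.files("emtime.data") / "signatures_synthetic.gmt"
    with resources.as_file(ref) as path:
        return read_gmt(path)


def score_signature(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-sample unweighted mean z-score over the signature genes present.

    Raises ValueError naming the signature if none of its genes occur in
    the matrix.
    """
    present = [g for g in sorted(gene_set.genes) if g in expr.values.index]
    if not present:
        raise ValueError(
            f"signature {gene_set.name!r}: none of its {len(gene_set.genes)} "
            f"genes present in cohort {expr.cohort_id}"
        )
    if len(present) < len(gene_set.genes):
        logger.warning("signature %s: %d/%d genes present", gene_set.name,
                       len(present), len(gene_set.genes))
    s = expr.values.loc[present].mean(axis=0, skipna=True)
    s.name = gene_set.name
    return s


def score_signatures(expr: ExpressionMatrix, gene_sets: list[GeneSet]) -> SignatureScoreTable:
    rows = {gs.name: score_signature(expr, gs) for gs in gene_sets}
    used = {gs.name: sum(g in expr.values.index for g in gs.genes)
            for gs in gene_sets}
    values = pd.DataFrame(rows).T
    values = values.loc[[gs.name for gs in gene_sets]]  # preserve input order
    return SignatureScoreTable(values, used)


def _gene_rows(expr: ExpressionMatrix, names: tuple[str, ...],
               aliases: dict[str, str] | None) -> pd.DataFrame:
    if not names:
        return pd.DataFrame(columns=expr.values.columns, dtype=float)
    rows = {}
    for name in names:
        sym = resolve_symbol(name, aliases)
        if sym in expr.values.index:
            rows[name] = expr.values.loc[sym]
        else:
            logger.warning("marker gene %s (%s) absent from cohort %s; "
                           "row filled with NaN", name, sym, expr.cohort_id)
            rows[name] = pd.Series(np.nan, index=expr.values.columns)
    df = pd.DataFrame(rows).T
    return df.loc[list(names)]


def assemble_time_table(
    enrich: EnrichmentTable,
    expr: ExpressionMatrix,
    checkpoint_genes: tuple[str, ...] = CHECKPOINT_GENES,
    cytokine_genes: tuple[str, ...] = CYTOKINE_GENES,
    sig_scores: SignatureScoreTable | None = None,
    aliases: dict[str, str] | None = None,
) -> TimeMarkerTable:
    """Join enrichment rows, checkpoint/cytokine z-score rows and signature
    scores into one markers x samples table.

    Samples are inner-joined across all sources; an empty intersection is
    an error.  Marker names must be unique across categories.
    """
    sources: list[tuple[pd.DataFrame, str]] = [
        (enrich.values, "immune_cell"),
        (_gene_rows(expr, checkpoint_genes, aliases), "checkpoint"),
        (_gene_rows(expr, cytokine_genes, aliases), "cytokine"),
    ]
    if sig_scores is not None and len(sig_scores.values):
        sources.append((sig_scores.values, "signature"))

    shared = sources[0][0].columns
    for df, _ in sources[1:]:
        shared = shared.intersection(df.columns)
    # keep the expression matrix's sample order for determinism
    shared = [s for s in expr.samples if s in set(shared)]
    if not shared:
        raise ValueError("no samples shared across enrichment, expression "
                         "and signature sources")

    blocks = [df[shared] for df, _ in sources]
    values = pd.concat(blocks, axis=0)
    category = pd.Series(
        np.concatenate([[cat] * len(df) for df, cat in sources]),
        index=values.index, name="category",
    )
    return TimeMarkerTable(values, category)
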