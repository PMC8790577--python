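"""Readers, writers and validated in-memory containers for pipeline tables.

All external tables are plain text: tab-separated expression / enrichment /
clinical matrices and GMT gene-set files.  Parsing is strict — malformed
input raises :class:`ParseError` naming the offending line — and sample
order is always preserved exactly as it appears in the file.

Missing values are encoded by the tokens ``NA``, ``NaN`` or an empty field
and propagate as ``NaN``; downstream statistics exclude them pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("emtime")

NA_TOKENS = ("NA", "", "NaN", "nan")

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "EnrichmentTable",
    "GeneSet",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_enrichment_table",
    "write_enrichment_table",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the line involved."""


class ValidationError(ValueError):
    """A parsed structure violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Per-gene z-scored expression for one cohort (genes x samples).

    ``values`` is a DataFrame indexed by gene symbol with one column per
    sample; entries are dimensionless per-gene z-scores, NaN where missing.
    """

    cohort_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if self.values.size == 0:
            raise ValidationError("empty expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isinf(arr).any():
            raise ValidationError("expression values must be finite or NaN")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def standardize(self) -> "ExpressionMatrix":
        """Re-standardize each gene to mean 0, SD 1 across samples.

        For raw (not pre-scaled) inputs.  Genes with zero variance become
        all-zero rather than NaN.
        """
        v = self.values
        sd = v.std(axis=1, ddof=1).replace(0.0, 1.0)
        z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
        return ExpressionMatrix(self.cohort_id, z)


@dataclass
class EnrichmentTable:
    """Precomputed per-sample cell-type enrichment scores (cell types x samples).

    Scores are dimensionless and non-negative, as produced by xCell-style
    deconvolution; they are consumed as an input, never recomputed here.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate cell-type names")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs")
        arr = self.values.to_numpy()
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("enrichment scores must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (one GMT line)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints: OS and PFI time (days) / event flags.

    ``data`` is indexed by sample with float columns ``os_time``,
    ``os_event``, ``pfi_time``, ``pfi_event``.  NaN marks a missing entry;
    records with unparsable fields are retained and flagged, never silently
    dropped.
    """

    data: pd.DataFrame
    COLUMNS = ("os_time", "os_event", "pfi_time", "pfi_event")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"clinical table lacks columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in clinical table")
        for c in ("os_time", "pfi_time"):
            t = self.data[c]
            if (t.dropna() < 0).any():
                bad = self.data.index[t < 0].tolist()
                raise ValidationError(f"negative {c} for samples {bad}")
        for c in ("os_event", "pfi_event"):
            e = self.data[c].dropna()
            if not e.isin([0.0, 1.0]).all():
                raise ValidationError(f"{c} values must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, name: str) -> pd.DataFrame:
        """Complete (time, event) records for endpoint 'os' or 'pfi'.

        Rows with a missing time or event for that endpoint are dropped
        per-endpoint, not per-subject.
        """
        if name not in ("os", "pfi"):
            raise ValueError(f"unknown endpoint {name!r}")
        sub = self.data[[f"{name}_time", f"{name}_event"]].dropna()
        sub.columns = ["time", "event"]
        return sub


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _parse_matrix(path, kind: str) -> pd.DataFrame:
    """Parse a TSV with a header row and a leading row-name column.

    Non-numeric cells raise ParseError citing the 1-based line and column.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: line 1: empty header")
        cols = header.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}: line 1: header has no sample columns")
        samples = [c.strip() for c in cols[1:]]
        names: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            names.append(fields[0].strip())
            row = []
            for j, tok in enumerate(fields[1:], start=2):
                tok = tok.strip()
                if tok in NA_TOKENS:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}, column {j}: "
                        f"non-numeric {kind} value {tok!r}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=names, columns=samples, dtype=float)


def read_expression_matrix(
    path, cohort_id: str, standardize: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples TSV of per-gene z-scores.

    Duplicate gene rows are collapsed by their mean with a logged warning.
    Set ``standardize=True`` for raw inputs that still need per-gene
    scaling to mean 0 / SD 1 (GDAC-style inputs are already scaled).
    """
    df = _parse_matrix(path, "expression")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning(
            "%s: %d duplicated gene symbol(s) collapsed by mean: %s",
            path, len(dups), dups,
        )
        # groupby sorts; restore first-appearance order
        order = df.index.unique()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    mat = ExpressionMatrix(cohort_id, df)
    return mat.standardize() if standardize else mat


def write_expression_matrix(mat: ExpressionMatrix, path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="gene",
                      float_format="%.12g", na_rep="NA")


def read_enrichment_table(path) -> EnrichmentTable:
    """Read a cell types x samples enrichment-score TSV (xCell-style)."""
    return EnrichmentTable(_parse_matrix(path, "enrichment"))


def write_enrichment_table(tab: EnrichmentTable, path) -> None:
    tab.values.to_csv(path, sep="\t", index_label="cell_type",
                      float_format="%.12g", na_rep="NA")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file: name TAB description TAB gene1 TAB ...

    Lines with fewer than three fields (i.e. no genes) are rejected.
    """
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set has no genes")
            sets.append(GeneSet(fields[0].strip(), genes, fields[1].strip()))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


_DEFAULT_CLINICAL_COLS = {
    "sample": "sample",
    "os_time": "os_time",
    "os_event": "os_event",
    "pfi_time": "pfi_time",
    "pfi_event": "pfi_event",
}


def read_clinical(path, column_map: dict[str, str] | None = None) -> ClinicalTable:
    """Read a clinical TSV with OS/PFI time and event columns.

    ``column_map`` maps the canonical names (sample, os_time, os_event,
    pfi_time, pfi_event) to the file's actual header names.  Cells that do
    not parse as numbers become missing (flagged NaN); structurally invalid
    values (negative time, event not 0/1) raise ValidationError.
    """
    cols = dict(_DEFAULT_CLINICAL_COLS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [cols[k] for k in _DEFAULT_CLINICAL_COLS if cols[k] not in raw.columns]
    if missing:
        raise ParseError(
            f"{path}: missing mandatory clinical columns {missing}; "
            f"found {list(raw.columns)}"
        )
    out = pd.DataFrame(index=pd.Index(raw[cols["sample"]].str.strip(), name="sample"))
    for canon in ("os_time", "os_event", "pfi_time", "pfi_event"):
        tok = raw[cols[canon]].str.strip()
        vals = pd.to_numeric(tok.where(~tok.isin(NA_TOKENS)), errors="coerce")
        n_flagged = int((vals.isna() & ~tok.isin(NA_TOKENS)).sum())
        if n_flagged:
            logger.warning("%s: %d unparsable %s value(s) flagged missing",
                           path, n_flagged, canon)
        out[canon] = vals.to_numpy()
    return ClinicalTable(out)


def write_clinical(tab: ClinicalTable, path) -> None:
    tab.data.to_csv(path, sep="\t", index_label="sample",
                    float_format="%.12g", na_rep="NA")
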