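"""Readers and writers for the tabular artifacts of the pipeline.

All formats are plain text (TSV/CSV/GMT, UTF-8, LF line endings, ``.``
decimal separator).  Gene identifiers are opaque, case-sensitive strings.
Missing values are not permitted in expression matrices: callers must
pre-impute, otherwise the reader raises.

In-memory containers are plain :class:`pandas.DataFrame` objects:

* expression matrix — genes as index (name ``gene_id``), one float column
  per sample (FPKM, non-negative, finite);
* sample sheet — columns ``sample_id``, ``condition``, ``replicate``;
* ortholog map — columns ``gene_a``, ``gene_b`` (optional ``score``),
  duplicate pairs collapsed;
* annotation sets — :class:`AnnotationSets`, a thin wrapper over
  ``term_id -> set of gene ids`` with optional descriptions (GMT on disk).

Column order in the matrix carries no meaning; the sample sheet is the
authority for condition/replicate structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "replicate")
CT_COLUMNS = ("sample_id", "condition", "biological_rep", "gene_id", "role", "ct")
RWC_COLUMNS = ("fresh_weight", "dry_weight", "turgid_weight")


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


# ---------------------------------------------------------------------------
# expression matrix + sample sheet


def validate_expression(matrix: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Check matrix/sheet invariants; raise :class:`FormatError` on violation."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(f"duplicated gene id: {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise FormatError(f"duplicated sample id: {dup!r}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric values")
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid FPKM at gene {matrix.index[i]!r}, sample "
            f"{matrix.columns[j]!r}: {values[i, j]!r} (must be finite and >= 0)"
        )
    validate_sample_sheet(sheet)
    mat_samples = set(matrix.columns)
    sheet_samples = set(sheet["sample_id"])
    if mat_samples != sheet_samples:
        missing = sorted(mat_samples - sheet_samples)
        extra = sorted(sheet_samples - mat_samples)
        raise FormatError(
            "matrix and sample sheet disagree: "
            f"matrix-only samples {missing}, sheet-only samples {extra}"
        )


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in sheet.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicated sample id in sheet: {dup!r}")
    pairs = sheet[["condition", "replicate"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise FormatError(f"duplicated (condition, replicate) pair: {dup}")
    if (sheet["replicate"].astype(int) <= 0).any():
        raise FormatError("replicate numbers must be positive integers")


def read_expression(path, sample_sheet_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene-by-sample FPKM TSV and its companion sample sheet.

    The matrix file is tab-separated with a leading ``gene_id`` column; the
    sheet is CSV or TSV (sniffed from the header line) with columns
    ``sample_id, condition, replicate``.  Returns a validated
    ``(matrix, sheet)`` pair whose sample sets agree.
    """
    matrix = pd.read_csv(path, sep="\t", index_col="gene_id")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    if matrix.isna().any().any():
        row = matrix.index[matrix.isna().any(axis=1)][0]
        raise FormatError(f"missing FPKM value at gene {row!r}")
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric FPKM value: {exc}") from exc
    sheet = read_sample_sheet(sample_sheet_path)
    validate_expression(matrix, sheet)
    return matrix, sheet


def read_sample_sheet(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    sheet = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "condition": str})
    validate_sample_sheet(sheet)
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# ortholog map


def read_ortholog_map(path) -> pd.DataFrame:
    """Read a two- (or three-) column TSV of cross-species gene pairs.

    Duplicate pairs are collapsed with a logged warning.  Many-to-many maps
    are allowed.  Raises on an empty file.
    """
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    if {"gene_a", "gene_b"} - set(pairs.columns):
        raise FormatError("ortholog map needs columns gene_a, gene_b")
    if len(pairs) == 0:
        raise FormatError(f"ortholog map {path} is empty")
    if "score" in pairs.columns:
        pairs["score"] = pairs["score"].astype(float)
    n_dup = pairs.duplicated(subset=["gene_a", "gene_b"]).sum()
    if n_dup:
        logger.warning("ortholog map: collapsed %d duplicate pair(s)", n_dup)
        pairs = pairs.drop_duplicates(subset=["gene_a", "gene_b"])
    pairs = pairs.reset_index(drop=True)
    logger.info(
        "ortholog map: %d pairs, %d a-side genes, %d b-side genes",
        len(pairs), pairs["gene_a"].nunique(), pairs["gene_b"].nunique(),
    )
    return pairs


def write_ortholog_map(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation sets (GMT)


@dataclass
class AnnotationSets:
    """Flat gene sets keyed by term id (GO/KEGG style, no DAG structure)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise FormatError(f"annotation term {term!r} has no genes")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: set[str]) -> "AnnotationSets":
        """Intersect every term with *universe*, dropping emptied terms."""
        kept = {
            t: frozenset(g & universe)
            for t, g in self.sets.items()
            if g & universe
        }
        return AnnotationSets(kept, {t: self.descriptions.get(t, "") for t in kept})


def read_annotation_sets(path) -> AnnotationSets:
    """Read GMT: per line ``term_id <TAB> description <TAB> gene1 <TAB> ...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: term {fields[0]!r} has no member genes"
                )
            term, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no member genes")
            sets[term] = frozenset(genes)
            descriptions[term] = desc
    if not sets:
        raise FormatError(f"annotation file {path} is empty")
    return AnnotationSets(sets, descriptions)


def write_annotation_sets(annotations: AnnotationSets, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in annotations.sets:
            desc = annotations.descriptions.get(term, "")
            members = "\t".join(sorted(annotations.sets[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# contrast / assignment / Ct / physiology tables


def read_contrast_table(path) -> pd.DataFrame:
    """Read a precomputed per-gene contrast TSV (Cuffdiff-style export).

    Requires ``gene_id, log2fc, p_value``; ``q_value`` is optional and will
    be recomputed by Benjamini–Hochberg downstream when absent.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "p_value"}
    if required - set(table.columns):
        raise FormatError(f"contrast table needs columns {sorted(required)}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicated gene id: {dup!r}")
    return table


def write_contrast_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g",
                 lineterminator="\n")


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR table: one row per technical-replicate well."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str,
                                               "condition": str, "role": str})
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"Ct table missing columns {sorted(missing)}")
    bad_role = set(table["role"]) - {"target", "reference"}
    if bad_role:
        raise FormatError(f"Ct table has unknown role(s) {sorted(bad_role)}")
    table["ct"] = table["ct"].astype(float)
    return table


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g",
                 lineterminator="\n")


def read_physio_table(path) -> pd.DataFrame:
    """Read RWC weights (fresh/dry/turgid, grams) or a timed weight series."""
    table = pd.read_csv(path, sep="\t")
    has_rwc = set(RWC_COLUMNS) <= set(table.columns)
    has_series = {"time", "weight"} <= set(table.columns)
    if not (has_rwc or has_series):
        raise FormatError(
            "physiology table needs either fresh_weight/dry_weight/turgid_weight "
            "or time/weight columns"
        )
    return table
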