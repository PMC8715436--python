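"""Readers and writers for the tabular formats the tool touches.

Supported inputs are the Roary ``.Rtab`` gene presence/absence matrix
(tab-separated, genes as rows, genomes as columns, cells 0/1), the
Roary/Panaroo ``gene_presence_absence.csv`` dialect (gene entries per
genome; any non-empty entry counts as presence), a two-column genome ->
lineage table, and a per-gene annotation table.  All output is
tab-separated UTF-8 with a header line; ``#``-prefixed comment lines are
ignored on read so CLI provenance headers round-trip cleanly.
"""

from __future__ import annotations

import csv
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationTable, DISTRIBUTION_CLASSES, ABSENT_CLASS
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

# Metadata columns of Roary's gene_presence_absence.csv; Panaroo emits the
# first three only.  Everything else is treated as a genome column.
_ROARY_META_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genes in Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "Order within Fragment",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dup[:5]}")


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the presence/absence invariants; return the matrix as int8."""
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValidationError("matrix needs at least one gene and one genome")
    _check_unique(matrix.index, "gene")
    _check_unique(matrix.columns, "genome")
    values = matrix.to_numpy()
    ok = (values == 0) | (values == 1)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"non-binary value {matrix.iat[i, j]!r} for gene "
            f"{matrix.index[i]!r}, genome {matrix.columns[j]!r}"
        )
    out = matrix.astype(np.int8)
    out.index = matrix.index.astype(str)
    out.columns = matrix.columns.astype(str)
    out.index.name = "gene_id"
    return out


def read_presence_absence(path, dialect: str = "rtab") -> pd.DataFrame:
    """Read a gene presence/absence matrix (genes x genomes, values 0/1).

    ``dialect`` is ``"rtab"`` for Roary's .Rtab or ``"roary_csv"`` for the
    Roary/Panaroo gene_presence_absence.csv, where any non-empty gene entry
    for a genome (including multi-copy paralog entries) collapses to 1.
    """
    if dialect == "rtab":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except Exception as exc:  # malformed TSV
            raise FormatError(f"cannot parse Rtab file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"Rtab file {path} has no genome columns")
        for col in df.columns:
            bad = df[col][~df[col].astype(str).isin(["0", "1"])]
            if len(bad):
                raise ValidationError(
                    f"non-binary value {bad.iloc[0]!r} in column {col!r} "
                    f"of {path} (gene {bad.index[0]!r})"
                )
        return validate_matrix(df.astype(np.int8))
    if dialect == "roary_csv":
        try:
            df = pd.read_csv(path, index_col=False, dtype=str, keep_default_na=False)
        except Exception as exc:
            raise FormatError(f"cannot parse roary csv {path}: {exc}") from exc
        if "Gene" not in df.columns:
            raise FormatError(
                f"{path}: header line lacks the 'Gene' column expected in "
                "gene_presence_absence.csv"
            )
        genome_cols = [c for c in df.columns if c not in _ROARY_META_COLUMNS]
        if not genome_cols:
            raise FormatError(f"{path} has no genome columns")
        presence = (df[genome_cols] != "").astype(np.int8)
        presence.index = df["Gene"]
        return validate_matrix(presence)
    raise ValueError(f"unknown dialect {dialect!r}; use 'rtab' or 'roary_csv'")


def write_presence_absence(matrix: pd.DataFrame, path) -> None:
    """Write a matrix in Rtab layout (lossless round-trip with the reader)."""
    out = matrix.copy()
    out.index.name = "Gene"
    out.to_csv(path, sep="\t")


def _sniff_sep(path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t").delimiter
    except csv.Error:
        return "," if "," in first else "\t"


def read_lineages(path) -> pd.Series:
    """Read a two-column genome -> lineage table (CSV or TSV, with header).

    Exact duplicate rows are dropped; the same genome mapped to two
    different lineages is a validation error.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: expected two columns (genome, lineage), got {df.shape[1]}"
        )
    df = df.iloc[:, :2]
    df.columns = ["genome_id", "lineage_id"]
    df = df.drop_duplicates()
    conflict = df["genome_id"][df["genome_id"].duplicated()]
    if len(conflict):
        raise ValidationError(
            f"genome(s) assigned to more than one lineage: "
            f"{sorted(set(conflict))[:5]}"
        )
    return pd.Series(
        df["lineage_id"].to_numpy(), index=pd.Index(df["genome_id"], name="genome_id"),
        name="lineage_id",
    )


def read_annotations(path) -> pd.DataFrame:
    """Read a per-gene annotation table.

    Columns: ``gene_id``, ``cog_category`` (single letter or '?'),
    ``prediction`` (free text), optional ``transfer_probability`` in [0, 1].
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    required = {"gene_id", "cog_category", "prediction"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    _check_unique(df["gene_id"], "gene")
    df = df.set_index("gene_id")
    if "transfer_probability" in df.columns:
        prob = pd.to_numeric(df["transfer_probability"].replace("", np.nan))
        bad = prob[(prob < 0) | (prob > 1)]
        if len(bad):
            raise ValidationError(
                f"transfer_probability outside [0, 1] for gene(s) "
                f"{bad.index.tolist()[:5]}"
            )
        df["transfer_probability"] = prob
    return df


def write_classification(
    classification: ClassificationTable,
    path,
    include_frequencies: bool = False,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a classification as TSV (one gene per row).

    Columns: gene_id, distribution_class, n_lineages_present, n_core,
    n_intermediate, n_rare, then one frequency column per lineage when
    ``include_frequencies`` is set.  ``header_lines`` are emitted first as
    ``#``-prefixed comments (CLI provenance).
    """
    out = classification.table.copy()
    if include_frequencies:
        freqs = classification.frequencies.copy()
        freqs.columns = [f"freq_{c}" for c in freqs.columns]
        out = out.join(freqs)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t")


def read_classification(path) -> pd.DataFrame:
    """Read back a classification TSV into a per-gene DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    if "distribution_class" not in df.columns:
        raise FormatError(f"{path}: missing 'distribution_class' column")
    known = set(DISTRIBUTION_CLASSES) | {ABSENT_CLASS}
    bad = set(df["distribution_class"]) - known
    if bad:
        raise ValidationError(f"unknown distribution class(es): {sorted(bad)[:5]}")
    return df
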