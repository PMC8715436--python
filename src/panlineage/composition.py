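"""Genetic composition of genomes and lineages by distribution class.

Counts how many genes of each distribution class a genome carries, takes
per-lineage medians of those counts, and summarises the species by the
"typical genome": the median across lineage medians for every class.
Taking medians per lineage first keeps heavily over-sampled lineages from
dominating the species-level summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassificationTable, DISTRIBUTION_CLASSES
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CompositionSummary:
    """Gene-content composition at genome and lineage level.

    ``genome_counts``: genomes x classes DataFrame of integer gene counts.
    ``lineage_medians``: lineages x classes DataFrame of per-lineage
    medians (midpoint convention for even sizes, so half-integers occur).
    """

    genome_counts: pd.DataFrame
    lineage_medians: pd.DataFrame


def per_genome_class_counts(
    matrix: pd.DataFrame,
    classification: ClassificationTable | pd.Series,
    assignment: pd.Series,
) -> CompositionSummary:
    """Count, per genome, the carried genes of each distribution class.

    Every gene of the matrix must be classified; genes with the sentinel
    ``absent`` class (carried only by genomes of dropped lineages) are
    excluded from the per-class counts.
    """
    classes = (
        classification.classes
        if isinstance(classification, ClassificationTable)
        else pd.Series(classification)
    )
    missing = matrix.index.difference(classes.index)
    if len(missing):
        raise ValidationError(
            f"gene(s) in matrix missing from classification: "
            f"{missing.tolist()[:5]}"
        )
    classes = classes.reindex(matrix.index)
    onehot = pd.get_dummies(classes).reindex(
        columns=list(DISTRIBUTION_CLASSES), fill_value=0
    )
    counts = matrix.astype(np.int64).T @ onehot.astype(np.int64)
    counts.index.name = "genome_id"
    counts.columns.name = "distribution_class"

    common = counts.index.intersection(assignment.index)
    if len(common) < len(counts):
        logger.warning(
            "%d genome(s) lack a lineage assignment and are excluded from "
            "lineage medians", len(counts) - len(common),
        )
    medians = counts.loc[common].groupby(assignment.loc[common]).median()
    empty = assignment[~assignment.isin(medians.index)].unique()
    if len(empty):
        logger.warning("lineage(s) with no genomes in matrix excluded: %s",
                       ", ".join(map(str, empty)))
    medians.index.name = "lineage_id"
    return CompositionSummary(genome_counts=counts, lineage_medians=medians)


def typical_genome_composition(summary: CompositionSummary) -> pd.DataFrame:
    """Median-of-lineage-medians gene count per class, plus its fraction
    of the typical genome's total gene content."""
    if summary.lineage_medians.empty:
        raise ValidationError("no lineages with genomes; cannot summarise")
    typical = summary.lineage_medians.median(axis=0)
    total = typical.sum()
    fraction = typical / total if total > 0 else typical * 0.0
    out = pd.DataFrame({"typical_count": typical, "fraction": fraction})
    out.index.name = "distribution_class"
    return out
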