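"""Population-structure-aware classification of pan-genome gene clusters.

Genes are first labelled *within* each lineage by their carriage frequency
(core / intermediate / rare / absent) and the per-lineage labels are then
summarised into one of 13 species-wide distribution classes, combining the
number of lineages a gene occupies (all / multiple / one) with the labels it
takes there.  A gene core to a single under-sampled lineage is therefore
never mistaken for a collection-wide rare or intermediate gene, which is the
failure mode of frequency-over-the-whole-collection schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Within-lineage frequency labels.
LABELS = ("core", "intermediate", "rare", "absent")

#: Sentinel class for genes carried by no genome of any analysed lineage.
ABSENT_CLASS = "absent"

#: The 13 species-wide distribution classes, in canonical order: lineage
#: scope (all lineages -> several -> one), each core -> intermediate ->
#: rare, followed by the four mixed-label ("varied") combinations.
DISTRIBUTION_CLASSES = (
    "collection core",
    "collection intermediate",
    "collection rare",
    "multi-lineage core",
    "multi-lineage intermediate",
    "multi-lineage rare",
    "lineage specific core",
    "lineage specific intermediate",
    "lineage specific rare",
    "core and intermediate",
    "core and rare",
    "intermediate and rare",
    "core, intermediate and rare",
)

_VARIED_BY_LABELSET = {
    frozenset({"core", "intermediate"}): "core and intermediate",
    frozenset({"core", "rare"}): "core and rare",
    frozenset({"intermediate", "rare"}): "intermediate and rare",
    frozenset({"core", "intermediate", "rare"}): "core, intermediate and rare",
}


def enumerate_classes() -> list[str]:
    """Return the 13 distribution-class names in canonical order."""
    return list(DISTRIBUTION_CLASSES)


def _as_fraction(x) -> Fraction:
    """Exact rational from a threshold given as float/str/Fraction.

    Floats are interpreted through their decimal repr so 0.95 means 95/100.
    """
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


@dataclass(frozen=True)
class Thresholds:
    """Frequency cut-offs for the within-lineage labels.

    A gene at within-lineage frequency f is labelled

    * ``absent``       if f = 0
    * ``rare``         if 0 < f < rare_max
    * ``intermediate`` if rare_max <= f < core_min
    * ``core``         if f >= core_min

    The half-open convention resolves the overlap of the nominal
    "up to 15 %" / "15-95 %" / "more than 95 %" bands at the two boundary
    points; both cut-offs are configurable so the strictly-greater reading
    of the core boundary is reachable (e.g. ``core_min=0.9500001``).
    Comparisons are exact: carrier counts are compared against rational
    cut-offs, never against rounded floating-point frequencies.
    """

    core_min: float = 0.95
    rare_max: float = 0.15
    min_lineage_size: int = 1

    def __post_init__(self) -> None:
        core = _as_fraction(self.core_min)
        rare = _as_fraction(self.rare_max)
        if not (0 < rare < core <= 1):
            raise ValidationError(
                f"need 0 < rare_max < core_min <= 1, got "
                f"rare_max={self.rare_max}, core_min={self.core_min}"
            )
        if self.min_lineage_size < 1:
            raise ValidationError("min_lineage_size must be >= 1")

    def core_cutoff(self, lineage_size: int) -> int:
        """Smallest carrier count labelled core in a lineage of this size."""
        c = _as_fraction(self.core_min) * lineage_size
        return math.ceil(c)

    def intermediate_cutoff(self, lineage_size: int) -> int:
        """Smallest carrier count labelled intermediate (not rare)."""
        c = _as_fraction(self.rare_max) * lineage_size
        return math.ceil(c)


def label_within_lineage(frequency: float, thresholds: Thresholds | None = None) -> str:
    """Label a single within-lineage frequency as core/intermediate/rare/absent."""
    thresholds = thresholds or Thresholds()
    if not 0 <= frequency <= 1:
        raise ValidationError(f"frequency must be in [0, 1], got {frequency}")
    f = _as_fraction(frequency)
    if f == 0:
        return "absent"
    if f >= _as_fraction(thresholds.core_min):
        return "core"
    if f >= _as_fraction(thresholds.rare_max):
        return "intermediate"
    return "rare"


@dataclass
class LineageFrequencyTable:
    """Per-(gene, lineage) carrier counts, frequencies and labels.

    Attributes
    ----------
    counts : DataFrame (genes x lineages) of carrier counts (int)
    sizes : Series mapping lineage -> number of genomes
    frequencies : DataFrame (genes x lineages) of counts / size (float)
    labels : DataFrame (genes x lineages) of within-lineage labels (str)
    thresholds : the Thresholds used for labelling
    """

    counts: pd.DataFrame
    sizes: pd.Series
    frequencies: pd.DataFrame
    labels: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def lineages(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


def _align_genomes(matrix: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    """Restrict the assignment to the matrix genomes, warning on drop-outs."""
    missing = [g for g in matrix.columns if g not in assignment.index]
    if missing:
        logger.warning(
            "%d genome(s) in the matrix have no lineage assignment and are "
            "dropped: %s%s",
            len(missing),
            ", ".join(missing[:5]),
            " ..." if len(missing) > 5 else "",
        )
    kept = [g for g in matrix.columns if g in assignment.index]
    if not kept:
        raise ConfigurationError("no matrix genome has a lineage assignment")
    return assignment.loc[kept]


def compute_lineage_frequencies(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    thresholds: Thresholds | None = None,
) -> LineageFrequencyTable:
    """Count carriers of each gene per lineage and label the frequencies.

    Parameters
    ----------
    matrix : genes x genomes presence/absence DataFrame with 0/1 values.
    assignment : Series mapping genome id -> lineage id.
    thresholds : frequency cut-offs; lineages with fewer than
        ``thresholds.min_lineage_size`` genomes are dropped with a warning.
    """
    thresholds = thresholds or Thresholds()
    assignment = _align_genomes(matrix, assignment)
    matrix = matrix[assignment.index]

    sizes = assignment.value_counts().sort_index()
    small = sizes[sizes < thresholds.min_lineage_size]
    if len(small):
        logger.warning(
            "dropping %d lineage(s) below min_lineage_size=%d: %s",
            len(small), thresholds.min_lineage_size, ", ".join(map(str, small.index)),
        )
        sizes = sizes[sizes >= thresholds.min_lineage_size]
    if sizes.empty:
        raise ConfigurationError(
            f"no lineage has >= {thresholds.min_lineage_size} genomes"
        )
    keep = assignment.isin(sizes.index)
    assignment = assignment[keep]
    matrix = matrix[assignment.index]

    # carriers per (gene, lineage): one matmul against the lineage indicator
    indicator = pd.get_dummies(assignment).astype(np.int64)  # genomes x lineages
    indicator = indicator[sizes.index]
    counts = matrix.astype(np.int64) @ indicator.loc[matrix.columns]
    freqs = counts / sizes

    core_cut = np.array([thresholds.core_cutoff(n) for n in sizes], dtype=np.int64)
    inter_cut = np.array(
        [thresholds.intermediate_cutoff(n) for n in sizes], dtype=np.int64
    )
    c = counts.to_numpy()
    lab = np.full(c.shape, "absent", dtype=object)
    lab[(c > 0) & (c < inter_cut)] = "rare"
    lab[(c >= inter_cut) & (c < core_cut)] = "intermediate"
    lab[c >= core_cut] = "core"
    labels = pd.DataFrame(lab, index=counts.index, columns=counts.columns)

    return LineageFrequencyTable(
        counts=counts, sizes=sizes, frequencies=freqs, labels=labels,
        thresholds=thresholds,
    )


def assign_distribution_class(labels: Iterable[str], n_total_lineages: int) -> str:
    """Map one gene's per-lineage labels to its distribution class.

    ``labels`` is the multiset of within-lineage labels over all analysed
    lineages (``absent`` entries included or omitted, both work as long as
    ``n_total_lineages`` is the analysed-lineage count).
    """
    labels = list(labels)
    bad = set(labels) - set(LABELS)
    if bad:
        raise ValidationError(f"unknown label(s): {sorted(bad)}")
    if n_total_lineages < 1:
        raise ValidationError("n_total_lineages must be >= 1")
    present = [l for l in labels if l != "absent"]
    if len(present) > n_total_lineages:
        raise ValidationError("more non-absent labels than lineages")
    label_set = frozenset(present)
    p = len(present)
    if p == 0:
        return ABSENT_CLASS
    if len(label_set) >= 2:
        return _VARIED_BY_LABELSET[label_set]
    (only,) = label_set
    if p == n_total_lineages:
        return f"collection {only}"
    if p == 1:
        return f"lineage specific {only}"
    return f"multi-lineage {only}"


@dataclass
class ClassificationTable:
    """Per-gene distribution classes plus the labels/frequencies behind them.

    ``table`` has one row per gene with columns ``distribution_class``,
    ``n_lineages_present``, ``n_core``, ``n_intermediate``, ``n_rare``.
    """

    table: pd.DataFrame
    frequencies: pd.DataFrame
    labels: pd.DataFrame
    sizes: pd.Series
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def classes(self) -> pd.Series:
        return self.table["distribution_class"]

    @property
    def lineages(self) -> list[str]:
        return list(self.labels.columns)

    def class_counts(self) -> pd.Series:
        """Number of genes per distribution class (sentinel excluded)."""
        counts = self.classes.value_counts()
        return counts.reindex(DISTRIBUTION_CLASSES, fill_value=0)


def classify_pangenome(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    thresholds: Thresholds | None = None,
) -> ClassificationTable:
    """Classify every gene of a presence/absence matrix into the 13 classes."""
    thresholds = thresholds or Thresholds()
    freq = compute_lineage_frequencies(matrix, assignment, thresholds)
    lab = freq.labels.to_numpy()
    n_core = (lab == "core").sum(axis=1)
    n_inter = (lab == "intermediate").sum(axis=1)
    n_rare = (lab == "rare").sum(axis=1)
    n_present = n_core + n_inter + n_rare
    n_total = freq.labels.shape[1]

    classes = np.empty(len(freq.gene_ids), dtype=object)
    mixed = ((n_core > 0).astype(int) + (n_inter > 0).astype(int)
             + (n_rare > 0).astype(int)) >= 2
    for i in range(len(classes)):
        if n_present[i] == 0:
            classes[i] = ABSENT_CLASS
        elif mixed[i]:
            key = frozenset(
                name for name, n in
                (("core", n_core[i]), ("intermediate", n_inter[i]), ("rare", n_rare[i]))
                if n > 0
            )
            classes[i] = _VARIED_BY_LABELSET[key]
        else:
            only = "core" if n_core[i] else ("intermediate" if n_inter[i] else "rare")
            if n_present[i] == n_total:
                classes[i] = f"collection {only}"
            elif n_present[i] == 1:
                classes[i] = f"lineage specific {only}"
            else:
                classes[i] = f"multi-lineage {only}"

    table = pd.DataFrame(
        {
            "distribution_class": classes,
            "n_lineages_present": n_present,
            "n_core": n_core,
            "n_intermediate": n_inter,
            "n_rare": n_rare,
        },
        index=pd.Index(freq.gene_ids, name="gene_id"),
    )
    return ClassificationTable(
        table=table,
        frequencies=freq.frequencies,
        labels=freq.labels,
        sizes=freq.sizes,
        thresholds=thresholds,
    )
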