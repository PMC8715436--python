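"""Inter-lineage gene sharing with phylogenetic and sample-size corrections.

Raw sharing counts (genes of chosen distribution classes carried by both
lineages of a pair) are confounded twice: closely related lineages share
genes by descent, and heavily sampled lineages accumulate more observed
rare genes.  The corrections mirror that: pairs closer than a patristic
distance threshold are excluded, and every lineage is repeatedly
subsampled to the same number of genomes before recounting, with the mean
over repeats as the corrected count.  Outlier lineages — those whose
corrected pair counts sit above the rest of the collection — are flagged
by rank-sum tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassificationTable, DISTRIBUTION_CLASSES
from .errors import ValidationError
from .phylo import lineage_presence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharingConfig:
    """Parameters of the corrected sharing analysis.

    ``distance_threshold`` (patristic) excludes by-descent sharing between
    close relatives; ``subsample_size`` genomes are drawn per lineage
    without replacement in each of ``n_repeats`` repeats; ``classes``
    selects the distribution classes counted (the mobile-gene signal lives
    in "intermediate and rare" by default).
    """

    distance_threshold: float = 0.15
    subsample_size: int = 20
    n_repeats: int = 40
    seed: int = 0
    classes: frozenset[str] = frozenset({"intermediate and rare"})

    def __post_init__(self) -> None:
        if self.distance_threshold < 0:
            raise ValidationError("distance_threshold must be >= 0")
        if self.subsample_size < 1:
            raise ValidationError("subsample_size must be >= 1")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        _check_classes(self.classes)


def _check_classes(classes) -> None:
    bad = set(classes) - set(DISTRIBUTION_CLASSES)
    if bad:
        raise ValidationError(
            f"unknown distribution class(es) {sorted(bad)}; valid names: "
            f"{list(DISTRIBUTION_CLASSES)}"
        )


def _class_genes(classification, classes) -> pd.Index:
    cls = (
        classification.classes
        if isinstance(classification, ClassificationTable)
        else pd.Series(classification)
    )
    return cls.index[cls.isin(set(classes))]


def shared_gene_counts(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    classification,
    classes=frozenset({"intermediate and rare"}),
) -> pd.DataFrame:
    """Symmetric lineage x lineage matrix counting genes of the selected
    classes present (>= 1 carrier) in both lineages of each pair.

    The diagonal holds the number of selected genes present in the lineage
    itself.
    """
    _check_classes(classes)
    genes = _class_genes(classification, classes)
    sub = matrix.loc[matrix.index.intersection(genes)]
    if len(assignment.index.intersection(matrix.columns)) == 0:
        raise ValidationError("no matrix genome has a lineage assignment")
    lineages = sorted(assignment.loc[assignment.index.intersection(matrix.columns)].unique())
    if sub.empty:
        z = np.zeros((len(lineages), len(lineages)), dtype=np.int64)
        return pd.DataFrame(z, index=lineages, columns=lineages)
    presence = lineage_presence(sub, assignment).reindex(columns=lineages, fill_value=0)
    p = presence.to_numpy().astype(np.int64)
    counts = p.T @ p
    return pd.DataFrame(counts, index=lineages, columns=lineages)


def phylo_filter(
    lineages, distances: pd.DataFrame, threshold: float = 0.15
) -> pd.DataFrame:
    """Boolean lineage x lineage mask: True where the patristic distance is
    >= ``threshold`` (diagonal always False)."""
    lineages = list(lineages)
    missing = [l for l in lineages if l not in distances.index or l not in distances.columns]
    if missing:
        raise ValidationError(f"lineage(s) missing from distance matrix: {missing}")
    d = distances.loc[lineages, lineages]
    mask = d.to_numpy() >= threshold
    np.fill_diagonal(mask, False)
    return pd.DataFrame(mask, index=lineages, columns=lineages)


@dataclass
class SharingResult:
    """Raw and corrected sharing counts for one collection.

    ``repeat_counts`` stacks the per-repeat subsampled count matrices
    (shape n_repeats x L x L) so Monte-Carlo error is recoverable.
    """

    lineages: list[str]
    raw_counts: pd.DataFrame
    corrected_mean: pd.DataFrame
    repeat_counts: np.ndarray
    config: SharingConfig
    retained_pairs: pd.DataFrame | None = None

    def pair_table(self, sizes: pd.Series | None = None) -> pd.DataFrame:
        """Long-form table of unordered lineage pairs with raw and
        corrected counts (and lineage sizes when supplied)."""
        rows = []
        L = self.lineages
        for i in range(len(L)):
            for j in range(i + 1, len(L)):
                retained = (
                    bool(self.retained_pairs.iat[i, j])
                    if self.retained_pairs is not None
                    else True
                )
                row = {
                    "lineage_1": L[i],
                    "lineage_2": L[j],
                    "raw_count": self.raw_counts.iat[i, j],
                    "corrected_count": self.corrected_mean.iat[i, j],
                    "retained": retained,
                }
                if sizes is not None:
                    row["min_size"] = min(sizes[L[i]], sizes[L[j]])
                rows.append(row)
        return pd.DataFrame(rows)


def subsampled_sharing(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    classification,
    config: SharingConfig | None = None,
    distances: pd.DataFrame | None = None,
) -> SharingResult:
    """Mean shared-gene counts over repeated equal-size subsampling.

    In every repeat, ``subsample_size`` genomes are drawn per lineage
    without replacement, shared genes of the selected classes are
    recounted on the reduced matrix (class labels are *not* recomputed —
    the full-data classification defines each gene's class), and the mean
    over repeats is reported.  Lineages with fewer genomes than the
    subsample size are excluded with a warning.  Draws are seeded per
    (seed, repeat) so results are bit-reproducible and repeat-order
    independent.
    """
    config = config or SharingConfig()
    genomes = assignment.index.intersection(matrix.columns)
    assignment = assignment.loc[genomes]
    sizes = assignment.value_counts()
    small = sorted(sizes.index[sizes < config.subsample_size])
    if small:
        logger.warning(
            "excluding %d lineage(s) smaller than subsample_size=%d: %s",
            len(small), config.subsample_size, ", ".join(map(str, small)),
        )
    lineages = sorted(sizes.index[sizes >= config.subsample_size])
    if len(lineages) < 2:
        raise ValidationError(
            "need >= 2 lineages at least as large as subsample_size"
        )
    assignment = assignment[assignment.isin(lineages)]

    genes = _class_genes(classification, config.classes)
    sub = matrix.loc[matrix.index.intersection(genes), assignment.index]
    raw = shared_gene_counts(matrix, assignment, classification, config.classes)
    raw = raw.loc[lineages, lineages]

    # genomes grouped per lineage, in deterministic (sorted) order
    members = {
        lin: sorted(assignment.index[assignment == lin]) for lin in lineages
    }
    values = sub.to_numpy()
    col_pos = {g: k for k, g in enumerate(sub.columns)}

    L = len(lineages)
    repeat_counts = np.zeros((config.n_repeats, L, L), dtype=np.int64)
    for r in range(config.n_repeats):
        rng = np.random.default_rng([config.seed, r])
        presence = np.zeros((values.shape[0], L), dtype=np.int64)
        for li, lin in enumerate(lineages):
            pick = rng.choice(len(members[lin]), size=config.subsample_size,
                              replace=False)
            cols = [col_pos[members[lin][k]] for k in pick]
            presence[:, li] = values[:, cols].any(axis=1)
        repeat_counts[r] = presence.T @ presence

    corrected = pd.DataFrame(
        repeat_counts.mean(axis=0), index=lineages, columns=lineages
    )
    retained = None
    if distances is not None:
        retained = phylo_filter(lineages, distances, config.distance_threshold)
    return SharingResult(
        lineages=lineages,
        raw_counts=raw,
        corrected_mean=corrected,
        repeat_counts=repeat_counts,
        config=config,
        retained_pairs=retained,
    )


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p (exact for small tie-free samples, normal
    approximation with tie correction otherwise); degenerate all-equal
    input gives p = 1 by convention."""
    if len(x) == 0 or len(y) == 0:
        return np.nan, 1.0
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def outlier_lineages(result: SharingResult) -> pd.DataFrame:
    """Test, per lineage, whether its corrected pair counts differ from
    the pair counts among all other lineages.

    For lineage i the comparison is its (phylogenetically retained) pair
    counts versus the retained pair counts not involving i, two-sided
    rank-sum, Benjamini-Hochberg adjusted across lineages.
    """
    L = result.lineages
    n = len(L)
    mask = (
        result.retained_pairs.to_numpy()
        if result.retained_pairs is not None
        else ~np.eye(n, dtype=bool)
    )
    counts = result.corrected_mean.to_numpy()
    iu = np.triu_indices(n, k=1)
    pair_ok = mask[iu]
    pair_i, pair_j = iu[0][pair_ok], iu[1][pair_ok]
    pair_vals = counts[pair_i, pair_j]
    if len(pair_vals) == 0:
        raise ValidationError("no retained lineage pairs to test")

    rows = []
    for li in range(n):
        mine = (pair_i == li) | (pair_j == li)
        stat, p = _ranksum_p(pair_vals[mine], pair_vals[~mine])
        rows.append({"lineage_id": L[li], "n_pairs": int(mine.sum()),
                     "statistic": stat, "p_value": p})
    out = pd.DataFrame(rows).set_index("lineage_id")
    out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def per_isolate_sharing(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    classification,
    classes=frozenset({"intermediate and rare"}),
) -> pd.Series:
    """Per-genome count of carried genes from the selected classes — the
    isolate-level view of mobile-gene load, for per-isolate group
    comparisons."""
    _check_classes(classes)
    genes = _class_genes(classification, classes)
    sub = matrix.loc[matrix.index.intersection(genes)]
    counts = sub.sum(axis=0).astype(np.int64)
    counts.name = "n_shared_class_genes"
    return counts.loc[counts.index.intersection(assignment.index)]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def sharing_vs_size_regression(
    result: SharingResult, sizes: pd.Series, use_corrected: bool = False
) -> RegressionResult:
    """OLS of log(shared count + 1) on the smaller lineage size of each
    pair (the +1 offset admits zero counts)."""
    table = result.pair_table(sizes=sizes)
    if result.retained_pairs is not None:
        table = table[table["retained"]]
    y = np.log1p(table["corrected_count" if use_corrected else "raw_count"].astype(float))
    x = table["min_size"].astype(float)
    if len(table) < 3:
        raise ValidationError("need >= 3 lineage pairs for a regression")
    if np.allclose(y, y.iloc[0]):
        # constant response: no variance to explain
        return RegressionResult(0.0, float(y.iloc[0]), 0.0, 1.0, len(table))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(table),
    )
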