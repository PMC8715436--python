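"""Functional-annotation summaries per distribution class.

Covers three summaries over an external annotation table (COG category,
free-text functional prediction, optional per-gene transfer probability):
a class x COG contingency table, sub-sentence mining of the free-text
predictions (all contiguous runs of >= 2 non-stopword tokens, counted per
class and merged so nested sub-sentences with nearly equal counts keep
only the longer, more specific phrase), and per-class order statistics of
the transfer probability.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from .classify import ClassificationTable
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Default ignored words: a small set of English function words plus a few
#: generic annotation fillers.  User-replaceable; no claim of completeness.
DEFAULT_STOPWORDS = frozenset({
    "a", "an", "the", "and", "or", "of", "in", "to", "for", "with", "by",
    "on", "at", "from", "as", "is", "its", "system",
})


def _classes_series(classification) -> pd.Series:
    if isinstance(classification, ClassificationTable):
        return classification.classes
    return pd.Series(classification)


def cog_class_summary(
    annotations: pd.DataFrame, classification
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate distribution class against COG category.

    Returns (counts, fractions); fractions are row-normalised per class.
    Genes classified but missing from the annotation table are counted
    under category ``'?'`` (no database match).
    """
    cls = _classes_series(classification)
    cats = annotations["cog_category"].reindex(cls.index)
    n_missing = int(cats.isna().sum())
    if n_missing:
        logger.warning("%d classified gene(s) lack an annotation; counted as '?'",
                       n_missing)
    cats = cats.fillna("?").replace("", "?")
    counts = pd.crosstab(cls, cats)
    counts.index.name = "distribution_class"
    counts.columns.name = "cog_category"
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return counts, fractions


def extract_subsentences(
    prediction: str, stopwords: Iterable[str] = DEFAULT_STOPWORDS
) -> set[str]:
    """All contiguous runs of >= 2 retained words from a free-text
    functional prediction.

    The text is lower-cased and whitespace-tokenised; stopwords are
    removed before runs are formed, so a run may bridge an elided word
    ("atp-binding component transport" from "...component of a transport
    system").  A prediction with fewer than two retained words yields
    nothing.
    """
    stop = {w.lower() for w in stopwords}
    words = [w for w in str(prediction).lower().split() if w not in stop]
    out: set[str] = set()
    for i in range(len(words)):
        for j in range(i + 2, len(words) + 1):
            out.add(" ".join(words[i:j]))
    return out


def count_subsentences(
    predictions_by_class: Mapping[str, Iterable[str]],
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
) -> dict[str, Counter]:
    """Count, per distribution class, how many predictions contain each
    sub-sentence."""
    out: dict[str, Counter] = {}
    for cls, predictions in predictions_by_class.items():
        counter: Counter = Counter()
        for text in predictions:
            counter.update(extract_subsentences(text, stopwords))
        out[cls] = counter
    return out


def _contains(longer: tuple[str, ...], shorter: tuple[str, ...]) -> bool:
    """Contiguous word-sequence containment (strictly longer)."""
    if len(shorter) >= len(longer):
        return False
    for k in range(len(longer) - len(shorter) + 1):
        if tuple(longer[k:k + len(shorter)]) == shorter:
            return True
    return False


def merge_subsentence_counts(counts: Mapping[str, int], merge_delta: int = 3) -> dict[str, int]:
    """Collapse nested sub-sentences with nearly equal counts.

    Where one sub-sentence's word sequence contains another's and their
    counts differ by at most ``merge_delta``, the shorter entry is dropped
    and the longer kept with its own count (the longer phrase carries the
    more specific information).  Entries are processed longest-first,
    which makes the operation deterministic and idempotent.
    """
    kept = dict(counts)
    order = sorted(kept, key=lambda s: (-len(s.split()), s))
    for long_s in order:
        if long_s not in kept:
            continue
        long_words = tuple(long_s.split())
        for short_s in [s for s in kept if s != long_s]:
            if _contains(long_words, tuple(short_s.split())) and \
                    abs(kept[long_s] - kept[short_s]) <= merge_delta:
                del kept[short_s]
    return kept


def count_and_merge(
    predictions_by_class: Mapping[str, Iterable[str]],
    merge_delta: int = 3,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
) -> pd.DataFrame:
    """Full sub-sentence pipeline: extract, count per class, merge.

    Returns a long-form DataFrame (distribution_class, subsentence, count)
    sorted by class and descending count.
    """
    merged = {
        cls: merge_subsentence_counts(counter, merge_delta)
        for cls, counter in count_subsentences(predictions_by_class, stopwords).items()
    }
    rows = [
        {"distribution_class": cls, "subsentence": s, "count": c}
        for cls, table in merged.items()
        for s, c in sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["distribution_class", "subsentence", "count"])


def transfer_probability_summary(
    annotations: pd.DataFrame, classification
) -> pd.DataFrame:
    """Per-class median and quartiles of the horizontal-transfer
    probability column; classes with no annotated gene appear as NaN."""
    if "transfer_probability" not in annotations.columns:
        raise ValidationError("annotation table has no transfer_probability column")
    cls = _classes_series(classification)
    prob = pd.to_numeric(annotations["transfer_probability"], errors="coerce")
    bad = prob[(prob < 0) | (prob > 1)]
    if len(bad):
        raise ValidationError(
            f"transfer probability outside [0, 1] for gene(s) "
            f"{bad.index.tolist()[:5]}"
        )
    joined = pd.DataFrame({"distribution_class": cls,
                           "p_transfer": prob.reindex(cls.index)}).dropna()
    if joined.empty:
        raise ValidationError("no gene has a transfer probability")
    g = joined.groupby("distribution_class")["p_transfer"]
    out = pd.DataFrame({
        "n": g.size(),
        "q1": g.quantile(0.25),
        "median": g.median(),
        "q3": g.quantile(0.75),
    })
    return out.reindex(sorted(cls.unique()))
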