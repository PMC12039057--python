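"""Retrieval evaluation arithmetic and genus-level source attribution.

Precision here is computed over retrieved features that carry an independent
reference annotation (the source publication reports this quantity as
"accuracy"); recall denominators likewise count only reference-annotated
relevant items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "AnnotatedRetrieval",
    "retrieval_metrics",
    "merge_duplicate_samples",
    "genus_attribution",
]


@dataclass(frozen=True)
class AnnotatedRetrieval:
    """Counts for evaluating a query against reference annotations.

    retrieved_annotated: retrieved features carrying a reference annotation.
    true_positive: those whose annotation matches the target skeleton(s).
    relevant_total: all reference-annotated features of the target
    skeleton(s) present in the dataset.
    """

    true_positive: int
    retrieved_annotated: int
    relevant_total: int

    def __post_init__(self) -> None:
        if min(self.true_positive, self.retrieved_annotated, self.relevant_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.true_positive > self.retrieved_annotated:
            raise ValueError("true_positive cannot exceed retrieved_annotated")
        if self.true_positive > self.relevant_total:
            raise ValueError("true_positive cannot exceed relevant_total")


def retrieval_metrics(r: AnnotatedRetrieval) -> tuple[float | None, float | None]:
    """(precision %, recall %) at two decimals; ``None`` marks an undefined
    metric (zero denominator), never 0."""
    precision = (
        round(100.0 * r.true_positive / r.retrieved_annotated, 2)
        if r.retrieved_annotated > 0
        else None
    )
    recall = (
        round(100.0 * r.true_positive / r.relevant_total, 2)
        if r.relevant_total > 0
        else None
    )
    return precision, recall


def merge_duplicate_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Average columns with identical (plant, genus) labels.

    ``table`` rows are feature ids; columns are a 2-level MultiIndex
    (plant name, genus); cells are ion intensities.
    """
    if not isinstance(table.columns, pd.MultiIndex) or table.columns.nlevels != 2:
        raise ValueError("table columns must be a (plant, genus) MultiIndex")
    if (table.values < 0).any():
        raise ValueError("ion intensities must be non-negative")
    return table.T.groupby(level=[0, 1], sort=True).mean().T


def genus_attribution(
    table: pd.DataFrame, tagged: Sequence[str]
) -> dict[str, float]:
    """Per-genus percentage of total ion intensity across tagged features.

    Duplicate sample columns (same plant) are first merged by arithmetic
    mean; shares sum to 100.
    """
    tagged = list(tagged)
    missing = [t for t in tagged if t not in table.index]
    if missing:
        raise KeyError(f"tagged feature ids missing from table: {missing}")
    merged = merge_duplicate_samples(table)
    sub = merged.loc[tagged]
    by_genus = sub.T.groupby(level=1).sum().T.sum(axis=0)
    total = float(by_genus.sum())
    if total <= 0:
        raise ValueError("tagged features carry no intensity")
    return {genus: 100.0 * float(v) / total for genus, v in by_genus.items()}
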