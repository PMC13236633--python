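"""Matrisome annotation: classify proteins into divisions/categories and
summarize category distributions.

Every protein is labeled; anything absent from the reference is
non-matrisome by contract (never an error), so matrisome + non-matrisome
always partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import (
    ASSOCIATED_CATEGORIES,
    CORE_CATEGORIES,
    NON_MATRISOME,
    MatrisomeReference,
    ProteinQuantTable,
)

logger = logging.getLogger(__name__)

__all__ = ["CategoryDistribution", "annotate_proteins", "category_distribution"]

ALL_CATEGORIES = CORE_CATEGORIES + ASSOCIATED_CATEGORIES


@dataclass
class CategoryDistribution:
    """Counts of matrisome proteins per category.

    ``core_fraction`` is the share of core-matrisome proteins (ECM
    glycoproteins + collagens + proteoglycans) among all matrisome proteins
    counted; it is None for an empty input.  Non-matrisome proteins are
    excluded from ``counts`` but reported in ``n_non_matrisome``.
    """

    counts: dict[str, int]
    total: int
    core_fraction: float | None
    n_non_matrisome: int = 0

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.total

    @property
    def core_count(self) -> int:
        return sum(self.counts.get(c, 0) for c in CORE_CATEGORIES)

    @property
    def associated_count(self) -> int:
        return sum(self.counts.get(c, 0) for c in ASSOCIATED_CATEGORIES)


def annotate_proteins(table: ProteinQuantTable, ref: MatrisomeReference) -> ProteinQuantTable:
    """Label every protein with its matrisome division and category.

    Returns the same table with an ``annotation`` DataFrame attached
    (columns ``division`` and ``category``, indexed like the intensities).
    """
    divisions, categories = [], []
    for sym in table.gene_symbol:
        division, category = ref.lookup(sym)
        divisions.append(division)
        categories.append(category)
    table.annotation = pd.DataFrame(
        {"division": divisions, "category": categories}, index=table.protein_ids
    )
    n_matri = int((table.annotation["division"] != NON_MATRISOME).sum())
    logger.info(
        "annotated %d proteins: %d matrisome, %d non-matrisome",
        len(table.protein_ids),
        n_matri,
        len(table.protein_ids) - n_matri,
    )
    return table


def category_distribution(
    annotated: pd.DataFrame | Iterable[tuple[str, str]]
) -> CategoryDistribution:
    """Distribution of a set of annotated proteins across matrisome categories.

    Accepts either the ``annotation`` DataFrame of a table subset or an
    iterable of (division, category) pairs.
    """
    if isinstance(annotated, pd.DataFrame):
        pairs = list(zip(annotated["division"], annotated["category"]))
    else:
        pairs = list(annotated)
    counts = {c: 0 for c in ALL_CATEGORIES}
    n_non = 0
    for division, category in pairs:
        if division == NON_MATRISOME:
            n_non += 1
        else:
            counts[category] += 1
    counts = {c: n for c, n in counts.items() if n > 0}
    total = sum(counts.values())
    if total == 0:
        return CategoryDistribution(counts={}, total=0, core_fraction=None, n_non_matrisome=n_non)
    core = sum(counts.get(c, 0) for c in CORE_CATEGORIES)
    return CategoryDistribution(
        counts=counts, total=total, core_fraction=core / total, n_non_matrisome=n_non
    )


def write_annotated_table(table: ProteinQuantTable, path) -> None:
    """Annotated table as TSV with added division/category columns."""
    if table.annotation is None:
        raise ValueError("table is not annotated; call annotate_proteins first")
    out = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "gene_symbol": table.gene_symbol.values,
            "division": table.annotation["division"].values,
            "category": table.annotation["category"].values,
        }
    )
    out.to_csv(path, sep="\t", index=False)
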