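"""Identification filters and the k-of-n replicate presence rule.

A protein enters a model's matrisome profile only when it passes the
identification filters (>= 2 peptides, protein FDR < 1% by default), is
matrisome-annotated, and is detected in at least k of that model's n
biological replicates (default 3 of 5).  A tumor-type profile is the
intersection of its two model profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import NON_MATRISOME, ProteinQuantTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionMatrix",
    "MatrisomeProfile",
    "apply_identification_filters",
    "detection_matrix",
    "model_profile",
    "type_profile",
]


@dataclass
class DetectionMatrix:
    """Boolean protein x sample presence calls plus the thresholds used."""

    detected: pd.DataFrame  # bool, same shape as intensities
    min_peptides: int
    max_protein_fdr: float
    table: ProteinQuantTable = field(repr=False)


@dataclass
class MatrisomeProfile:
    """Set of matrisome proteins (gene symbols) credited to a model or tumor type."""

    label: str
    level: str  # "model" or "tumor_type"
    proteins: frozenset[str]
    rule: tuple[int, int]  # (k, n)
    tumor_type: str | None = None

    def __len__(self) -> int:
        return len(self.proteins)


def apply_identification_filters(
    table: ProteinQuantTable,
    min_peptides: int = 2,
    max_protein_fdr: float = 0.01,
) -> ProteinQuantTable:
    """Keep proteins with peptide_count >= min_peptides and protein FDR
    strictly below max_protein_fdr."""
    keep = (table.peptide_count >= min_peptides) & (table.protein_fdr < max_protein_fdr)
    removed = int((~keep).sum())
    logger.info(
        "identification filters (>=%d peptides, FDR<%g): removed %d of %d proteins",
        min_peptides,
        max_protein_fdr,
        removed,
        len(keep),
    )
    return table.subset(table.protein_ids[keep])


def detection_matrix(table: ProteinQuantTable) -> DetectionMatrix:
    """Presence calls: detected(p, s) iff the intensity is non-missing.

    Zero intensities were already mapped to missing at read time, so a
    detected call always implies a positive measured intensity.
    """
    return DetectionMatrix(
        detected=table.intensities.notna(),
        min_peptides=0,
        max_protein_fdr=1.0,
        table=table,
    )


def model_profile(dm: DetectionMatrix, model: str, k: int = 3) -> MatrisomeProfile:
    """Matrisome proteins detected in >= k of the model's n replicates."""
    table = dm.table
    if table.annotation is None:
        raise ValidationError("table must be annotated before profiling")
    samples = table.samples_of_model(model)  # raises KeyError for unknown model
    n = len(samples)
    if n < k:
        raise ValidationError(f"model {model!r} has only {n} replicates but k={k}")
    hits = dm.detected[samples].sum(axis=1) >= k
    is_matrisome = table.annotation["division"] != NON_MATRISOME
    ids = table.protein_ids[hits & is_matrisome]
    symbols = frozenset(s.upper() for s in table.gene_symbol.loc[ids])
    return MatrisomeProfile(
        label=model,
        level="model",
        proteins=symbols,
        rule=(k, n),
        tumor_type=table.tumor_type_of_model(model),
    )


def type_profile(
    profile_a: MatrisomeProfile, profile_b: MatrisomeProfile, tumor_type: str
) -> MatrisomeProfile:
    """Tumor-type profile: proteins present in both model profiles of one type."""
    for prof in (profile_a, profile_b):
        if prof.tumor_type != tumor_type:
            raise ValidationError(
                f"profile {prof.label!r} belongs to tumor type {prof.tumor_type!r}, "
                f"not {tumor_type!r}"
            )
    k = max(profile_a.rule[0], profile_b.rule[0])
    n = min(profile_a.rule[1], profile_b.rule[1])
    return MatrisomeProfile(
        label=tumor_type,
        level="tumor_type",
        proteins=profile_a.proteins & profile_b.proteins,
        rule=(k, n),
        tumor_type=tumor_type,
    )
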