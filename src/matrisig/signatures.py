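"""Set algebra across tumor-type profiles: shared matrisome and
type-exclusive signatures with per-category summaries.

Proteins are compared by case-insensitive gene symbol, since signatures are
reported as gene symbols rather than accessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import CategoryDistribution, category_distribution
from .detection import MatrisomeProfile
from .io import MatrisomeReference, ValidationError

__all__ = ["SignatureResult", "exclusive_signatures", "signature_category_split"]


@dataclass
class SignatureResult:
    """Shared and exclusive protein sets between two tumor-type profiles.

    Invariants: the three sets are pairwise disjoint and
    |profile| = |exclusive| + |shared| on each side.
    """

    label_a: str
    label_b: str
    shared: frozenset[str]
    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]
    summary_shared: CategoryDistribution | None = None
    summary_a: CategoryDistribution | None = None
    summary_b: CategoryDistribution | None = None
    provenance: dict | None = None

    def venn_counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            f"exclusive_{self.label_a}": len(self.exclusive_a),
            f"exclusive_{self.label_b}": len(self.exclusive_b),
        }

    def write(self, directory: str | Path, ref: MatrisomeReference) -> None:
        """Signature TSV (gene_symbol, division, category, membership) and
        proportional-Venn counts JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for membership, members in (
            ("shared", self.shared),
            (f"exclusive_{self.label_a}", self.exclusive_a),
            (f"exclusive_{self.label_b}", self.exclusive_b),
        ):
            for sym in sorted(members):
                division, category = ref.lookup(sym)
                rows.append(
                    {
                        "gene_symbol": sym,
                        "division": division,
                        "category": category,
                        "membership": membership,
                    }
                )
        pd.DataFrame(rows).to_csv(directory / "signatures.tsv", sep="\t", index=False)
        with open(directory / "venn_counts.json", "w") as fh:
            json.dump(self.venn_counts(), fh, indent=2, sort_keys=True)


def exclusive_signatures(
    profile_a: MatrisomeProfile,
    profile_b: MatrisomeProfile,
    ref: MatrisomeReference | None = None,
) -> SignatureResult:
    """Shared = A ∩ B; exclusive_a = A \\ B; exclusive_b = B \\ A.

    When a reference is given, per-set category summaries are attached.
    """
    shared = profile_a.proteins & profile_b.proteins
    excl_a = profile_a.proteins - profile_b.proteins
    excl_b = profile_b.proteins - profile_a.proteins
    result = SignatureResult(
        label_a=profile_a.label,
        label_b=profile_b.label,
        shared=frozenset(shared),
        exclusive_a=frozenset(excl_a),
        exclusive_b=frozenset(excl_b),
        provenance={
            "rule_a": profile_a.rule,
            "rule_b": profile_b.rule,
            "size_a": len(profile_a),
            "size_b": len(profile_b),
        },
    )
    if ref is not None:
        result.summary_shared = category_distribution(_pairs(shared, ref))
        result.summary_a = category_distribution(_pairs(excl_a, ref))
        result.summary_b = category_distribution(_pairs(excl_b, ref))
    return result


def _pairs(symbols, ref: MatrisomeReference):
    return [ref.lookup(sym) for sym in symbols]


def signature_category_split(
    signature: frozenset[str] | set[str], ref: MatrisomeReference
) -> tuple[int, int, dict[str, int]]:
    """(core count, matrisome-associated count, per-category counts) for a
    signature.  Signatures are matrisome by construction, so an unannotated
    member is an error rather than a silent non-matrisome label."""
    unknown = sorted(sym for sym in signature if sym not in ref)
    if unknown:
        raise ValidationError(f"signature members not in matrisome reference: {unknown[:5]}")
    dist = category_distribution(_pairs(signature, ref))
    return dist.core_count, dist.associated_count, dict(dist.counts)
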