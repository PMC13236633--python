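"""Label-free differential abundance between tumor types and the combined
(exclusive + differential) signatures.

The quantitative comparison runs on normalized total precursor / LFQ
intensities: per-sample totals are equalized (to the median raw sample sum),
shared proteins are tested with an unpaired two-sided t test, and a protein
is called differential when p < alpha and its hi/lo abundance ratio moves by
at least the fold thresholds (default +/-20%, i.e. ratio >= 1.2 or <= 0.8).
Tests run on the raw normalized scale by default, matching total-precursor-
intensity quantification practice; a log2 option is available.  Missing
values are excluded pairwise (no imputation); a protein needs at least two
values per group to be testable.  No multiple-testing correction is applied
to the calls; a Benjamini-Hochberg q column is emitted for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuantTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "CombinedSignature",
    "normalize_intensities",
    "student_t_test",
    "differential_proteins",
    "combined_signature",
]


def normalize_intensities(table: ProteinQuantTable, method: str = "total_sum") -> ProteinQuantTable:
    """Equalize per-sample intensity totals.

    ``total_sum`` scales every sample so its (non-missing) intensity sum
    equals the median of the raw per-sample sums; ``median_ratio`` scales by
    the median per-sample ratio to a reference profile (DESeq-style);
    ``none`` is the identity.  Missing values stay missing.
    """
    if method == "none":
        return table
    inten = table.intensities
    sums = inten.sum(axis=0, skipna=True)
    if (sums == 0).any():
        empty = list(sums.index[sums == 0])
        raise ValidationError(f"all-missing sample(s): {empty}")
    if method == "total_sum":
        target = float(np.median(sums.to_numpy()))
        factors = target / sums
    elif method == "median_ratio":
        reference = inten.mean(axis=1, skipna=True)
        ratios = inten.div(reference, axis=0)
        factors = 1.0 / ratios.median(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    scaled = inten.mul(factors, axis=1)
    out = table.subset(table.protein_ids)
    out.intensities = scaled
    out.annotation = table.annotation
    return out


def student_t_test(x, y, variant: str = "student") -> tuple[float, float]:
    """Unpaired two-sided t test.

    ``student`` pools variances (df = n_x + n_y - 2); ``welch`` uses the
    Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t test needs >= 2 non-missing values per group")
    if variant == "student":
        t, p = stats.ttest_ind(x, y, equal_var=True)
    elif variant == "welch":
        t, p = stats.ttest_ind(x, y, equal_var=False)
    else:
        raise ValueError(f"unknown t-test variant: {variant!r}")
    return float(t), float(p)


@dataclass
class DifferentialResult:
    """Per-protein differential-abundance table between two tumor types.

    ``table`` columns: gene_symbol, category, mean_lo, mean_hi, ratio
    (mean_hi / mean_lo), log2_ratio, t, p, bh_q, call.  ``call`` is
    ``up_in_hi`` iff p < alpha and ratio >= up threshold, ``up_in_lo`` iff
    p < alpha and ratio <= down threshold, else ``unchanged``.
    Untestable proteins (fewer than two values in a group) are reported
    separately in ``untestable``.
    """

    table: pd.DataFrame
    alpha: float
    up_threshold: float
    down_threshold: float
    group_lo: str
    group_hi: str
    untestable: list[str] = field(default_factory=list)

    def called(self, call: str) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["call"] == call, "gene_symbol"])

    @property
    def up_in_hi(self) -> frozenset[str]:
        return self.called("up_in_hi")

    @property
    def up_in_lo(self) -> frozenset[str]:
        return self.called("up_in_lo")

    def write(self, path) -> None:
        """Volcano TSV: gene_symbol, category, means, log2 ratio, t, p, q, call."""
        self.table.to_csv(path, sep="\t", index=False)


def differential_proteins(
    table: ProteinQuantTable,
    shared: frozenset[str] | set[str],
    group_lo: str = "CD8lo",
    group_hi: str = "CD8hi",
    alpha: float = 0.05,
    up: float = 1.2,
    down: float = 0.8,
    variant: str = "student",
    log2_transform: bool = False,
) -> DifferentialResult:
    """Test shared proteins for differential abundance between tumor types.

    ``table`` should already be normalized.  ``shared`` holds uppercase gene
    symbols; every member must be present in the table.
    """
    symbols_upper = table.gene_symbol.str.upper()
    present = set(symbols_upper)
    missing = sorted(set(shared) - present)
    if missing:
        raise ValidationError(f"shared proteins absent from table: {missing[:5]}")

    lo_samples = table.samples_of_type(group_lo)
    hi_samples = table.samples_of_type(group_hi)

    rows, untestable = [], []
    for pid in table.protein_ids:
        sym = symbols_upper.loc[pid]
        if sym not in shared:
            continue
        lo_vals = table.intensities.loc[pid, lo_samples].to_numpy(dtype=float)
        hi_vals = table.intensities.loc[pid, hi_samples].to_numpy(dtype=float)
        lo_vals = lo_vals[~np.isnan(lo_vals)]
        hi_vals = hi_vals[~np.isnan(hi_vals)]
        if len(lo_vals) < 2 or len(hi_vals) < 2:
            untestable.append(sym)
            continue
        mean_lo = float(np.mean(lo_vals))
        mean_hi = float(np.mean(hi_vals))
        ratio = mean_hi / mean_lo if mean_lo > 0 else np.inf
        if log2_transform:
            t, p = student_t_test(np.log2(lo_vals), np.log2(hi_vals), variant=variant)
        else:
            t, p = student_t_test(lo_vals, hi_vals, variant=variant)
        category = (
            table.annotation.loc[pid, "category"] if table.annotation is not None else "none"
        )
        rows.append(
            {
                "gene_symbol": sym,
                "category": category,
                "mean_lo": mean_lo,
                "mean_hi": mean_hi,
                "ratio": ratio,
                "log2_ratio": float(np.log2(ratio)) if ratio > 0 else np.nan,
                "t": t,
                "p": p,
            }
        )

    result = pd.DataFrame(rows)
    if len(result):
        result["bh_q"] = multipletests(result["p"], method="fdr_bh")[1]
        sig = result["p"] < alpha
        call = np.where(
            sig & (result["ratio"] >= up),
            "up_in_hi",
            np.where(sig & (result["ratio"] <= down), "up_in_lo", "unchanged"),
        )
        result["call"] = call
    else:
        result = pd.DataFrame(
            columns=[
                "gene_symbol", "category", "mean_lo", "mean_hi", "ratio",
                "log2_ratio", "t", "p", "bh_q", "call",
            ]
        )
    if untestable:
        logger.info("differential abundance: %d untestable proteins", len(untestable))
    return DifferentialResult(
        table=result,
        alpha=alpha,
        up_threshold=up,
        down_threshold=down,
        group_lo=group_lo,
        group_hi=group_hi,
        untestable=untestable,
    )


@dataclass
class CombinedSignature:
    """Exclusive proteins plus differential proteins called toward one type,
    with a per-protein source tag."""

    label: str
    proteins: frozenset[str]
    source: dict[str, str]  # gene -> {exclusive, differential}

    def __len__(self) -> int:
        return len(self.proteins)


def combined_signature(
    exclusive: frozenset[str] | set[str],
    diff: DifferentialResult,
    direction: str,
    label: str | None = None,
) -> CombinedSignature:
    """Union of a type-exclusive set and the differential proteins called
    toward that type (``direction`` in {'lo', 'hi'})."""
    if direction == "lo":
        diff_set = diff.up_in_lo
        label = label or diff.group_lo
    elif direction == "hi":
        diff_set = diff.up_in_hi
        label = label or diff.group_hi
    else:
        raise ValueError(f"direction must be 'lo' or 'hi', got {direction!r}")
    source = {sym: "exclusive" for sym in exclusive}
    for sym in diff_set:
        source.setdefault(sym, "differential")
    return CombinedSignature(
        label=label, proteins=frozenset(exclusive) | diff_set, source=source
    )
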