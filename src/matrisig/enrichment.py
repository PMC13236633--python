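"""Single-sample gene set enrichment (ssGSEA), score correlations, and a
generic hypergeometric overrepresentation test.

The ssGSEA score follows the summed weighted-ECDF-difference convention:
within each sample, genes are ranked by expression (average ranks on ties);
walking down the ranking, the running weighted ECDF of in-set genes (weights
rank^alpha, alpha = 0.25 by default) is compared with the unweighted ECDF of
out-of-set genes, and the differences are summed over all positions.  Being
rank-based, the score is invariant under any strictly monotone transform of
a sample's expression values.  Tie groups contribute their tie-averaged
positions, which makes the score of an all-constant sample exactly zero.

With tie-averaged ascending ranks r_g (1..N) the summed ECDF difference
collapses to a closed form used here:

    score = sum_{g in S} r_g^alpha * r_g / W  -  sum_{g not in S} r_g / (N - m)

with W = sum_{g in S} r_g^alpha, m = |S|.  The test suite checks this
against a direct double-loop ECDF summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, ValidationError

__all__ = [
    "SampleScoreVector",
    "ssgsea_score",
    "ssgsea_score_matrix",
    "signature_ctl_correlation",
    "overrepresentation_test",
]


@dataclass
class SampleScoreVector:
    """Per-sample enrichment scores for one gene set."""

    gene_set: str
    scores: pd.Series  # index: samples
    alpha: float
    normalized: bool

    def __len__(self) -> int:
        return len(self.scores)


def _single_sample_score(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    n = len(values)
    m = int(in_set.sum())
    ranks = stats.rankdata(values, method="average")  # ascending, ties averaged
    weights = ranks[in_set] ** alpha
    w_total = weights.sum()
    in_term = float((weights * ranks[in_set]).sum() / w_total)
    out_term = float(ranks[~in_set].sum() / (n - m))
    return in_term - out_term


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = True,
) -> SampleScoreVector:
    """ssGSEA score of one gene set across all samples.

    Requires at least two set members present in the matrix and a non-empty
    complement.  When ``normalize`` is on, scores are divided by their range
    (max - min) across the samples of this matrix; single-sample calls should
    disable it (the range of one value is zero).
    """
    gene_index = pd.Index([g.upper() for g in expr.genes])
    member_mask = gene_index.isin({g.upper() for g in gene_set.members})
    n_overlap = int(member_mask.sum())
    if n_overlap < 2:
        missing = sorted({g.upper() for g in gene_set.members} - set(gene_index))
        raise ValidationError(
            f"gene set {gene_set.name!r} overlaps the matrix in {n_overlap} gene(s); "
            f"need >= 2 (missing e.g. {missing[:5]})"
        )
    if n_overlap == len(gene_index):
        raise ValidationError(
            f"gene set {gene_set.name!r} covers every gene in the matrix; "
            "the out-of-set ECDF is undefined"
        )
    mat = expr.values.to_numpy(dtype=float)
    raw = np.array(
        [_single_sample_score(mat[:, j], member_mask, alpha) for j in range(mat.shape[1])]
    )
    if normalize:
        span = raw.max() - raw.min()
        if span > 0:
            raw = raw / span
    return SampleScoreVector(
        gene_set=gene_set.name,
        scores=pd.Series(raw, index=expr.samples, name=gene_set.name),
        alpha=alpha,
        normalized=normalize,
    )


def ssgsea_score_matrix(
    expr: ExpressionMatrix,
    gene_sets,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Sample x gene-set score table for a collection of gene sets."""
    cols = {}
    for gs in gene_sets:
        cols[gs.name] = ssgsea_score(expr, gs, alpha=alpha, normalize=normalize).scores
    return pd.DataFrame(cols)


def signature_ctl_correlation(
    expr: ExpressionMatrix,
    hot_set: GeneSet,
    cold_set: GeneSet,
    ctl_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of ssGSEA score vectors for the hot
    matrisome, cold matrisome and cytotoxic-lymphocyte gene sets."""
    if len(expr.samples) < 3:
        raise ValidationError("correlation needs at least 3 samples")
    sets = [hot_set, cold_set, ctl_set]
    scores = {gs.name: ssgsea_score(expr, gs, alpha=alpha, normalize=normalize).scores
              for gs in sets}
    names = [gs.name for gs in sets]
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            r = stats.spearmanr(scores[a], scores[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return rho


def overrepresentation_test(
    query: set[str] | frozenset[str],
    annotation: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> tuple[int, float]:
    """Hypergeometric overrepresentation of ``annotation`` in ``query``.

    Returns (overlap k, one-sided p = P[X >= k]) for X hypergeometric with
    population |universe|, |annotation| successes and |query| draws.  Both
    query and annotation must be subsets of the universe.
    """
    query, annotation, universe = set(query), set(annotation), set(universe)
    if not query <= universe:
        raise ValidationError(f"query not a subset of universe: {sorted(query - universe)[:5]}")
    if not annotation <= universe:
        raise ValidationError(
            f"annotation not a subset of universe: {sorted(annotation - universe)[:5]}"
        )
    k = len(query & annotation)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(annotation), len(query)))
    return k, min(p, 1.0)
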