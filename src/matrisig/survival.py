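"""Quartile stratification, Kaplan-Meier estimation, log-rank testing and
Cox proportional-hazards fitting, implemented from their defining formulas.

The Cox model follows a Model/Results layout: ``CoxPH`` is built from a
``SurvivalTable`` (or arrays) and ``fit()`` returns a ``CoxResults`` carrying
coefficients, standard errors, hazard ratios, Wald tests and a ``summary()``
table.  The partial likelihood is maximized by Newton-Raphson with
step-halving; tied event times use the Efron correction by default
(Breslow available), and Efron and Breslow coincide exactly on tie-free
data.

``signature_score_survival`` composes the pipeline's downstream analysis:
ssGSEA score -> quartile stratification (high = upper quartile, low = lower
quartile, middle half excluded) -> Kaplan-Meier curves, log-rank test, and a
Cox fit of high-vs-low adjusted for a stromal-content covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ssgsea_score
from .io import ExpressionMatrix, GeneSet, SurvivalTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxPH",
    "CoxResults",
    "quartile_stratify",
    "km_estimate",
    "logrank_test",
    "signature_score_survival",
    "ScoreSurvivalResult",
]


# ---------------------------------------------------------------------------
# Quartile stratification
# ---------------------------------------------------------------------------

def quartile_stratify(values) -> np.ndarray:
    """Label each patient ``high`` (value >= Q3), ``low`` (value <= Q1) or
    ``mid``.

    Quartiles use the linear-interpolation quantile rule (numpy default,
    R type 7).  Boundary values are inclusive on both sides.  At least four
    patients are required, and an all-constant vector is a degenerate
    stratification error.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValidationError("quartile stratification needs >= 4 patients")
    if np.isnan(values).any():
        raise ValidationError("quartile stratification got NaN values")
    if np.all(values == values[0]):
        raise ValidationError("all values identical: degenerate stratification")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    labels = np.full(len(values), "mid", dtype=object)
    labels[values >= q3] = "high"
    labels[values <= q1] = "low"
    return labels


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate.

    At each distinct event time: number at risk, number of events, and
    S(t) = prod_{t_i <= t} (1 - d_i / n_i).  Subjects censored exactly at an
    event time count as at risk through that time.  S is non-increasing,
    S(0) = 1, and with no censoring S equals one minus the empirical CDF.
    """

    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "events": self.n_events,
                "survival": self.survival,
                "group": self.label,
            }
        )


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate from follow-up times and event
    indicators (1 = death observed, 0 = censored)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("empty survival input")
    if len(times) != len(events):
        raise ValidationError("times and events differ in length")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    distinct_event_times = np.unique(times[events == 1])
    n_risk, n_events, survival = [], [], []
    s = 1.0
    for t in distinct_event_times:
        at_risk = int(np.sum(times >= t))
        deaths = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - deaths / at_risk
        n_risk.append(at_risk)
        n_events.append(deaths)
        survival.append(s)
    return KMCurve(
        event_times=distinct_event_times,
        n_risk=np.asarray(n_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
        survival=np.asarray(survival, dtype=float),
        censor_times=np.sort(times[events == 0]),
        label=label,
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """K-sample log-rank test.

    At every distinct event time the observed per-group event counts are
    compared with their expectation under the hypergeometric distribution of
    events across groups; the summed observed-minus-expected vector and its
    summed covariance give a chi-square statistic with (k - 1) degrees of
    freedom.  Returns (statistic, df, p).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(times) != len(events) or len(times) != len(groups):
        raise ValidationError("times, events and groups must have equal length")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank test needs >= 2 groups")
    for lab in labels:
        if not np.any(groups == lab):
            raise ValidationError(f"group {lab!r} has no members")
    if events.sum() == 0:
        raise ValidationError("log-rank test needs >= 1 event")

    k = len(labels)
    group_idx = np.array([np.searchsorted(labels, g) for g in groups])
    observed = np.zeros(k)
    expected = np.zeros(k)
    # covariance of the first k-1 components of (O - E)
    cov = np.zeros((k - 1, k - 1))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int(((times == t) & (events == 1)).sum())
        n_gj = np.bincount(group_idx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(
            group_idx[(times == t) & (events == 1)], minlength=k
        ).astype(float)
        observed += d_gj
        expected += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj[: k - 1] / n_j
            hyper = d_j * (n_j - d_j) / (n_j - 1)
            cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[: k - 1]
    try:
        stat = float(diff @ np.linalg.solve(cov, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(cov) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class CoxPH:
    """Cox proportional-hazards model on a :class:`SurvivalTable`.

    Parameters
    ----------
    table:
        Survival data; ``time`` and ``event`` columns are used.
    covariates:
        Names of covariate columns to include, in order.  The conventional
        downstream model is a high-vs-low stratum indicator (low quartile as
        the reference level, coded 0) plus ``stromal_score``.
    """

    def __init__(self, table: SurvivalTable, covariates: list[str]):
        if not covariates:
            raise ValidationError("CoxPH needs at least one covariate")
        missing = [c for c in covariates if c not in table.data.columns]
        if missing:
            raise ValidationError(f"covariates absent from table: {missing}")
        self.table = table
        self.covariates = list(covariates)
        self.time = table.time
        self.event = table.event
        self.X = np.column_stack([table.covariate(c) for c in covariates])
        if int(self.event.sum()) < 2:
            raise ValidationError("Cox fit needs >= 2 events")
        self._check_condition()

    @classmethod
    def from_arrays(cls, time, event, X, names: list[str] | None = None) -> "CoxPH":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(time):
            X = X.T
        names = names or [f"x{i}" for i in range(X.shape[1])]
        data = pd.DataFrame(X, columns=names)
        data["time"] = np.asarray(time, dtype=float)
        data["event"] = np.asarray(event, dtype=int)
        return cls(SurvivalTable(data=data), names)

    def _check_condition(self) -> None:
        centered = self.X - self.X.mean(axis=0)
        stds = centered.std(axis=0)
        if (stds == 0).any():
            degenerate = [c for c, s in zip(self.covariates, stds) if s == 0]
            raise ValidationError(f"constant covariate(s): {degenerate}")
        corr = np.corrcoef(centered, rowvar=False)
        corr = np.atleast_2d(corr)
        if np.linalg.cond(corr) > 1e8:
            raise ValidationError("covariates are (near-)collinear")

    # -- partial likelihood ---------------------------------------------
    def _prepare(self):
        order = np.argsort(self.time, kind="stable")
        t = self.time[order]
        d = self.event[order]
        X = self.X[order]
        event_times = np.unique(t[d == 1])
        groups = []
        for tau in event_times:
            i0 = int(np.searchsorted(t, tau, side="left"))
            dead = np.where((t == tau) & (d == 1))[0]
            groups.append((i0, dead))
        return t, d, X, groups

    def loglik_grad_hess(self, beta: np.ndarray, ties: str = "efron"):
        """Log partial likelihood, gradient and (positive-definite) observed
        information at ``beta``."""
        cached = getattr(self, "_cached", None)
        if cached is None:
            cached = self._cached = self._prepare()
        t, d, X, groups = cached
        n, p = X.shape
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = wX[:, :, None] * X[:, None, :]
        # suffix (risk-set) sums: index i holds sums over rows i..n-1
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for i0, dead in groups:
            dd = len(dead)
            ll += float(eta[dead].sum())
            grad += X[dead].sum(axis=0)
            s0r, s1r, s2r = S0[i0], S1[i0], S2[i0]
            if ties == "efron" and dd > 1:
                s0d = w[dead].sum()
                s1d = wX[dead].sum(axis=0)
                s2d = wXX[dead].sum(axis=0)
                for el in range(dd):
                    f = el / dd
                    phi0 = s0r - f * s0d
                    phi1 = s1r - f * s1d
                    phi2 = s2r - f * s2d
                    ll -= np.log(phi0)
                    grad -= phi1 / phi0
                    info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
            else:  # breslow, or a single death where the two coincide
                ll -= dd * np.log(s0r)
                grad -= dd * s1r / s0r
                info += dd * (s2r / s0r - np.outer(s1r, s1r) / s0r**2)
        return ll, grad, info

    def fit(
        self,
        ties: str = "efron",
        max_iter: int = 100,
        tol: float = 1e-9,
    ) -> "CoxResults":
        """Newton-Raphson maximization with step-halving; the log partial
        likelihood is non-decreasing across accepted iterations."""
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method: {ties!r}")
        self._cached = self._prepare()
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self.loglik_grad_hess(beta, ties)
        llnull = ll
        converged = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            # step-halving: never accept a decrease of the partial likelihood
            scale = 1.0
            for _half in range(30):
                candidate = beta + scale * step
                ll_new, grad_new, info_new = self.loglik_grad_hess(candidate, ties)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta, ll, grad, info = candidate, ll_new, grad_new, info_new
            if np.max(np.abs(scale * step)) < tol:
                converged = True
                break
        if not converged:
            logger.warning("Cox fit did not converge in %d iterations", max_iter)
        separation = bool(np.any(np.abs(beta) > 15))
        if separation:
            logger.warning("Cox fit: |beta| > 15 suggests separation")
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        return CoxResults(
            model=self,
            params=pd.Series(beta, index=self.covariates),
            cov_params=pd.DataFrame(cov, index=self.covariates, columns=self.covariates),
            llf=float(ll),
            llnull=float(llnull),
            converged=converged,
            separation=separation,
            ties=ties,
            n_iter=max_iter,
        )


@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, their uncertainty and Wald tests."""

    model: CoxPH
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    llnull: float
    converged: bool
    separation: bool
    ties: str
    n_iter: int = field(default=0, repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "HR lower 95%": np.exp(ci["lower"]),
                "HR upper 95%": np.exp(ci["upper"]),
            }
        )


def cox_fit(
    table: SurvivalTable,
    covariates: list[str],
    ties: str = "efron",
    max_iter: int = 100,
) -> CoxResults:
    """Functional wrapper: build a :class:`CoxPH` and fit it."""
    return CoxPH(table, covariates).fit(ties=ties, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Composition: score -> stratify -> survive
# ---------------------------------------------------------------------------

@dataclass
class ScoreSurvivalResult:
    scores: pd.Series
    strata: pd.Series  # high / low / mid per joined patient
    km_high: KMCurve
    km_low: KMCurve
    logrank: tuple[float, int, float]
    cox: CoxResults


def signature_score_survival(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    clinical: SurvivalTable,
    stromal_covariate: str | None = "stromal_score",
    alpha: float = 0.25,
    ties: str = "efron",
) -> ScoreSurvivalResult:
    """Score patients with ssGSEA, stratify into upper/lower score quartiles,
    and compare survival of high vs low scorers.

    The Cox model uses the high-vs-low indicator (low quartile = reference)
    plus the stromal covariate when available.  Expression and clinical data
    are joined on sample/patient identifiers; fewer than 8 joined patients is
    an error.
    """
    common = [s for s in expr.samples if s in clinical.data.index]
    if len(common) < 8:
        raise ValidationError(
            f"expression/clinical join produced only {len(common)} patients; need >= 8"
        )
    sub_expr = ExpressionMatrix(values=expr.values[common])
    scores = ssgsea_score(sub_expr, gene_set, alpha=alpha, normalize=True).scores
    labels = quartile_stratify(scores.to_numpy())
    strata = pd.Series(labels, index=scores.index, name="stratum")

    keep = strata[strata != "mid"].index
    clin = clinical.data.loc[keep]
    indicator = (strata.loc[keep] == "high").astype(float)

    km_high = km_estimate(
        clin.loc[indicator == 1, "time"], clin.loc[indicator == 1, "event"], label="high"
    )
    km_low = km_estimate(
        clin.loc[indicator == 0, "time"], clin.loc[indicator == 0, "event"], label="low"
    )
    lr = logrank_test(clin["time"], clin["event"], indicator.to_numpy())

    fit_data = pd.DataFrame(
        {"time": clin["time"], "event": clin["event"], "score_high": indicator}
    )
    covs = ["score_high"]
    if stromal_covariate and stromal_covariate in clinical.data.columns:
        fit_data[stromal_covariate] = clin[stromal_covariate]
        covs.append(stromal_covariate)
    cox = CoxPH(SurvivalTable(data=fit_data), covs).fit(ties=ties)
    return ScoreSurvivalResult(
        scores=scores, strata=strata, km_high=km_high, km_low=km_low, logrank=lr, cox=cox
    )
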