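"""Seeded generators for synthetic proteomic, expression and survival data
with ground-truth manifests.

``simulate_proteomics`` emulates a 4-model x 5-replicate label-free ECM
proteomics experiment: two tumor models per tumor type (CD8lo "cold" and
CD8hi "hot"), log-normal total precursor intensities, planted type-exclusive
matrisome proteins, planted fold changes among the proteins shared by both
types, and missing-not-at-random dropout (detection probability logistic in
log-intensity, the standard LFQ behavior).  The generator's defaults mirror
the study design this pipeline targets: 5 biological replicates per model,
114 matrisome proteins shared by both tumor types, 16 CD8lo-exclusive and
8 CD8hi-exclusive proteins, and 5 + 7 planted fold changes, so that the
combined signatures have 21 and 15 members by construction.

``simulate_expression_cohort`` and ``simulate_survival_cohort`` produce the
expression matrices and clinical tables the scoring and survival stages
expect, with a single latent infiltration factor (expression) and an
exponential proportional-hazards model (survival) as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    MatrisomeReference,
    ProteinQuantTable,
    SampleGroup,
    SurvivalTable,
    ValidationError,
    bundled_matrisome_reference,
)

__all__ = [
    "ProteomicsSimConfig",
    "GroundTruth",
    "simulate_proteomics",
    "simulate_expression_cohort",
    "simulate_survival_cohort",
    "analytic_score_correlation",
    "paper_shaped_config",
]

# Planted gene identities: curated matrisome genes assigned to each role so
# the synthetic experiment carries realistic symbols and category structure.
EXCLUSIVE_LO_GENES = (
    # 6 core matrisome
    "AGRN", "DMBT1", "FBLN5", "IGFBP4", "IGSF10", "THBS3",
    # 10 matrisome-associated
    "MMP9", "P4HA1", "P4HA2", "ITIH1", "ITIH4", "SERPINC1", "SERPINB2",
    "KNG1", "IL1RN", "LMAN1",
)
EXCLUSIVE_HI_GENES = (
    # 5 core matrisome
    "COL8A2", "COL14A1", "MFAP2", "FBLN2", "SRPX2",
    # 3 matrisome-associated
    "LOXL2", "CSTB", "C1QTNF5",
)
DIFFERENTIAL_LO_GENES = ("S100A10", "ANXA1", "PLAT", "SERPINE1", "TIMP1")
DIFFERENTIAL_HI_GENES = ("POSTN", "COL8A1", "TGFBI", "ADAMTSL1", "LTBP2", "THSD4", "LTBP1")

_CORE_FILLER_CATEGORIES = ("ECM glycoproteins", "Collagens", "Proteoglycans")
_ASSOC_FILLER_CATEGORIES = ("ECM-affiliated proteins", "ECM regulators", "Secreted factors")


@dataclass
class ProteomicsSimConfig:
    """Configuration of the synthetic label-free proteomics experiment."""

    models: dict[str, str] = field(
        default_factory=lambda: {"TC3": "CD8lo", "TC4": "CD8lo", "TH2": "CD8hi", "TH3": "CD8hi"}
    )
    replicates: int = 5
    n_background: int = 250          # non-matrisome proteins
    n_shared: int = 114              # matrisome proteins present in every model
    n_exclusive_lo: int = 16
    n_exclusive_hi: int = 8
    n_differential_lo: int = 5       # shared proteins more abundant in CD8lo
    n_differential_hi: int = 7       # shared proteins more abundant in CD8hi
    log2_fold: float = 1.0           # planted fold change (2-fold by default)
    n_model_specific: dict[str, int] | None = None  # default: 20 (lo) / 28 (hi)
    mean_log10: float = 6.5          # log10 intensity, between-protein mean
    sd_log10: float = 0.7            # between-protein spread
    replicate_sd_log10: float = 0.1  # within-protein replicate noise (~26% CV)
    detection_midpoint_log10: float = 4.0
    detection_slope: float = 3.0     # logistic slope per log10-intensity unit
    deterministic_detection: bool = False  # no MNAR dropout; p_in/p_out still apply
    p_in: float = 0.9                # exclusive-protein detection in its own type
    p_out: float = 0.05              # exclusive-protein detection in the other type
    filter_fail_fraction: float = 0.0  # background decoys failing the ID filters
    core_fraction: float = 0.6       # target core-matrisome share of planted fillers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for name in (
            "n_background", "n_shared", "n_exclusive_lo", "n_exclusive_hi",
            "n_differential_lo", "n_differential_hi",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_differential_lo + self.n_differential_hi > self.n_shared:
            raise ValidationError("differential proteins must fit inside the shared set")
        for name in ("p_in", "p_out", "filter_fail_fraction", "core_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        types = set(self.models.values())
        if len(types) != 2:
            raise ValidationError("exactly two tumor types are required")
        if self.n_model_specific is None:
            lo, hi = self._type_labels()
            self.n_model_specific = {
                m: (20 if t == lo else 28) for m, t in self.models.items()
            }

    def _type_labels(self) -> tuple[str, str]:
        """(lo, hi) tumor-type labels; 'lo'/'cold' sorts first by convention."""
        types = sorted(set(self.models.values()))
        lo = [t for t in types if "lo" in t.lower() or "cold" in t.lower()]
        if lo:
            lo_label = lo[0]
            hi_label = next(t for t in types if t != lo_label)
        else:
            lo_label, hi_label = types
        return lo_label, hi_label


def paper_shaped_config(seed: int = 0) -> ProteomicsSimConfig:
    """The planted scenario whose ground truth equals the study's headline
    counts (130/122 model-type profiles, 114 shared, 16/8 exclusive, 21/15
    combined, 150 matrisome proteins per sample), in the deterministic
    detection limit with low replicate noise so recovery is exact."""
    return ProteomicsSimConfig(
        deterministic_detection=True,
        p_in=1.0,
        p_out=0.0,
        # low enough that a false joint (p < 0.05, |change| >= 20%) call is a
        # many-sigma event and recovery of the planted calls is exact
        replicate_sd_log10=0.02,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    shared: frozenset[str]
    exclusive_lo: frozenset[str]
    exclusive_hi: frozenset[str]
    model_specific: dict[str, frozenset[str]]
    differential: dict[str, dict]  # gene -> {direction, log2_fold}
    tumor_type_lo: str
    tumor_type_hi: str
    extras: dict = field(default_factory=dict)

    @property
    def differential_lo(self) -> frozenset[str]:
        return frozenset(g for g, d in self.differential.items() if d["direction"] == "lo")

    @property
    def differential_hi(self) -> frozenset[str]:
        return frozenset(g for g, d in self.differential.items() if d["direction"] == "hi")

    @property
    def combined_lo(self) -> frozenset[str]:
        return self.exclusive_lo | self.differential_lo

    @property
    def combined_hi(self) -> frozenset[str]:
        return self.exclusive_hi | self.differential_hi

    def profile_of_type(self, tumor_type: str) -> frozenset[str]:
        if tumor_type == self.tumor_type_lo:
            return self.shared | self.exclusive_lo
        if tumor_type == self.tumor_type_hi:
            return self.shared | self.exclusive_hi
        raise KeyError(tumor_type)

    def write(self, path: str | Path) -> None:
        payload = {
            "shared": sorted(self.shared),
            "exclusive_lo": sorted(self.exclusive_lo),
            "exclusive_hi": sorted(self.exclusive_hi),
            "model_specific": {m: sorted(v) for m, v in self.model_specific.items()},
            "differential": self.differential,
            "tumor_type_lo": self.tumor_type_lo,
            "tumor_type_hi": self.tumor_type_hi,
            "extras": self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _planted_genes(n: int, named: tuple[str, ...], prefix: str) -> list[str]:
    if n <= len(named):
        return list(named[:n])
    fillers = [f"{prefix}{i:04d}" for i in range(1, n - len(named) + 1)]
    return list(named) + fillers


def _assign_categories(
    genes: list[str], ref: MatrisomeReference, core_fraction: float
) -> list[tuple[str, str, str]]:
    """(gene, division, category) rows; named genes keep their curated
    category, synthetic fillers are assigned to hit the target core share."""
    rows = []
    n_core = 0
    fillers = []
    for g in genes:
        if g in ref:
            division, category = ref.lookup(g)
            rows.append((g, division, category))
            if division == "Core matrisome":
                n_core += 1
        else:
            fillers.append(g)
    target_core = int(round(core_fraction * len(genes)))
    for i, g in enumerate(fillers):
        if n_core < target_core:
            category = _CORE_FILLER_CATEGORIES[i % 3]
            rows.append((g, "Core matrisome", category))
            n_core += 1
        else:
            category = _ASSOC_FILLER_CATEGORIES[i % 3]
            rows.append((g, "Matrisome-associated", category))
    order = {g: i for i, g in enumerate(genes)}
    rows.sort(key=lambda r: order[r[0]])
    return rows


def simulate_proteomics(
    cfg: ProteomicsSimConfig,
) -> tuple[ProteinQuantTable, MatrisomeReference, GroundTruth]:
    """Generate a protein quantification table, a matching matrisome
    reference and the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    lo_label, hi_label = cfg._type_labels()
    bundled = bundled_matrisome_reference()

    exclusive_lo = _planted_genes(cfg.n_exclusive_lo, EXCLUSIVE_LO_GENES, "EXLO")
    exclusive_hi = _planted_genes(cfg.n_exclusive_hi, EXCLUSIVE_HI_GENES, "EXHI")
    diff_lo = _planted_genes(cfg.n_differential_lo, DIFFERENTIAL_LO_GENES, "DFLO")
    diff_hi = _planted_genes(cfg.n_differential_hi, DIFFERENTIAL_HI_GENES, "DFHI")

    used = set(exclusive_lo) | set(exclusive_hi) | set(diff_lo) | set(diff_hi)
    curated_pool = [g for g in bundled.genes if g not in used]
    shared = list(diff_lo) + list(diff_hi)
    n_rest = cfg.n_shared - len(shared)
    shared += curated_pool[:n_rest]
    if len(shared) < cfg.n_shared:
        shared += [f"MATG{i:04d}" for i in range(1, cfg.n_shared - len(shared) + 1)]

    model_specific = {
        model: [f"MS{model}{i:03d}" for i in range(1, cfg.n_model_specific[model] + 1)]
        for model in cfg.models
    }
    background = [f"BKG{i:04d}" for i in range(1, cfg.n_background + 1)]

    # matrisome reference covering every planted matrisome gene
    matrisome_genes = list(shared) + exclusive_lo + exclusive_hi
    for genes in model_specific.values():
        matrisome_genes += genes
    ref_rows = _assign_categories(matrisome_genes, bundled, cfg.core_fraction)
    reference = MatrisomeReference.from_records(ref_rows)

    # design
    design: dict[str, SampleGroup] = {}
    samples: list[str] = []
    for model, tumor_type in cfg.models.items():
        for r in range(1, cfg.replicates + 1):
            name = f"{model}_r{r}"
            design[name] = SampleGroup(model=model, tumor_type=tumor_type, replicate=r)
            samples.append(name)

    all_genes = matrisome_genes + background
    n_prot, n_samp = len(all_genes), len(samples)
    baseline = rng.normal(cfg.mean_log10, cfg.sd_log10, size=n_prot)

    diff_fold = {g: ("lo", cfg.log2_fold) for g in diff_lo}
    diff_fold.update({g: ("hi", cfg.log2_fold) for g in diff_hi})
    exclusive_of = {g: lo_label for g in exclusive_lo}
    exclusive_of.update({g: hi_label for g in exclusive_hi})
    model_of = {g: m for m, genes in model_specific.items() for g in genes}

    log2_to_log10 = np.log10(2.0)
    log_intensity = np.empty((n_prot, n_samp))
    presence = np.ones((n_prot, n_samp), dtype=bool)  # designed presence
    for j, s in enumerate(samples):
        grp = design[s]
        shift = np.zeros(n_prot)
        for i, g in enumerate(all_genes):
            if g in diff_fold:
                direction, fold = diff_fold[g]
                favored = lo_label if direction == "lo" else hi_label
                if grp.tumor_type == favored:
                    shift[i] = fold * log2_to_log10
            elif g in exclusive_of:
                if exclusive_of[g] != grp.tumor_type:
                    presence[i, j] = rng.random() < cfg.p_out
                else:
                    presence[i, j] = rng.random() < cfg.p_in
            elif g in model_of and model_of[g] != grp.model:
                presence[i, j] = False
        log_intensity[:, j] = baseline + shift + rng.normal(
            0.0, cfg.replicate_sd_log10, size=n_prot
        )

    if cfg.deterministic_detection:
        detected = presence
    else:
        logit = cfg.detection_slope * (log_intensity - cfg.detection_midpoint_log10)
        p_detect = 1.0 / (1.0 + np.exp(-logit))
        # exclusive proteins are governed by p_in/p_out alone
        excl_rows = np.array([g in exclusive_of for g in all_genes])
        p_detect[excl_rows, :] = 1.0
        detected = presence & (rng.random((n_prot, n_samp)) < p_detect)

    values = np.where(detected, 10.0 ** log_intensity, np.nan)

    peptide_count = rng.integers(2, 31, size=n_prot)
    protein_fdr = rng.uniform(0.0, 0.009, size=n_prot)
    if cfg.filter_fail_fraction > 0 and cfg.n_background > 0:
        n_fail = int(round(cfg.filter_fail_fraction * cfg.n_background))
        fail_idx = len(matrisome_genes) + rng.choice(
            cfg.n_background, size=n_fail, replace=False
        )
        halves = rng.random(n_fail) < 0.5
        peptide_count[fail_idx[halves]] = 1
        protein_fdr[fail_idx[~halves]] = rng.uniform(0.011, 0.05, size=(~halves).sum())

    symbols = [g.capitalize() for g in all_genes]
    table = ProteinQuantTable(
        intensities=pd.DataFrame(
            values, index=pd.Index(symbols, name="protein_id"), columns=samples
        ),
        gene_symbol=pd.Series(symbols, index=symbols, name="gene_symbol"),
        peptide_count=pd.Series(peptide_count, index=symbols, name="peptide_count"),
        protein_fdr=pd.Series(protein_fdr, index=symbols, name="protein_fdr"),
        design=design,
    )
    truth = GroundTruth(
        shared=frozenset(shared),
        exclusive_lo=frozenset(exclusive_lo),
        exclusive_hi=frozenset(exclusive_hi),
        model_specific={m: frozenset(v) for m, v in model_specific.items()},
        differential={
            g: {"direction": d, "log2_fold": f} for g, (d, f) in diff_fold.items()
        },
        tumor_type_lo=lo_label,
        tumor_type_hi=hi_label,
        extras={"seed": cfg.seed, "n_background": cfg.n_background},
    )
    return table, reference, truth


# ---------------------------------------------------------------------------
# Expression cohort with one latent infiltration factor
# ---------------------------------------------------------------------------

def _default_set(prefix: str, size: int) -> GeneSet:
    return GeneSet(
        name=prefix,
        description=f"synthetic {prefix} gene set",
        members=frozenset(f"{prefix}{i:03d}" for i in range(1, size + 1)),
    )


def analytic_score_correlation(
    loading: float, noise_sd: float, m1: int, m2: int
) -> float:
    """Correlation of the means of two gene sets of sizes m1, m2 whose genes
    load on one latent factor: cov = loading^2, var = loading^2 + sd^2/m."""
    cov = loading**2
    v1 = loading**2 + noise_sd**2 / m1
    v2 = loading**2 + noise_sd**2 / m2
    return cov / np.sqrt(v1 * v2)


def simulate_expression_cohort(
    n_samples: int = 200,
    hot_set: GeneSet | None = None,
    cold_set: GeneSet | None = None,
    ctl_set: GeneSet | None = None,
    loading: float = 0.6,
    noise_sd: float = 1.0,
    n_background_genes: int = 2000,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression cohort where hot-set and CTL genes share one latent
    infiltration factor (with the given loading) while cold-set and
    background genes are independent noise."""
    if not 0.0 <= loading <= 1.0:
        raise ValidationError("loading must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hot_set = hot_set or _default_set("HOT", 20)
    cold_set = cold_set or _default_set("COLD", 20)
    ctl_set = ctl_set or _default_set("CTL", 20)

    factor = rng.normal(size=n_samples)
    genes, rows = [], []
    marginal_sd = float(np.sqrt(loading**2 + noise_sd**2))
    for gs, loaded in ((hot_set, True), (ctl_set, True), (cold_set, False)):
        for g in sorted(gs.members):
            genes.append(g)
            if loaded:
                rows.append(loading * factor + noise_sd * rng.normal(size=n_samples))
            else:
                rows.append(marginal_sd * rng.normal(size=n_samples))
    for i in range(1, n_background_genes + 1):
        genes.append(f"BG{i:04d}")
        rows.append(marginal_sd * rng.normal(size=n_samples))

    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(np.array(rows), index=pd.Index(genes, name="gene"),
                            columns=sample_ids)
    )
    truth = GroundTruth(
        shared=frozenset(),
        exclusive_lo=frozenset(),
        exclusive_hi=frozenset(),
        model_specific={},
        differential={},
        tumor_type_lo="CD8lo",
        tumor_type_hi="CD8hi",
        extras={
            "latent_factor": factor.tolist(),
            "loading": loading,
            "noise_sd": noise_sd,
            "analytic_rho_hot_ctl": analytic_score_correlation(
                loading, noise_sd, len(hot_set), len(ctl_set)
            ),
            "seed": seed,
        },
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Survival cohort under an exponential proportional-hazards model
# ---------------------------------------------------------------------------

def simulate_survival_cohort(
    n: int = 400,
    beta_high: float = 0.7,
    beta_stromal: float = 0.3,
    baseline_rate: float = 0.01,
    censor_rate: float = 0.005,
    seed: int = 0,
    with_expression: bool = False,
    n_set_genes: int = 20,
    n_background_genes: int = 80,
    signature_name: str = "signature",
) -> tuple[SurvivalTable, ExpressionMatrix | None, GeneSet | None, GroundTruth]:
    """Survival cohort drawn from an exponential proportional-hazards model.

    A latent per-patient score drives a ``score_high`` indicator (upper
    quartile vs the rest) with planted log-hazard ``beta_high``;
    ``stromal_score`` is an independent standard-normal covariate with
    planted ``beta_stromal``.  Censoring is independent exponential.  With
    ``with_expression``, an aligned expression matrix is emitted whose
    signature genes load on the latent score, so the scoring + stratification
    + Cox composition can be tested end to end.
    """
    if baseline_rate <= 0 or censor_rate < 0:
        raise ValidationError("rates must be positive (censor_rate may be 0)")
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n)
    stromal = rng.normal(size=n)
    high = (latent >= np.quantile(latent, 0.75)).astype(float)
    hazard = baseline_rate * np.exp(beta_high * high + beta_stromal * stromal)
    death = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    patient_ids = [f"P{i:04d}" for i in range(1, n + 1)]
    data = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "score_high": high,
            "stromal_score": stromal,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    table = SurvivalTable(data=data)

    expr = gene_set = None
    if with_expression:
        gene_set = _default_set("SIG", n_set_genes)
        gene_set = GeneSet(
            name=signature_name, description="planted survival signature",
            members=gene_set.members,
        )
        genes, rows = [], []
        for g in sorted(gene_set.members):
            genes.append(g)
            rows.append(2.0 * latent + 0.7 * rng.normal(size=n))
        for i in range(1, n_background_genes + 1):
            genes.append(f"BG{i:04d}")
            rows.append(rng.normal(size=n) * np.sqrt(2.0**2 + 0.7**2))
        expr = ExpressionMatrix(
            values=pd.DataFrame(np.array(rows), index=pd.Index(genes, name="gene"),
                                columns=patient_ids)
        )

    truth = GroundTruth(
        shared=frozenset(),
        exclusive_lo=frozenset(),
        exclusive_hi=frozenset(),
        model_specific={},
        differential={},
        tumor_type_lo="CD8lo",
        tumor_type_hi="CD8hi",
        extras={
            "beta_high": beta_high,
            "beta_stromal": beta_stromal,
            "baseline_rate": baseline_rate,
            "censor_rate": censor_rate,
            "latent_score": latent.tolist(),
            "seed": seed,
        },
    )
    return table, expr, gene_set, truth
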