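"""Config-driven end-to-end orchestration.

``run_pipeline`` executes annotate -> identification filters -> detection ->
k-of-n model profiles -> tumor-type profiles -> shared/exclusive signatures
-> normalization -> differential abundance -> combined signatures, writing
every stage artifact plus a machine-readable ``summary.json`` with the
headline counts.  Runs are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import annotate_proteins, category_distribution, write_annotated_table
from .detection import (
    apply_identification_filters,
    detection_matrix,
    model_profile,
    type_profile,
)
from .diffabund import combined_signature, differential_proteins, normalize_intensities
from .io import (
    NON_MATRISOME,
    ProteinQuantTable,
    MatrisomeReference,
    ValidationError,
    read_design,
    read_matrisome_reference,
    read_protein_quant_table,
    write_protein_quant_table,
)
from .signatures import exclusive_signatures, signature_category_split
from .simulate import ProteomicsSimConfig, simulate_proteomics

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

SUMMARY_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run.

    Either ``quant_path`` + ``design_path`` + ``reference_path`` point at
    real tables, or ``simulate`` holds a :class:`ProteomicsSimConfig` and the
    inputs are generated.
    """

    output_dir: str = "matrisig_out"
    seed: int = 0
    # inputs
    quant_path: str | None = None
    quant_dialect: str = "generic"
    design_path: str | None = None
    reference_path: str | None = None
    simulate: ProteomicsSimConfig | None = None
    # stage parameters
    min_peptides: int = 2
    max_protein_fdr: float = 0.01
    k: int = 3
    normalization: str = "total_sum"
    alpha: float = 0.05
    up_threshold: float = 1.2
    down_threshold: float = 0.8
    t_test_variant: str = "student"
    log2_transform: bool = False
    group_lo: str = "CD8lo"
    group_hi: str = "CD8hi"

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("quant_path", "design_path", "reference_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValidationError(f"config needs {name} (or a simulate block)")
                if not Path(path).exists():
                    raise ValidationError(f"{name} does not exist: {path}")
            n_reps = None
        else:
            n_reps = self.simulate.replicates
        if n_reps is not None and self.k > n_reps:
            raise ValidationError(f"k={self.k} exceeds replicates n={n_reps}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.up_threshold <= 1 or self.down_threshold >= 1:
            raise ValidationError("fold thresholds must bracket 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = ProteomicsSimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _load_inputs(cfg: PipelineConfig) -> tuple[ProteinQuantTable, MatrisomeReference]:
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        if sim_cfg.seed != cfg.seed:
            sim_cfg = ProteomicsSimConfig(**{**asdict(sim_cfg), "seed": cfg.seed})
        table, reference, truth = simulate_proteomics(sim_cfg)
        return table, reference
    design = read_design(cfg.design_path)
    table = read_protein_quant_table(cfg.quant_path, design, dialect=cfg.quant_dialect)
    reference = read_matrisome_reference(cfg.reference_path)
    return table, reference


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the summary dict (also
    written to <output_dir>/summary.json)."""
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValidationError, KeyError, FileNotFoundError) as exc:
            raise PipelineError(name, str(exc)) from exc

    table, reference = stage("load", _load_inputs, cfg)
    table = stage("annotate", annotate_proteins, table, reference)
    write_annotated_table(table, out_dir / "annotated.tsv")
    filtered = stage(
        "filter", apply_identification_filters, table,
        cfg.min_peptides, cfg.max_protein_fdr,
    )
    dm = stage("detect", detection_matrix, filtered)

    profiles = {}
    for model in filtered.models:
        profiles[model] = stage("profile", model_profile, dm, model, cfg.k)

    by_type: dict[str, list] = {}
    for prof in profiles.values():
        by_type.setdefault(prof.tumor_type, []).append(prof)
    type_profiles = {}
    for tumor_type, profs in by_type.items():
        if len(profs) != 2:
            raise PipelineError(
                "type_profile", f"tumor type {tumor_type!r} has {len(profs)} models, need 2"
            )
        type_profiles[tumor_type] = stage(
            "type_profile", type_profile, profs[0], profs[1], tumor_type
        )
    for label, prof in {**profiles, **type_profiles}.items():
        with open(out_dir / f"profile_{label}.tsv", "w") as fh:
            fh.write("gene_symbol\n")
            for sym in sorted(prof.proteins):
                fh.write(sym + "\n")

    lo, hi = cfg.group_lo, cfg.group_hi
    if lo not in type_profiles or hi not in type_profiles:
        raise PipelineError(
            "signatures",
            f"configured groups {lo!r}/{hi!r} not among tumor types {list(type_profiles)}",
        )
    sig = stage(
        "signatures", exclusive_signatures, type_profiles[lo], type_profiles[hi], reference
    )
    sig.write(out_dir, reference)

    normalized = stage("normalize", normalize_intensities, filtered, cfg.normalization)
    diff = stage(
        "diffabund", differential_proteins, normalized, sig.shared,
        lo, hi, cfg.alpha, cfg.up_threshold, cfg.down_threshold,
        cfg.t_test_variant, cfg.log2_transform,
    )
    diff.write(out_dir / "volcano.tsv")
    combined_lo = combined_signature(sig.exclusive_a, diff, "lo")
    combined_hi = combined_signature(sig.exclusive_b, diff, "hi")

    # per-sample matrisome counts on the filtered, annotated table
    is_matrisome = filtered.annotation["division"] != NON_MATRISOME
    per_sample = {
        s: int((filtered.intensities[s].notna() & is_matrisome).sum())
        for s in filtered.samples
    }
    per_sample_core = {}
    for s in filtered.samples:
        mask = filtered.intensities[s].notna() & is_matrisome
        dist = category_distribution(filtered.annotation[mask])
        per_sample_core[s] = dist.core_fraction

    lo_core, lo_assoc, lo_cats = signature_category_split(sig.exclusive_a, reference)
    hi_core, hi_assoc, hi_cats = signature_category_split(sig.exclusive_b, reference)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "matrisig_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "min_peptides": cfg.min_peptides,
            "max_protein_fdr": cfg.max_protein_fdr,
            "k": cfg.k,
            "normalization": cfg.normalization,
            "alpha": cfg.alpha,
            "up_threshold": cfg.up_threshold,
            "down_threshold": cfg.down_threshold,
            "t_test_variant": cfg.t_test_variant,
            "log2_transform": cfg.log2_transform,
        },
        "model_profiles": {m: len(p) for m, p in profiles.items()},
        "profile_lo": len(type_profiles[lo]),
        "profile_hi": len(type_profiles[hi]),
        "shared": len(sig.shared),
        "exclusive_lo": len(sig.exclusive_a),
        "exclusive_hi": len(sig.exclusive_b),
        "exclusive_lo_split": {"core": lo_core, "associated": lo_assoc, "categories": lo_cats},
        "exclusive_hi_split": {"core": hi_core, "associated": hi_assoc, "categories": hi_cats},
        "n_up_in_lo": len(diff.up_in_lo),
        "n_up_in_hi": len(diff.up_in_hi),
        "combined_lo": len(combined_lo),
        "combined_hi": len(combined_hi),
        "per_sample_matrisome": per_sample,
        "mean_per_sample_matrisome": sum(per_sample.values()) / len(per_sample),
        "mean_core_fraction": (
            sum(v for v in per_sample_core.values() if v is not None)
            / max(1, sum(1 for v in per_sample_core.values() if v is not None))
        ),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_protein_quant_table(normalized, out_dir / "normalized.tsv")
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return summary
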