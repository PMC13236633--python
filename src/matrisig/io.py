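"""Domain containers and readers/writers for every table format the pipeline touches.

All tabular formats are 1-header-row TSV by default (CSV via ``sep=","``).
Missing label-free intensities are encoded uniformly: an empty cell and a
literal 0 both mean "not detected" (the LFQ convention, where a zero LFQ
intensity denotes absence, not a measured zero) and are stored as NaN.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "SampleGroup",
    "ProteinQuantTable",
    "MatrisomeReference",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "SurvivalTable",
    "CORE_CATEGORIES",
    "ASSOCIATED_CATEGORIES",
    "read_protein_quant_table",
    "write_protein_quant_table",
    "read_matrisome_reference",
    "read_gene_sets",
    "write_gene_sets",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_survival_table",
    "write_survival_table",
    "read_design",
    "bundled_matrisome_reference",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


#: Categories making up the core matrisome division.
CORE_CATEGORIES = ("ECM glycoproteins", "Collagens", "Proteoglycans")
#: Categories making up the matrisome-associated division.
ASSOCIATED_CATEGORIES = ("ECM-affiliated proteins", "ECM regulators", "Secreted factors")

CORE_DIVISION = "Core matrisome"
ASSOCIATED_DIVISION = "Matrisome-associated"
NON_MATRISOME = "Non-matrisome"

_CANONICAL_CATEGORY = {c.lower(): c for c in CORE_CATEGORIES + ASSOCIATED_CATEGORIES}
_CANONICAL_DIVISION = {
    "core matrisome": CORE_DIVISION,
    "matrisome-associated": ASSOCIATED_DIVISION,
    "matrisome associated": ASSOCIATED_DIVISION,
    "non-matrisome": NON_MATRISOME,
}


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive gene-symbol key: trim, split multi-ID cells on ';'
    keeping the first token, uppercase."""
    first = str(symbol).strip().split(";")[0].strip()
    return first.upper()


@dataclass(frozen=True)
class SampleGroup:
    """Experimental-design assignment of one sample."""

    model: str
    tumor_type: str
    replicate: int


@dataclass
class ProteinQuantTable:
    """Protein x sample label-free intensity matrix with identification metadata.

    ``intensities`` is indexed by ``protein_id`` with one column per sample;
    NaN marks a protein not detected in that sample.  ``design`` maps every
    sample to its (model, tumor_type, replicate) assignment.
    """

    intensities: pd.DataFrame
    gene_symbol: pd.Series
    peptide_count: pd.Series
    protein_fdr: pd.Series
    design: dict[str, SampleGroup]
    annotation: pd.DataFrame | None = None  # division/category, set by annotate_proteins

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein_id: {dupes[:5]}")
        if self.intensities.columns.duplicated().any():
            raise ValidationError("duplicate sample identifiers")
        missing = [s for s in self.intensities.columns if s not in self.design]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        model_types: dict[str, str] = {}
        for grp in self.design.values():
            prev = model_types.setdefault(grp.model, grp.tumor_type)
            if prev != grp.tumor_type:
                raise ValidationError(
                    f"model {grp.model!r} maps to two tumor types ({prev!r}, {grp.tumor_type!r})"
                )
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ValidationError("negative intensity")
        if ((self.peptide_count < 0) | (self.peptide_count != self.peptide_count.astype(int))).any():
            raise ValidationError("peptide_count must be a non-negative integer")
        if ((self.protein_fdr < 0) | (self.protein_fdr > 1)).any():
            raise ValidationError("protein_fdr must lie in [0, 1]")

    # -- conveniences ----------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_of_model(self, model: str) -> list[str]:
        out = [s for s in self.samples if self.design[s].model == model]
        if not out:
            raise KeyError(f"unknown model: {model!r}")
        return out

    def samples_of_type(self, tumor_type: str) -> list[str]:
        out = [s for s in self.samples if self.design[s].tumor_type == tumor_type]
        if not out:
            raise KeyError(f"unknown tumor_type: {tumor_type!r}")
        return out

    @property
    def models(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.design[s].model, None)
        return list(seen)

    @property
    def tumor_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.design[s].tumor_type, None)
        return list(seen)

    def tumor_type_of_model(self, model: str) -> str:
        for grp in self.design.values():
            if grp.model == model:
                return grp.tumor_type
        raise KeyError(f"unknown model: {model!r}")

    def subset(self, protein_ids: Iterable[str]) -> "ProteinQuantTable":
        ids = pd.Index(protein_ids)
        return ProteinQuantTable(
            intensities=self.intensities.loc[ids].copy(),
            gene_symbol=self.gene_symbol.loc[ids].copy(),
            peptide_count=self.peptide_count.loc[ids].copy(),
            protein_fdr=self.protein_fdr.loc[ids].copy(),
            design=dict(self.design),
            annotation=None if self.annotation is None else self.annotation.loc[ids].copy(),
        )


@dataclass
class MatrisomeReference:
    """Gene symbol -> (division, category) lookup defining the six matrisome
    categories; matching is case-insensitive on the trimmed first ';' token."""

    table: pd.DataFrame  # index: normalized symbol; columns: gene_symbol, division, category

    def __post_init__(self) -> None:
        for row_no, (sym, row) in enumerate(self.table.iterrows(), start=1):
            _check_division_category(row["division"], row["category"], row_no)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "MatrisomeReference":
        rows = []
        for sym, division, category in records:
            rows.append(
                {
                    "gene_symbol": str(sym).strip(),
                    "division": _canonical_division(division),
                    "category": _canonical_category(category),
                }
            )
        tab = pd.DataFrame(rows)
        tab.index = pd.Index([normalize_symbol(s) for s in tab["gene_symbol"]], name="key")
        if tab.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in matrisome reference")
        return cls(tab)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.table.index

    def lookup(self, symbol: str) -> tuple[str, str]:
        """Return (division, category); unknown genes are non-matrisome."""
        key = normalize_symbol(symbol)
        if key in self.table.index:
            row = self.table.loc[key]
            return row["division"], row["category"]
        return NON_MATRISOME, "none"

    @property
    def genes(self) -> list[str]:
        return self.table["gene_symbol"].tolist()


def _canonical_category(category: str) -> str:
    key = str(category).strip().lower()
    if key in ("none", ""):
        return "none"
    if key not in _CANONICAL_CATEGORY:
        raise ValidationError(f"unknown matrisome category: {category!r}")
    return _CANONICAL_CATEGORY[key]


def _canonical_division(division: str) -> str:
    key = str(division).strip().lower()
    if key not in _CANONICAL_DIVISION:
        raise ValidationError(f"unknown matrisome division: {division!r}")
    return _CANONICAL_DIVISION[key]


def _check_division_category(division: str, category: str, row_no: int) -> None:
    ok = (
        (division == CORE_DIVISION and category in CORE_CATEGORIES)
        or (division == ASSOCIATED_DIVISION and category in ASSOCIATED_CATEGORIES)
        or (division == NON_MATRISOME and category == "none")
    )
    if not ok:
        raise ValidationError(
            f"row {row_no}: category {category!r} inconsistent with division {division!r}"
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene set name: {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (unit-agnostic)."""

    values: pd.DataFrame  # index: gene symbol; columns: samples

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene rows in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample columns in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SurvivalTable:
    """Per-patient follow-up time, event indicator and covariates.

    ``event`` is 1 for an observed death and 0 for censoring; ``time`` must be
    positive and on one unit throughout.  Covariate columns (for example
    ``stromal_score``) live in ``data`` alongside time/event.
    """

    data: pd.DataFrame  # index: patient_id; columns: time, event, covariates...
    n_rejected: int = 0  # rows dropped at read time for non-positive time

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ValidationError("survival table requires 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise ValidationError("time must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0 (censored) or 1 (death)")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def covariate(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_GENERIC_REQUIRED = ("protein_id", "gene_symbol", "peptide_count", "protein_fdr")

_PG_ID = "Majority protein IDs"
_PG_GENES = "Gene names"
_PG_PEPTIDES = "Razor + unique peptides"
_PG_LFQ_PREFIX = "LFQ intensity "
_PG_FDR = "Q-value"


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_intensity(cell: str, where: str) -> float:
    """Empty cell and literal 0 both mean not-detected (NaN)."""
    text = cell.strip()
    if text == "" or text.upper() in ("NA", "NAN"):
        return np.nan
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity {cell!r} at {where}") from exc
    if value == 0:
        return np.nan
    if value < 0:
        raise ValidationError(f"negative intensity {value} at {where}")
    return value


def read_protein_quant_table(
    path: str | Path,
    design: Mapping[str, SampleGroup] | Mapping[str, Mapping[str, object]],
    dialect: str = "generic",
    sep: str = "\t",
) -> ProteinQuantTable:
    """Read a protein-level quantification table.

    ``dialect='generic'`` expects columns protein_id, gene_symbol,
    peptide_count, protein_fdr plus one intensity column per sample.
    ``dialect='proteingroups'`` expects the standard proteinGroups layout
    ("Majority protein IDs", "Gene names", "Razor + unique peptides",
    "Q-value", "LFQ intensity <sample>").
    """
    design = coerce_design(design)
    raw = _read_table(path, sep)
    if dialect == "generic":
        for col in _GENERIC_REQUIRED:
            if col not in raw.columns:
                raise FormatError(f"missing required column: {col}")
        sample_cols = {s: s for s in design}
        id_col, gene_col, pep_col, fdr_col = _GENERIC_REQUIRED
    elif dialect == "proteingroups":
        for col in (_PG_ID, _PG_GENES, _PG_PEPTIDES, _PG_FDR):
            if col not in raw.columns:
                raise FormatError(f"missing required column: {col}")
        sample_cols = {s: _PG_LFQ_PREFIX + s for s in design}
        id_col, gene_col, pep_col, fdr_col = _PG_ID, _PG_GENES, _PG_PEPTIDES, _PG_FDR
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    for sample, col in sample_cols.items():
        if col not in raw.columns:
            raise FormatError(f"sample {sample!r} in design has no column {col!r}")

    protein_ids = raw[id_col].map(lambda s: str(s).strip().split(";")[0].strip())
    if protein_ids.duplicated().any():
        dupes = protein_ids[protein_ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate protein_id: {dupes[:5]}")

    inten = pd.DataFrame(index=pd.Index(protein_ids, name="protein_id"))
    for sample in design:  # preserve design order
        col = sample_cols[sample]
        inten[sample] = [
            _parse_intensity(cell, f"{col} row {i + 2}")
            for i, cell in enumerate(raw[col])
        ]

    genes = raw[gene_col].map(lambda s: str(s).strip().split(";")[0].strip())
    table = ProteinQuantTable(
        intensities=inten,
        gene_symbol=pd.Series(genes.values, index=inten.index, name="gene_symbol"),
        peptide_count=pd.Series(
            pd.to_numeric(raw[pep_col], errors="raise").astype(int).values,
            index=inten.index,
            name="peptide_count",
        ),
        protein_fdr=pd.Series(
            pd.to_numeric(raw[fdr_col], errors="raise").astype(float).values,
            index=inten.index,
            name="protein_fdr",
        ),
        design=dict(design),
    )
    return table


def write_protein_quant_table(table: ProteinQuantTable, path: str | Path, sep: str = "\t") -> None:
    """Write the generic dialect; round-trips values to 6 significant digits
    and preserves the missingness mask (missing written as empty cells)."""
    out = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "gene_symbol": table.gene_symbol.values,
            "peptide_count": table.peptide_count.values,
            "protein_fdr": table.protein_fdr.values,
        }
    )
    for sample in table.samples:
        col = table.intensities[sample]
        out[sample] = ["" if pd.isna(v) else f"{v:.6g}" for v in col]
    out.to_csv(path, sep=sep, index=False)


def coerce_design(design: Mapping[str, object]) -> dict[str, SampleGroup]:
    out: dict[str, SampleGroup] = {}
    for sample, grp in design.items():
        if isinstance(grp, SampleGroup):
            out[sample] = grp
        else:
            out[sample] = SampleGroup(
                model=str(grp["model"]),
                tumor_type=str(grp["tumor_type"]),
                replicate=int(grp["replicate"]),
            )
    return out


def read_design(path: str | Path) -> dict[str, SampleGroup]:
    """Design map from YAML or JSON: {sample: {model, tumor_type, replicate}}."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return coerce_design(raw)


def read_matrisome_reference(path: str | Path, sep: str = "\t") -> MatrisomeReference:
    raw = _read_table(path, sep)
    for col in ("gene_symbol", "division", "category"):
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col}")
    rows = []
    for i, row in raw.iterrows():
        try:
            division = _canonical_division(row["division"])
            category = _canonical_category(row["category"])
            _check_division_category(division, category, i + 2)
        except ValidationError as exc:
            raise ValidationError(f"row {i + 2}: {exc}") from exc
        rows.append((row["gene_symbol"], division, category))
    return MatrisomeReference.from_records(rows)


def bundled_matrisome_reference() -> MatrisomeReference:
    """The packaged curated matrisome subset (~100 genes across all six
    categories).  It is a convenience fixture, not a complete matrisome list;
    supply the full species list for real analyses."""
    here = Path(__file__).parent / "data" / "matrisome_subset.tsv"
    return read_matrisome_reference(here)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {line_no}: GMT line needs >= 3 fields")
            name, description = fields[0], fields[1]
            members = [m.strip() for m in fields[2:] if m.strip()]
            if not members:
                raise FormatError(f"line {line_no}: gene set {name!r} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"line {line_no}: {len(members) - len(unique)} duplicate members "
                    f"in gene set {name!r} dropped"
                )
                logger.warning("GMT %s line %d: duplicate members de-duplicated", name, line_no)
            coll.add(GeneSet(name=name, description=description, members=frozenset(unique)))
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def read_expression_matrix(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    return ExpressionMatrix(values=values.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.values.to_csv(path, sep=sep, index_label="gene")


def read_survival_table(path: str | Path, sep: str = "\t") -> SurvivalTable:
    raw = _read_table(path, sep)
    for col in ("patient_id", "time", "event"):
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col}")
    out = raw.copy()
    out["time"] = pd.to_numeric(out["time"], errors="raise")
    out["event"] = pd.to_numeric(out["event"], errors="raise")
    if not out["event"].isin([0, 1]).all():
        bad = sorted(set(out["event"]) - {0, 1})
        raise ValidationError(f"event values outside {{0,1}}: {bad}")
    bad_time = out["time"] <= 0
    n_rejected = int(bad_time.sum())
    if n_rejected:
        warnings.warn(f"dropped {n_rejected} rows with non-positive time")
        logger.warning("survival table: dropped %d rows with non-positive time", n_rejected)
        out = out[~bad_time]
    out = out.set_index("patient_id")
    for col in out.columns:
        if col not in ("time", "event"):
            try:
                out[col] = pd.to_numeric(out[col])
            except (ValueError, TypeError):
                pass  # non-numeric covariate (e.g. a stratum label) stays as-is
    out["event"] = out["event"].astype(int)
    return SurvivalTable(data=out, n_rejected=n_rejected)


def write_survival_table(table: SurvivalTable, path: str | Path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index_label="patient_id")
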