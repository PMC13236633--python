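import numpy as np
import pandas as pd
import pytest

from matrisig.io import (
    MatrisomeReference,
    ProteinQuantTable,
    SampleGroup,
)


@pytest.fixture
def small_design():
    return {
        "A1": SampleGroup(model="MA", tumor_type="lo", replicate=1),
        "A2": SampleGroup(model="MA", tumor_type="lo", replicate=2),
    }


@pytest.fixture
def tiny_quant_tsv(tmp_path):
    """3-protein, 2-sample generic table with one empty (missing) cell."""
    text = (
        "protein_id\tgene_symbol\tpeptide_count\tprotein_fdr\tA1\tA2\n"
        "P1\tCol1a1\t10\t0.001\t1e6\t2e6\n"
        "P2\tMmp9\t3\t0.005\t\t5e5\n"
        "P3\tGapdh\t8\t0.002\t3e5\t4e5\n"
    )
    path = tmp_path / "quant.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def small_reference():
    return MatrisomeReference.from_records(
        [
            ("Col1a1", "Core matrisome", "Collagens"),
            ("Col3a1", "Core matrisome", "Collagens"),
            ("Fn1", "Core matrisome", "ECM glycoproteins"),
            ("Agrn", "Core matrisome", "Proteoglycans"),
            ("Mmp9", "Matrisome-associated", "ECM regulators"),
            ("Anxa1", "Matrisome-associated", "ECM-affiliated proteins"),
            ("S100a10", "Matrisome-associated", "Secreted factors"),
        ]
    )


def make_table(values, design, genes=None, peptides=None, fdrs=None):
    """Build a ProteinQuantTable from a dict {protein: [per-sample values]}
    using NaN for missing."""
    samples = list(design)
    proteins = list(values)
    mat = pd.DataFrame(
        {s: [values[p][j] for p in proteins] for j, s in enumerate(samples)},
        index=pd.Index(proteins, name="protein_id"),
    )
    genes = genes or {p: p for p in proteins}
    return ProteinQuantTable(
        intensities=mat.astype(float),
        gene_symbol=pd.Series([genes[p] for p in proteins], index=proteins),
        peptide_count=pd.Series(
            [2 if peptides is None else peptides[p] for p in proteins], index=proteins
        ),
        protein_fdr=pd.Series(
            [0.001 if fdrs is None else fdrs[p] for p in proteins], index=proteins
        ),
        design=dict(design),
    )


@pytest.fixture
def four_model_design():
    design = {}
    for model, ttype in [("TC3", "CD8lo"), ("TC4", "CD8lo"), ("TH2", "CD8hi"), ("TH3", "CD8hi")]:
        for r in range(1, 6):
            design[f"{model}_r{r}"] = SampleGroup(model=model, tumor_type=ttype, replicate=r)
    return design


NAN = np.nan
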