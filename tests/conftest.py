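import pandas as pd
import pytest

from energyomics.synthetic import SimConfig

# Expressed-feature margins of the TAIR10-style annotation summary,
# at gene level (nuclear collapses to 23,250 genes) and transcript
# level (29,278 nuclear transcripts).  Cells are (compartment,
# gene_type) -> expressed count.
TABLE1_GENE_CELLS = {
    ("nuclear", "protein_coding"): 21497,
    ("nuclear", "rRNA"): 2,
    ("nuclear", "snRNA"): 13,
    ("nuclear", "snoRNA"): 18,
    ("nuclear", "miRNA"): 66,
    ("nuclear", "other_RNA"): 339,
    ("nuclear", "pseudogene"): 368,
    ("nuclear", "TE"): 947,
    ("mitochondrial", "protein_coding"): 121,
    ("mitochondrial", "pre_tRNA"): 2,
    ("mitochondrial", "rRNA"): 3,
    ("chloroplast", "protein_coding"): 87,
    ("chloroplast", "pre_tRNA"): 1,
    ("chloroplast", "rRNA"): 8,
}

TRANSCRIPT_MARGINS = {"nuclear": 29278, "mitochondrial": 126, "chloroplast": 96}


def annotation_from_cells(cells: dict) -> pd.DataFrame:
    rows = []
    i = 0
    for (comp, gtype), n in cells.items():
        for _ in range(n):
            rows.append(
                {
                    "gene_id": f"F{i:06d}",
                    "compartment": comp,
                    "gene_type": gtype,
                    "length_bp": 1000,
                }
            )
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table1_annotation() -> pd.DataFrame:
    """Annotation whose expressed margins reproduce the published summary."""
    return annotation_from_cells(TABLE1_GENE_CELLS)


@pytest.fixture
def small_sim_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_genes_by_compartment={
            "nuclear": 1000,
            "mitochondrial": 40,
            "chloroplast": 40,
        },
        n_proteins=200,
    )
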