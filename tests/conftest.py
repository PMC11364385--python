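import numpy as np
import pandas as pd
import pytest

from empflow.datamodel import ExpressionDataset, GeneSignature
from empflow.synthetic import PanelConfig, simulate_panel


@pytest.fixture(scope="session")
def small_config() -> PanelConfig:
    """Reduced panel used by unit tests: 4 models, 300 genes, 2 platforms."""
    return PanelConfig(
        n_models=4,
        potential_counts={"low": 2, "moderate": 1, "high": 1},
        cells_per_model_per_tissue=30,
        n_genes=300,
        n_epithelial=20,
        n_mesenchymal=20,
        n_intermediate=12,
        n_tissue_de=16,
        cnv_segment_genes=40,
        n_chromosomes=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def default_panel():
    """Panel at default study conditions (both platforms, planted truth)."""
    return simulate_panel(PanelConfig(seed=20240903))


@pytest.fixture(scope="session")
def program_signatures(default_panel):
    _, truth = default_panel
    return (
        GeneSignature("epithelial_program", tuple(truth.epithelial_genes)),
        GeneSignature("mesenchymal_program", tuple(truth.mesenchymal_genes)),
    )


@pytest.fixture()
def toy_dataset() -> ExpressionDataset:
    """4 cells x 5 genes with hand-checkable counts."""
    counts = np.array(
        [
            [4, 0, 1, 0, 5],
            [0, 2, 0, 0, 3],
            [1, 1, 1, 1, 1],
            [10, 0, 0, 2, 8],
        ]
    )
    cell_meta = pd.DataFrame(
        {
            "tumor_model": ["A", "A", "B", "B"],
            "tissue": ["primary", "metastasis", "primary", "metastasis"],
            "platform": ["plate"] * 4,
            "metastatic_potential": ["low", "low", "high", "high"],
        },
        index=[f"c{i}" for i in range(4)],
    )
    gene_meta = pd.DataFrame(
        {"chromosome": ["1", "1", "1", "2", "2"], "start": [100, 200, 300, 100, 200]},
        index=pd.Index([f"g{i}" for i in range(5)], name="symbol"),
    )
    return ExpressionDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)
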