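import numpy as np
import pandas as pd
import pytest

from reversom import ExpressionMatrix, SimulationConfig, generate_dataset


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two groups in one tissue, values chosen by hand."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 0.0, 7.2],
            "s2": [2.0, 3.5, 7.2],
            "s3": [1.5, 0.5, 7.0],
            "s4": [2.5, 3.0, 7.4],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    metadata = pd.DataFrame(
        {
            "tissue": ["SCN", "SCN", "SCN", "SCN"],
            "group": ["ctrl", "ctrl", "case", "case"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return ExpressionMatrix(values=values, metadata=metadata)


@pytest.fixture(scope="session")
def sim_default():
    """A moderately sized draw from the default study design (all four tissues)."""
    config = SimulationConfig(n_genes=4000, seed=11)
    matrix, truth = generate_dataset(config)
    return config, matrix, truth


def make_two_group_matrix(
    log2_ref: np.ndarray, log2_alt: np.ndarray, tissue: str = "T"
) -> ExpressionMatrix:
    """Wrap per-group log2(FPKM+1) value arrays (genes x reps) as a matrix."""
    fpkm_ref = np.maximum(np.exp2(log2_ref) - 1.0, 0.0)
    fpkm_alt = np.maximum(np.exp2(log2_alt) - 1.0, 0.0)
    n_genes, n_ref = fpkm_ref.shape
    n_alt = fpkm_alt.shape[1]
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    cols = {f"r{j}": fpkm_ref[:, j] for j in range(n_ref)}
    cols.update({f"a{j}": fpkm_alt[:, j] for j in range(n_alt)})
    values = pd.DataFrame(cols, index=genes)
    metadata = pd.DataFrame(
        {
            "tissue": [tissue] * (n_ref + n_alt),
            "group": ["ref"] * n_ref + ["alt"] * n_alt,
        },
        index=pd.Index(list(cols), name="sample_id"),
    )
    return ExpressionMatrix(values=values, metadata=metadata)
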