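import numpy as np
import pytest

from onionnorm import GeneEffectMatrix, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng) -> GeneEffectMatrix:
    """20 genes x 12 cell lines of plain Gaussian scores."""
    values = rng.standard_normal((20, 12))
    return GeneEffectMatrix(
        values,
        gene_ids=[f"G{i:02d}" for i in range(20)],
        sample_ids=[f"ACH-{i:06d}" for i in range(12)],
        orientation="genes_as_rows",
    )


@pytest.fixture(scope="session")
def tiny_synth():
    """Small synthetic dataset with planted structure, shared across tests."""
    cfg = SynthConfig(n_genes=120, n_cells=40, n_complexes=6,
                      n_confounder_complexes=2, complex_size_range=(3, 6),
                      seed=7)
    return generate(cfg)
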