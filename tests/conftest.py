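import numpy as np
import pytest

from orthocell import GeneratorConfig, generate_two_species


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A compact two-species study: 5 shared types + 1 private each,
    80 cells per type, 353 genes per species."""
    return GeneratorConfig(
        cells_per_type_per_condition={"control": 40, "aneurysm": 40},
        n_ortholog_genes=300,
        n_species_specific_genes=40,
        n_marker_genes_per_type=25,
        mito_gene_count=13,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_two_species(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
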