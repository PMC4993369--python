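import numpy as np
import pandas as pd
import pytest

from chromtx.annotation import GenomeAnnotation
from chromtx.synthetic import SimConfig, gen_genome


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale simulation: 100 genes, 2 clusters of 5, fixed seed."""
    return SimConfig(
        n_chromosomes=2,
        chrom_length=200_000,
        n_genes=100,
        n_sm_clusters=2,
        sm_cluster_size=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return gen_genome(small_config)


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two genes on a 10-kb chromosome: one per strand, mirror-placed."""
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [2000, 6000],
            "end": [4000, 8000],
            "strand": ["+", "-"],
            "category": ["CSF", "CSF"],
            "cluster_id": [np.nan, np.nan],
        },
        index=pd.Index(["plus", "minus"], name="gene_id"),
    )
    return GenomeAnnotation(genes, {"chr1": 10_000})
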