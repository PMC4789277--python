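import numpy as np
import pytest

from mbdscan.pipeline import PipelineConfig, call_dmrs
from mbdscan.synth import TruthConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A 2 x 1 Mb study with planted sharp regions, decoys and inverse genes."""
    return simulate_study(
        11,
        n_chroms=2,
        chrom_length=1_000_000,
        n_genes=40,
        n_islands=25,
        config=TruthConfig(
            n_sharp01=20,
            n_sharp10=20,
            n_shared=10,
            n_inverse_genes=6,
            n_concordant_genes=2,
            n_de_only_genes=3,
        ),
    )


@pytest.fixture(scope="session")
def small_call(small_study):
    return call_dmrs(small_study.matrix, PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
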