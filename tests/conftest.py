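import warnings

import numpy as np
import pytest

from aesig.autoencoder import TrainingConfig
from aesig.io import ExpressionMatrix
from aesig.synthetic import SimulationConfig, generate_cohort
from aesig.workflow import decompose

warnings.filterwarnings("ignore", category=RuntimeWarning, module="lifelines")


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = SimulationConfig(
        n_samples=60,
        n_genes=80,
        n_immune_genes=25,
        n_intrinsic_genes=25,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort):
    config = TrainingConfig(
        epochs=4, batch_size=16, seed=7, hidden_sizes=(10, 6, 4), dtype="float32"
    )
    bundle, selection = decompose(
        tiny_cohort.expression,
        tiny_cohort.lymphocyte,
        tiny_cohort.clinical,
        k=15,
        config=config,
    )
    return bundle, selection


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(5)]
    samples = [f"S{j}" for j in range(10)]
    return ExpressionMatrix(genes, samples, rng.uniform(1, 100, (5, 10)), space="raw")
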