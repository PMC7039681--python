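import numpy as np
import pytest

from burstline.synthetic_data import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic experiment shared across read-only tests."""
    config = SimConfig(n_genes=300, n_cells_per_condition=300, seed=11)
    wt, ko, truth, tss, peaks = generate_experiment(config)
    return {"config": config, "wt": wt, "ko": ko, "truth": truth,
            "tss": tss, "peaks": peaks}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
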