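import numpy as np
import pandas as pd
import pytest

import tmecausal as tc


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = tc.SimulationConfig(
        n_samples=300, n_genes=400, n_signature_genes=40, seed=7
    )
    counts, clinical, truth = tc.generate_cohort(cfg)
    return cfg, counts, clinical, truth


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{i}" for i in range(12)]
    mu = 2.0 ** rng.uniform(3, 8, size=30)
    r = 1 / 0.2
    return pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu[:, None]), size=(30, 12)),
        index=genes,
        columns=samples,
    )
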