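import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from emtrn import SimulationParams, StudyConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> StudyConfig:
    """A scaled-down study for fast Monte-Carlo checks."""
    sim = SimulationParams(
        n_chrom=2,
        enhancer_probes_per_chrom=120,
        n_lncrna=40,
        n_mrna=80,
        n_mirna=60,
        n_tumor=30,
        n_normal=15,
        n_validation_tumor=16,
        n_validation_normal=8,
        module_shapes=((2, 3), (2, 2)),
        n_extra_links=2,
        n_decoy_links=2,
        n_promoter_regulated=4,
        n_planted_hyper=2,
        **overrides,
    )
    return StudyConfig(seed=seed, sim=sim)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def beta_matrix():
    """A complete 12-probe x 10-sample beta matrix with labelled groups."""
    gen = np.random.default_rng(7)
    values = pd.DataFrame(
        np.round(np.clip(gen.beta(2.0, 2.0, size=(12, 10)), 0.01, 0.99), 6),
        index=[f"cg{i:03d}" for i in range(12)],
        columns=[f"T{i}" for i in range(6)] + [f"N{i}" for i in range(4)],
    )
    groups = pd.Series(["tumor"] * 6 + ["normal"] * 4, index=values.columns)
    return values, groups
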