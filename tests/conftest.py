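import numpy as np
import pytest

import incimort as im


@pytest.fixture(scope="session")
def mid_panel():
    """A 30k-person panel under the default study conditions."""
    cfg = im.PanelConfig(n_persons=30_000, seed=11)
    return cfg, im.generate_panel(cfg)


@pytest.fixture(scope="session")
def lc_truth():
    """A noise-free Lee-Carter surface with known parameters."""
    ages = np.arange(45.0, 90.0)
    years = np.arange(2005, 2014)
    rng = np.random.default_rng(42)
    A = len(ages)
    alpha = -10.0 + 0.085 * ages
    beta = rng.uniform(0.5, 1.5, A)
    beta /= beta.sum()
    kappa = -2.5 * (years - years.mean())
    m = np.exp(alpha[:, None] + beta[:, None] * kappa[None, :])
    return ages, years, alpha, beta, kappa, m
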