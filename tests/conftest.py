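"""Shared fixtures: small synthetic crowdsourcing worlds built at test time."""

import numpy as np
import pytest

from ddmcrowd import experiment_preset, fit_variational, make_dataset


@pytest.fixture(scope="session")
def small_world():
    """A reduced experiment-1 world: 60 items, 5 annotators."""
    cfg = experiment_preset(1, seed=11, n_items=60, n_annotators=5)
    ds, annotators = make_dataset(cfg)
    return cfg, ds, annotators


@pytest.fixture(scope="session")
def small_fit(small_world):
    """A converged variational state on the small world (plain, no RT)."""
    _, ds, _ = small_world
    return ds, fit_variational(ds.y)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
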