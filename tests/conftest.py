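from __future__ import annotations

import numpy as np
import pytest

from nitromir import synthetic


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact synthetic study shared across tests: 10 planted hairpins,
    30k reads per library, sequencing errors on."""
    outdir = tmp_path_factory.mktemp("study")
    return synthetic.write_simulation(
        outdir, n_hairpins=10, depth_a=30_000, depth_b=30_000,
        error_rate=0.005, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
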