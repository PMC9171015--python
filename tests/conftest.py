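import numpy as np
import pytest

import cocscreen as cs


@pytest.fixture(scope="session")
def maturation_counts():
    """Bundled nuclear-maturation contingency table (5 groups x MII/abnormal)."""
    return cs.load_counts("nuclear_maturation")


@pytest.fixture(scope="session")
def worked_nucleus_scene():
    """Noiseless field matching the documented worked COC: 227 nuclei,
    7 TUNEL-only, 10 double-positive."""
    return cs.make_coc_nucleus_scene(
        n_total=227, n_tunel_only=7, n_ethd1_only=0, n_double=10,
        noise_sd=0.0, seed=4,
    )


@pytest.fixture(scope="session")
def oocyte_stack():
    """Noiseless 11-plane oocyte sphere stack, cortex/center ratio 3."""
    return cs.make_oocyte_scene(radius_px=100, true_ratio=3.0, noise_sd=0.0,
                                n_z=11, seed=1)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
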