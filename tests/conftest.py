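import numpy as np
import pytest

import apoptimer as ap


@pytest.fixture(scope="session")
def params():
    return ap.default_parameters()


@pytest.fixture(scope="session")
def hela_state():
    return ap.default_initial_state()


@pytest.fixture(scope="session")
def ranges():
    return ap.default_ranges()


def random_states(n, seed, ranges):
    """Random virtual-cell initial states drawn from the screening ranges."""
    rng = np.random.default_rng(seed)
    base = ap.default_initial_state()
    out = []
    for _ in range(n):
        out.append(
            base.replace(
                apaf1=float(rng.uniform(*ranges["apaf1"])),
                pc9=float(rng.uniform(*ranges["pc9"])),
                pc3=float(rng.uniform(*ranges["pc3"])),
                xiap=float(rng.uniform(*ranges["xiap"])),
                smac_mito=float(rng.uniform(*ranges["smac"])),
            )
        )
    return out
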