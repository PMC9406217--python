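from importlib import resources

import numpy as np
import pytest

from foxscreen import motifs


@pytest.fixture(scope="session")
def forkhead_pwm() -> motifs.PWM:
    """Bundled synthetic forkhead-style scoring matrix."""
    ref = resources.files("foxscreen.data").joinpath("synthetic_forkhead.pfm")
    with resources.as_file(ref) as path:
        pfm = motifs.read_jaspar(path)
    return motifs.build_pwm(pfm)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
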