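import numpy as np
import pytest

from nirbran import Block, GeneratorConfig, SpectraSet, generate


@pytest.fixture(scope="session")
def small_pair():
    """A small default-condition DR/DT pair (n=30, coarse grids)."""
    cfg = GeneratorConfig(
        n_samples=30,
        dr_grid=(4000.0, 12000.0, 32.0),
        dt_grid=(5793.0, 12489.0, 32.0),
        seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def study_pair():
    """A study-sized pair (n=141) on the default grids."""
    return generate(GeneratorConfig(n_samples=141, seed=5))


@pytest.fixture
def toy_set():
    """Hand-constructed 3-sample, 5-point DR set with references."""
    return SpectraSet(
        sample_ids=["a", "b", "c"],
        block=Block.DR,
        wavenumbers=[4000.0, 4008.0, 4016.0, 4024.0, 4032.0],
        absorbance=np.array(
            [
                [0.10, 0.20, 0.30, 0.25, 0.15],
                [0.12, 0.22, 0.33, 0.27, 0.16],
                [0.09, 0.18, 0.28, 0.24, 0.14],
            ]
        ),
        reference=np.array([3.5, 4.1, 3.2]),
    )
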