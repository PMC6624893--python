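import numpy as np
import pytest

from bpgrowth import AnnealConfig, BPParameters, ExponentPair, paper_dataset


@pytest.fixture(scope="session")
def paper():
    """The built-in 14-point xenograft series."""
    return paper_dataset()


@pytest.fixture(scope="session")
def truth_params():
    """The best-fitting full-data curve (annealing-rounded parameters);
    used as the generating truth for synthetic-data experiments."""
    return BPParameters(ExponentPair(1.62, 2.44), 5.02e-4, 5.55e-7, 318.5)


@pytest.fixture
def quick_cfg():
    """Reduced annealing budgets for unit tests (full restart interval)."""
    return AnnealConfig(seed=7).scaled(25)


@pytest.fixture
def full_cfg():
    """The reference budgets (50k cold / 10k warm / restart 1k)."""
    return AnnealConfig(seed=7)


@pytest.fixture(scope="session")
def paper_times():
    return np.array([0, 9, 20, 32, 43, 54, 65, 76, 82, 87, 93, 98, 107, 114],
                    dtype=float)
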