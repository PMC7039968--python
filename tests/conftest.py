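import numpy as np
import pytest

from mbstereo import NetworkParams, ResponseTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A miniature network that keeps simulation tests fast."""
    return NetworkParams(n_pns=20, n_kcs=200, kc_threshold=40.0,
                         n_odors=5, n_individuals=2)


@pytest.fixture
def locust_style_table(rng):
    """A 6 individuals x 6 odors table shaped like the locust MBON data:
    three odorants at two concentrations, responses scaling with
    concentration plus individual jitter."""
    odors = [f"{od}_{conc}" for conc in ("lo", "hi")
             for od in ("cyclohexanone", "octanol", "hexanol")]
    base = np.array([10.0, 14.0, 18.0, 30.0, 38.0, 46.0])
    values = base[None, :] + rng.normal(0, 2.0, size=(6, 6))
    return ResponseTable(values, individuals=[f"locust{i}" for i in range(6)],
                         odors=odors)
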