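import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tandemrrm.containers import PeakList

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_peaklist(n=10, seed=0, intensity=1e6, label="apo"):
    rng = np.random.default_rng(seed)
    return PeakList(
        pd.DataFrame(
            {
                "residue_number": np.arange(1, n + 1),
                "residue_name": ["A"] * n,
                "dH_ppm": rng.uniform(7.0, 9.5, n).round(4),
                "dN_ppm": rng.uniform(105.0, 130.0, n).round(3),
                "intensity": np.full(n, float(intensity)),
            }
        ),
        label=label,
    )


@pytest.fixture
def ref_peaklist():
    return make_peaklist(n=12, seed=5)


@pytest.fixture
def coil_structure():
    from tandemrrm.synth import gen_structure

    return gen_structure(30, "coil", seed=2)


@pytest.fixture
def spread_vectors():
    """40 well-spread unit vectors indexed like residues."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=(40, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return pd.DataFrame(v, columns=["x", "y", "z"], index=np.arange(2, 42))
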