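import numpy as np
import pandas as pd
import pytest

from cytoploid.synthetic import SyntheticSpec, preset_cytotype, sample_nuclei


@pytest.fixture(scope="session")
def gamete_sample() -> pd.DataFrame:
    """A large, well-separated gamete-like population (G1 at 0.5, G2 at 1.0)."""
    spec = SyntheticSpec(
        class_centers=(0.5, 1.0), class_weights=(18 / 26, 8 / 26),
        cv=(0.16, 0.16), n=1000, seed=42,
        labels=dict(species="C. prolifera", portion="gamete",
                    reproductive=True),
    )
    return sample_nuclei(spec)


@pytest.fixture(scope="session")
def sterile_frond_sample() -> pd.DataFrame:
    """One draw of the sterile frond preset at its published size."""
    return sample_nuclei(preset_cytotype("prolifera_sterile_frond", seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
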