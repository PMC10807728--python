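import numpy as np
import pytest

from siftersim.synthetic_data_io import SampleSpec, StudyConfig, generate_study


@pytest.fixture(scope="session")
def noise_free_biradical_entry():
    """One clean biradical study entry (r=3.0 nm, sigma=0.2 nm, lambda=0.3)."""
    cfg = StudyConfig(samples=(SampleSpec(name="bi_clean", kind="bi"),),
                      tau0_list_us=(2.5,), snr=float("inf"), master_seed=17)
    return generate_study(cfg).entries[0]


@pytest.fixture(scope="session")
def noise_free_mono_entry():
    cfg = StudyConfig(samples=(SampleSpec(name="mono_clean", kind="mono"),),
                      tau0_list_us=(2.5,), snr=float("inf"), master_seed=17)
    return generate_study(cfg).entries[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
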