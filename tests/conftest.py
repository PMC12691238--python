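import numpy as np
import pytest

from pedlipid import CohortConfig, LipidPanel, generate


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at n=2000 with a fixed seed."""
    return generate(CohortConfig(n=2000, seed=1))


@pytest.fixture()
def median_panel():
    """A panel at the emulated cohort's median lipid values."""
    return LipidPanel(
        subject_id="median",
        sex="girl",
        age_years=13,
        tc=153.0,
        hdl=54.0,
        tg=81.0,
        ldl_direct=95.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20230401)
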