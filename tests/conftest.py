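import numpy as np
import pytest

import somnopharm as sp


@pytest.fixture(scope="session")
def cno_study():
    """Full study run on the CNO-like preset cohort (n=12, fixed seed)."""
    cfg = sp.StudyConfig(preset="cno-like", n_animals=12, seed=1, spectra=True)
    return sp.run_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Full study run on the identity-drug cohort (n=12, fixed seed)."""
    cfg = sp.StudyConfig(preset="null", n_animals=12, seed=1, spectra=True)
    return sp.run_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def series_from(text: str, **kw) -> sp.EpochSeries:
    """Build an EpochSeries from a compact state string like 'WWNNR'."""
    return sp.EpochSeries.from_states(list(text), **kw)


@pytest.fixture
def make_series():
    return series_from
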