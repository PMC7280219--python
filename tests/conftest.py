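import numpy as np
import pytest

from dermaflim import AnalysisConfig, CohortConfig

#: Canonical time axis: 256 bins over 12.5 ns (48.8 ps bins).
N_BINS = 256
TIME_RANGE_NS = 12.5
DT_NS = TIME_RANGE_NS / N_BINS


def biexp_trace(a1, tau1, a2, tau2, n_bins=N_BINS, dt=DT_NS):
    t = (np.arange(n_bins) + 0.5) * dt
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


@pytest.fixture(scope="session")
def tiny_cohort_cfg():
    """Smallest legal acquisition geometry, for smoke-scale cohorts."""
    return CohortConfig(frame_size=64, n_time_bins=64, layers_only=True)


@pytest.fixture(scope="session")
def fast_analysis_cfg():
    return AnalysisConfig(fit_stride=8)
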