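import warnings

import pytest

import cryptdrift as cd

# arviz emits a refactor FutureWarning at import; irrelevant to the suite
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-size cohort shared across inference tests."""
    return cd.simulate_cohort(cd.CohortSimParams(n_patients=100, seed=3))


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-draw MCMC settings for test runtime."""
    return cd.InferenceConfig(seed=1, n_draws=800, n_warmup=800)


@pytest.fixture()
def spiked_matrix():
    """30-sample count matrix with one VAF-5% spike in both replicates."""
    panel = cd.random_panel(1, insert_length=20, seed=5)
    ref = panel["amp00"].reference_sequence
    alt = "A" if ref[30] != "A" else "C"
    matrix = cd.simulate_amplicon_counts(
        panel, 30, 0.002, 0.0005, [("S03", "amp00", 30, alt, 0.05)], 2000, seed=7
    )
    return panel, matrix, ("S03", 30, alt)
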