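import warnings

import numpy as np
import pytest

from nirsconn.synthetic import (
    ArtifactSpec,
    CohortSpec,
    generate_cohort,
    generate_network,
    simulate_roi_timeseries,
    synthesize_raw_recording,
)

# statsmodels emits convergence/iteration chatter irrelevant to the checks
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_network():
    return generate_network(edge_density=0.2, seed=11)


@pytest.fixture(scope="session")
def small_series(small_network):
    series, truth = simulate_roi_timeseries(small_network, n_samples=1500, seed=12)
    return series, truth


@pytest.fixture(scope="session")
def clean_recording():
    """Artifact-free recording from an uncoupled network (round-trip fixture)."""
    net = generate_network(edge_density=0.0, seed=21)
    latent, _ = simulate_roi_timeseries(net, n_samples=800, seed=22)
    rec = synthesize_raw_recording(
        latent, artifact_spec=ArtifactSpec.none(), seed=23
    )
    return latent, rec


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=5))
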