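import numpy as np
import pytest

from dceauc import PhantomSpec, TissueCurveParams, generate_dce_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default heterogeneous phantom, no noise, no artifacts."""
    spec = PhantomSpec(noise_sd=0.0, artifact_fraction=0.0, seed=7)
    series, pair, truth = generate_dce_phantom(spec)
    return spec, series, pair, truth


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """Noiseless phantom with identical tissue curves in every tumor voxel."""
    spec = PhantomSpec(
        noise_sd=0.0,
        artifact_fraction=0.0,
        tissue_curve_params=TissueCurveParams(amp_spread=0.0),
        seed=7,
    )
    series, pair, truth = generate_dce_phantom(spec)
    return spec, series, pair, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240912)
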