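import numpy as np
import pytest

from gluten_nir.synthetic import (
    ExperimentDesign,
    InstrumentModel,
    TrajectoryParams,
    simulate_reference_trajectories,
    simulate_spectra,
)


@pytest.fixture(scope="session")
def default_refs():
    """Reference table for the standard protocol: 4 power densities x 16 timepoints."""
    return simulate_reference_trajectories(ExperimentDesign(), TrajectoryParams(), seed=11)


@pytest.fixture(scope="session")
def default_spectra(default_refs):
    return simulate_spectra(default_refs, InstrumentModel(), seed=12, replicates=3)


@pytest.fixture(scope="session")
def noiseless_instrument():
    """No baseline, no scatter, no detector noise, no saturation: spectra are
    an exact linear mixture of the analyte bands."""
    from gluten_nir.synthetic import default_band_library

    bands = tuple(b for b in default_band_library() if b.label in ("SH", "SS"))
    return InstrumentModel(
        band_library=bands,
        baseline_order=0,
        baseline_coeffs=(),
        scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
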