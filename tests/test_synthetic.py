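"""Generator behaviour: protocol bookkeeping, trajectory structure, forward model."""

import numpy as np
import pandas as pd
import pytest

from gluten_nir.preprocess import snv
from gluten_nir.synthetic import (
    ConfigurationError,
    DesignError,
    ExperimentDesign,
    InstrumentModel,
    SpectralBand,
    TrajectoryParams,
    simulate_reference_trajectories,
    simulate_spectra,
)


class TestDesign:
    def test_default_protocol_counts(self):
        d = ExperimentDesign()
        assert d.n_samples == 64
        assert len(d.timepoints) == 16
        assert d.timepoints[0] == 0.0 and d.timepoints[-1] == 30.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration_min=30.0, sampling_interval_min=7.0),
            dict(replicates_per_sample=0),
            dict(power_densities=(-5.0, 80.0)),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(DesignError):
            ExperimentDesign(**kwargs)


class TestTrajectories:
    def test_one_row_per_density_timepoint(self, default_refs):
        assert len(default_refs) == 64
        assert not default_refs.duplicated(["power_density_W_per_L", "time_min"]).any()
        assert default_refs["sample_id"].is_unique

    def test_values_stay_in_physical_ranges(self, default_refs):
        assert default_refs["SH_umol_g"].between(1.95, 5.43).all()
        assert default_refs["SS_umol_g"].between(32.2, 75.5).all()

    def test_zero_amplitude_zero_noise_is_constant(self):
        params = TrajectoryParams(
            sh_amp0=0, sh_amp_slope=0, sh_noise_sd=0, ss_amp0=0, ss_amp_slope=0, ss_noise_sd=0
        )
        refs = simulate_reference_trajectories(ExperimentDesign(), params, seed=3)
        for p, grp in refs.groupby("power_density_W_per_L"):
            assert grp["SH_umol_g"].nunique() == 1
            assert grp["SS_umol_g"].nunique() == 1

    def test_fluctuation_grows_with_power_density(self):
        """Higher acoustic power drives stronger SH fluctuation over time."""
        design = ExperimentDesign(power_densities=(0.0, 160.0))
        refs = simulate_reference_trajectories(design, TrajectoryParams(), seed=5)
        var = refs.groupby("power_density_W_per_L")["SH_umol_g"].var()
        assert var[160.0] > var[0.0]

    def test_seed_reproducibility_bitwise(self):
        a = simulate_reference_trajectories(ExperimentDesign(), seed=9)
        b = simulate_reference_trajectories(ExperimentDesign(), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSpectra:
    def test_protocol_spectrum_counts(self, default_spectra):
        assert default_spectra.n_spectra == 192
        assert default_spectra.n_channels == 256
        assert np.all(np.diff(default_spectra.wavelengths) > 0)

    def test_noiseless_spectra_equal_band_mixture(self, default_refs, noiseless_instrument):
        spec = simulate_spectra(default_refs, noiseless_instrument, seed=7, replicates=1)
        wl = noiseless_instrument.wavelengths
        expected = np.zeros_like(spec.absorbance)
        for i, (_, rec) in enumerate(default_refs.iterrows()):
            for band in noiseless_instrument.band_library:
                level = rec["SH_umol_g"] if band.label == "SH" else rec["SS_umol_g"]
                expected[i] += band.loading * level * np.exp(
                    -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
                )
        np.testing.assert_allclose(spec.absorbance, expected, atol=1e-12)

    def test_snv_cancels_gain_and_offset_between_replicates(self, default_refs):
        """Replicates of one aliquot share chemistry; after SNV their spectra agree."""
        inst = InstrumentModel(noise_sd=0.0, scatter_gain_sd=0.1, scatter_offset_sd=0.05)
        spec = simulate_spectra(default_refs.head(2), inst, seed=21, replicates=2)
        z = snv(spec.absorbance)
        np.testing.assert_allclose(z[0], z[1], atol=1e-8)
        np.testing.assert_allclose(z[2], z[3], atol=1e-8)

    def test_seeded_spectra_bitwise_reproducible(self, default_refs):
        a = simulate_spectra(default_refs, InstrumentModel(), seed=4, replicates=2)
        b = simulate_spectra(default_refs, InstrumentModel(), seed=4, replicates=2)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_empty_band_library_with_analytes_rejected(self, default_refs):
        inst = InstrumentModel(band_library=(), baseline_order=0, baseline_coeffs=())
        with pytest.raises(ConfigurationError):
            simulate_spectra(default_refs, inst, seed=1)

    def test_saturating_ss_response_is_sublinear(self):
        """Doubling SS less than doubles the band response once SS ~ K."""
        refs = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "power_density_W_per_L": [0.0, 0.0],
                "time_min": [0.0, 2.0],
                "SH_umol_g": [1e-12, 1e-12],
                "SS_umol_g": [40.0, 80.0],
            }
        )
        inst = InstrumentModel(
            band_library=(SpectralBand(1417.0, 14.0, "SS", 0.002),),
            baseline_order=0,
            baseline_coeffs=(),
            scatter_gain_sd=0.0,
            scatter_offset_sd=0.0,
            noise_sd=0.0,
            nonlinear_ss_saturation=50.0,
        )
        spec = simulate_spectra(refs, inst, seed=0, replicates=1)
        peak = np.argmax(spec.absorbance[0])
        ratio = spec.absorbance[1, peak] / spec.absorbance[0, peak]
        assert ratio < 1.6  # linear response would give 2.0

    def test_noise_free_full_spectrum_pls_recovers_sh(self, default_refs, noiseless_instrument):
        """Parameter recovery: the generator's linear forward model is exactly
        invertible by full-spectrum PLS."""
        from gluten_nir.io import build_dataset
        from gluten_nir.pls import fit_pls, predict

        spec = simulate_spectra(default_refs, noiseless_instrument, seed=13, replicates=1)
        ds = build_dataset(spec, default_refs)
        model = fit_pls(ds.X, ds.y_sh, 6)
        yhat = predict(model, ds.X)
        assert np.corrcoef(yhat, ds.y_sh)[0, 1] > 1 - 1e-9
        assert np.sqrt(np.mean((yhat - ds.y_sh) ** 2)) < 1e-7
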