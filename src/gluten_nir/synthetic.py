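"""Synthetic reference chemistry and NIR spectra for the ultrasound protocol.

No experimental spectra are publicly available for the wheat-gluten ultrasound
study, so this module generates data with the statistical structure the
downstream analysis assumes: SH/SS reference trajectories that fluctuate in a
power-dependent wave pattern, and absorbance spectra built from Gaussian
analyte/interferent bands on a polynomial baseline with multiplicative and
additive scatter.

The default :class:`ExperimentDesign` mirrors the acquisition protocol:
4 power densities (0/80/120/160 W/L), 30 min of sonication sampled every
2 min including t=0 (64 samples), triplicate spectra (192 spectra), and a
256-channel grid over 850-2500 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gluten_nir.io import SpectraSet

__all__ = [
    "ExperimentDesign",
    "TrajectoryParams",
    "SpectralBand",
    "InstrumentModel",
    "simulate_reference_trajectories",
    "simulate_spectra",
    "default_band_library",
    "REFERENCE_COLUMNS",
]

#: canonical column order of a reference table
REFERENCE_COLUMNS = ("sample_id", "power_density_W_per_L", "time_min", "SH_umol_g", "SS_umol_g")


class DesignError(ValueError):
    """Invalid experiment design (e.g. duration not divisible by interval)."""


class ParameterError(ValueError):
    """Invalid trajectory or instrument parameters."""


class ConfigurationError(ValueError):
    """Inconsistent instrument configuration."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling protocol of the ultrasound treatment runs.

    Parameters
    ----------
    power_densities
        Acoustic power densities in W/L, one treatment run each.
    duration_min
        Total sonication time in minutes.
    sampling_interval_min
        Minutes between aliquots.
    replicates_per_sample
        Number of spectra acquired per aliquot.
    include_time_zero
        Whether an untreated t=0 aliquot is sampled for each run.
    """

    power_densities: tuple[float, ...] = (0.0, 80.0, 120.0, 160.0)
    duration_min: float = 30.0
    sampling_interval_min: float = 2.0
    replicates_per_sample: int = 3
    include_time_zero: bool = True

    def __post_init__(self) -> None:
        if self.sampling_interval_min <= 0:
            raise DesignError("sampling_interval_min must be positive")
        n_steps = self.duration_min / self.sampling_interval_min
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise DesignError(
                f"duration_min={self.duration_min} is not divisible by "
                f"sampling_interval_min={self.sampling_interval_min}"
            )
        if self.replicates_per_sample < 1:
            raise DesignError("replicates_per_sample must be >= 1")
        if any(p < 0 for p in self.power_densities):
            raise DesignError("power densities must be non-negative")

    @property
    def timepoints(self) -> np.ndarray:
        start = 0.0 if self.include_time_zero else self.sampling_interval_min
        return np.arange(start, self.duration_min + 1e-9, self.sampling_interval_min)

    @property
    def n_samples(self) -> int:
        return len(self.power_densities) * len(self.timepoints)


@dataclass(frozen=True)
class TrajectoryParams:
    """Baseline + damped power-dependent oscillation model for SH and SS.

    Each analyte trajectory at power density P is

        y(t) = baseline + shift*(P/P_ref) + amp(P) * exp(-decay*t) * sin(2*pi*t/period + phase)
               + N(0, noise_sd)

    with ``amp(P) = amp0 + amp_slope * P / P_ref`` non-decreasing in P: higher
    acoustic power drives stronger fluctuation of the thiol/disulfide balance.
    The default amplitudes keep SH within roughly 1.95-5.42 umol/g and SS
    within roughly 32.3-75.4 umol/g, the observed physical ranges. The shift
    term reproduces the net effect of sonication (SH up, SS down relative to
    the stirred control).
    """

    sh_baseline: float = 3.6
    sh_shift: float = 0.3
    sh_amp0: float = 0.35
    sh_amp_slope: float = 1.15
    sh_noise_sd: float = 0.08
    ss_baseline: float = 52.0
    ss_shift: float = -3.0
    ss_amp0: float = 4.0
    ss_amp_slope: float = 12.0
    ss_noise_sd: float = 1.2
    period_min: float = 12.0
    decay_per_min: float = 0.01
    power_ref: float = 160.0

    def __post_init__(self) -> None:
        for name in ("sh_amp0", "sh_amp_slope", "ss_amp0", "ss_amp_slope"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.period_min <= 0:
            raise ParameterError("period_min must be positive")
        if self.sh_noise_sd < 0 or self.ss_noise_sd < 0:
            raise ParameterError("noise SDs must be non-negative")


@dataclass(frozen=True)
class SpectralBand:
    """One Gaussian absorption band.

    ``label`` is ``"SH"`` or ``"SS"`` for analyte bands (the loading is
    absorbance units per umol/g); any other label names an interferent species
    whose per-sample level is drawn around 1 and shared by all bands with the
    same label (so distinct wavelength regions can carry correlated
    interference).
    """

    center_nm: float
    width_nm: float  # Gaussian sigma
    label: str
    loading: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ParameterError("band width must be positive")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2)


def default_band_library() -> tuple[SpectralBand, ...]:
    """Band library placing SH and SS responses inside the wavelength regions
    the interval search is expected to recover, plus broad water/starch
    interferents and overtone structure elsewhere."""
    return (
        # SH (free thiol) linked bands: 869-947, 1207-1284, 1458-1536, 2205-2274 nm
        SpectralBand(908.0, 18.0, "SH", 0.012),
        SpectralBand(1245.0, 20.0, "SH", 0.010),
        SpectralBand(1497.0, 18.0, "SH", 0.008),
        SpectralBand(2240.0, 16.0, "SH", 0.009),
        # SS (disulfide) linked bands: 933-992, 1388-1446, 2091-2148, 2217-2274 nm
        SpectralBand(962.0, 14.0, "SS", 0.0018),
        SpectralBand(1417.0, 14.0, "SS", 0.0022),
        SpectralBand(2120.0, 13.0, "SS", 0.0016),
        SpectralBand(2245.0, 13.0, "SS", 0.0020),
        # interferents: water OH overtones, starch CH/OH combination bands
        SpectralBand(1940.0, 60.0, "water", 0.40),
        SpectralBand(1450.0, 50.0, "water", 0.25),
        SpectralBand(2100.0, 45.0, "starch", 0.12),
        SpectralBand(1200.0, 80.0, "starch", 0.08),
    )


@dataclass(frozen=True)
class InstrumentModel:
    """Forward model of the fibre-optic NIR spectrometer.

    Each replicate spectrum is

        a(lambda) = gain * [ sum_bands loading * G(lambda) * level + baseline(lambda) ]
                    + offset + N(0, noise_sd)

    where ``gain ~ 1 + N(0, scatter_gain_sd)`` and ``offset ~ N(0,
    scatter_offset_sd)`` model multiplicative/additive scatter from suspended
    particles, ``baseline`` is a polynomial without constant term in the
    normalised wavelength (degree ``baseline_order``; order 0 means no
    baseline), and the SS band level optionally saturates as
    ``SS / (1 + SS / K)`` with half-saturation constant
    ``nonlinear_ss_saturation`` (K = inf disables it), reflecting the weak,
    nonlinear sensitivity of NIR to S-S stretching.
    """

    lambda_min: float = 850.0
    lambda_max: float = 2500.0
    n_channels: int = 256
    band_library: tuple[SpectralBand, ...] = field(default_factory=default_band_library)
    baseline_order: int = 2
    baseline_coeffs: tuple[float, ...] = (0.25, -0.10)
    scatter_gain_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 1e-3
    interferent_level_sd: float = 0.3
    nonlinear_ss_saturation: float = math.inf

    def __post_init__(self) -> None:
        if not self.lambda_min < self.lambda_max:
            raise ParameterError("lambda_min must be < lambda_max")
        if self.n_channels < 2:
            raise ParameterError("n_channels must be >= 2")
        if self.noise_sd < 0 or self.scatter_gain_sd < 0 or self.scatter_offset_sd < 0:
            raise ParameterError("noise/scatter SDs must be non-negative")
        if len(self.baseline_coeffs) != self.baseline_order:
            raise ParameterError(
                f"baseline_coeffs has {len(self.baseline_coeffs)} terms, "
                f"baseline_order={self.baseline_order} requires exactly that many"
            )
        if self.nonlinear_ss_saturation <= 0:
            raise ParameterError("nonlinear_ss_saturation must be positive (inf disables)")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.lambda_min, self.lambda_max, self.n_channels)

    def baseline(self) -> np.ndarray:
        u = (self.wavelengths - self.lambda_min) / (self.lambda_max - self.lambda_min)
        out = np.zeros_like(u)
        for j, c in enumerate(self.baseline_coeffs, start=1):
            out += c * u**j
        return out


def simulate_reference_trajectories(
    design: ExperimentDesign,
    params: TrajectoryParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the per-aliquot SH/SS reference table.

    Returns one row per (power density, timepoint) with columns
    ``sample_id, power_density_W_per_L, time_min, SH_umol_g, SS_umol_g``,
    ordered by power density then time. The oscillation phase is random per
    (analyte, power-density run); all randomness flows from ``seed``.
    """
    params = params or TrajectoryParams()
    rng = np.random.default_rng(seed)
    t = design.timepoints
    rows = []
    for p in design.power_densities:
        rel = p / params.power_ref
        damp = np.exp(-params.decay_per_min * t)
        osc = 2.0 * np.pi * t / params.period_min
        sh_phase = rng.uniform(0, 2 * np.pi)
        ss_phase = rng.uniform(0, 2 * np.pi)
        sh_amp = params.sh_amp0 + params.sh_amp_slope * rel
        ss_amp = params.ss_amp0 + params.ss_amp_slope * rel
        sh = (
            params.sh_baseline
            + params.sh_shift * rel
            + sh_amp * damp * np.sin(osc + sh_phase)
            + rng.normal(0.0, params.sh_noise_sd, size=t.size)
        )
        ss = (
            params.ss_baseline
            + params.ss_shift * rel
            + ss_amp * damp * np.sin(osc + ss_phase)
            + rng.normal(0.0, params.ss_noise_sd, size=t.size)
        )
        for i, ti in enumerate(t):
            rows.append(
                {
                    "sample_id": f"P{int(round(p)):03d}_t{int(round(ti)):02d}",
                    "power_density_W_per_L": float(p),
                    "time_min": float(ti),
                    "SH_umol_g": float(sh[i]),
                    "SS_umol_g": float(ss[i]),
                }
            )
    table = pd.DataFrame(rows, columns=list(REFERENCE_COLUMNS))
    if (table[["SH_umol_g", "SS_umol_g"]] <= 0).any().any():
        raise ParameterError("trajectory parameters produced non-positive SH or SS")
    return table


def simulate_spectra(
    refs: pd.DataFrame,
    instrument: InstrumentModel | None = None,
    seed: int = 0,
    replicates: int = 3,
) -> SpectraSet:
    """Generate replicate NIR spectra for every sample in a reference table.

    Per-sample interferent levels are drawn once and shared across the
    sample's replicates (they are properties of the aliquot); gain, offset and
    detector noise are drawn per replicate.
    """
    instrument = instrument or InstrumentModel()
    if len(refs) == 0:
        raise ConfigurationError("reference table is empty")
    missing = [c for c in REFERENCE_COLUMNS if c not in refs.columns]
    if missing:
        raise ConfigurationError(f"reference table missing columns: {missing}")
    analytes_present = (refs["SH_umol_g"].abs().gt(0).any()) or (refs["SS_umol_g"].abs().gt(0).any())
    if analytes_present and not instrument.band_library:
        raise ConfigurationError("band library is empty but reference analytes are nonzero")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")

    rng = np.random.default_rng(seed)
    wl = instrument.wavelengths
    profiles = np.array([b.profile(wl) for b in instrument.band_library]) if instrument.band_library else np.zeros((0, wl.size))
    labels = [b.label for b in instrument.band_library]
    loadings = np.array([b.loading for b in instrument.band_library])
    species = sorted({lab for lab in labels if lab not in ("SH", "SS")})
    baseline = instrument.baseline()
    k_sat = instrument.nonlinear_ss_saturation

    n = len(refs)
    spectra = np.empty((n * replicates, wl.size))
    sample_ids: list[str] = []
    rep_idx = np.empty(n * replicates, dtype=int)
    row = 0
    for _, rec in refs.iterrows():
        levels = {"SH": float(rec["SH_umol_g"])}
        ss = float(rec["SS_umol_g"])
        levels["SS"] = ss if math.isinf(k_sat) else ss / (1.0 + ss / k_sat)
        for sp in species:
            levels[sp] = rng.normal(1.0, instrument.interferent_level_sd)
        clean = baseline.copy()
        for j, lab in enumerate(labels):
            clean += loadings[j] * levels[lab] * profiles[j]
        for r in range(replicates):
            gain = 1.0 + rng.normal(0.0, instrument.scatter_gain_sd) if instrument.scatter_gain_sd > 0 else 1.0
            offset = rng.normal(0.0, instrument.scatter_offset_sd) if instrument.scatter_offset_sd > 0 else 0.0
            noise = rng.normal(0.0, instrument.noise_sd, size=wl.size) if instrument.noise_sd > 0 else 0.0
            spectra[row] = gain * clean + offset + noise
            sample_ids.append(str(rec["sample_id"]))
            rep_idx[row] = r
            row += 1
    return SpectraSet(
        wavelengths=wl,
        absorbance=spectra,
        sample_id=np.array(sample_ids, dtype=object),
        replicate=rep_idx,
    )
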