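"""Designed simulation experiments that probe the variable-selection machinery.

The planted-interval experiment places the analyte response in one known
spectral interval together with an overlapping interferent band, and puts a
second, pure band of the same interferent in another known interval. The
only way a two-interval model can cancel the interference is to select both
planted intervals, so the exhaustive synergy search has a unique correct
answer against which its recovery rate can be measured.
"""

from __future__ import annotations

import numpy as np

from gluten_nir.io import build_dataset
from gluten_nir.pls import CVScheme
from gluten_nir.sipls import sipls_search
from gluten_nir.synthetic import (
    ExperimentDesign,
    InstrumentModel,
    SpectralBand,
    TrajectoryParams,
    simulate_reference_trajectories,
    simulate_spectra,
)
from gluten_nir.evaluate import split_one_in_three

__all__ = ["planted_instrument", "run_planted_recovery", "PLANTED_INTERVALS"]

#: 1-based intervals (of 10) that carry the planted signal and interference
PLANTED_INTERVALS = (2, 7)


def planted_instrument(n_channels: int = 60, noise_sd: float = 2e-3) -> InstrumentModel:
    """Instrument whose SH response lives in interval 2 of 10 and whose
    interferent spans intervals 2 and 7 (shared species, so interval 7 is
    informative only as a correction channel)."""
    wl = np.linspace(850.0, 2500.0, n_channels)
    per = n_channels // 10
    mid = lambda itv: float(wl[(itv - 1) * per + per // 2])  # noqa: E731
    width = float(wl[1] - wl[0]) * 1.2
    return InstrumentModel(
        n_channels=n_channels,
        band_library=(
            SpectralBand(mid(2), width, "SH", 0.010),
            SpectralBand(mid(2) + width / 2, width, "turbidity", 0.050),
            SpectralBand(mid(7), width, "turbidity", 0.050),
        ),
        baseline_order=0,
        baseline_coeffs=(),
        scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        noise_sd=noise_sd,
        interferent_level_sd=0.3,
    )


def run_planted_recovery(
    n_replicates: int = 20,
    seed: int = 0,
    k: int = 10,
    max_pc: int = 4,
) -> dict:
    """Repeat the two-interval exhaustive search on freshly simulated data.

    Returns the fraction of replicates whose winning combination contains
    both planted intervals, plus the per-replicate winners.
    """
    design = ExperimentDesign(power_densities=(0.0, 160.0))
    traj = TrajectoryParams()
    instrument = planted_instrument()
    scheme = CVScheme(kind="kfold", k=5)
    winners = []
    hits = 0
    for rep in range(n_replicates):
        rep_seed = seed + 17 * rep
        refs = simulate_reference_trajectories(design, traj, seed=rep_seed)
        spectra = simulate_spectra(refs, instrument, seed=rep_seed + 1, replicates=1)
        ds = build_dataset(spectra, refs, average_replicates=True)
        ids = list(ds.metadata["sample_id"])
        cal_ids, pred_ids = split_one_in_three(ids)
        cal = np.array([ids.index(s) for s in cal_ids])
        pred = np.array([ids.index(s) for s in pred_ids])
        _, best = sipls_search(
            ds.X[cal],
            ds.y_sh[cal],
            ds.X[pred],
            ds.y_sh[pred],
            ds.wavelengths,
            k_range=(k,),
            combo_sizes=(2,),
            max_pc=max_pc,
            scheme=scheme,
        )
        winners.append(best.selected)
        if set(PLANTED_INTERVALS) <= set(best.selected):
            hits += 1
    return {
        "recovery_rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "winners": winners,
        "planted": PLANTED_INTERVALS,
    }
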