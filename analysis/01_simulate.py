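"""Simulate the ultrasound monitoring study and write the raw data tables.

Generates the SH/SS reference trajectories for 4 power densities (0/80/120/
160 W/L, 30 min sampled every 2 min => 64 aliquots) and triplicate NIR
spectra (192 x 256 channels, 850-2500 nm), then writes both CSVs.
"""

import argparse
from pathlib import Path

from gluten_nir.config import load_config
from gluten_nir.synthetic import (
    ExperimentDesign,
    InstrumentModel,
    TrajectoryParams,
    simulate_reference_trajectories,
    simulate_spectra,
)
from gluten_nir.io import write_reference_table, write_spectra

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--config", type=Path, default=None,
                help="YAML/JSON simulation config (design/trajectory/instrument)")
ap.add_argument("--out", type=Path, default=Path("results/data"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

if args.config:
    cfg = load_config(args.config)
    design, traj, instrument = cfg["design"], cfg["trajectory"], cfg["instrument"]
else:
    design, traj, instrument = ExperimentDesign(), TrajectoryParams(), InstrumentModel()
refs = simulate_reference_trajectories(design, traj, seed=args.seed)
spectra = simulate_spectra(refs, instrument, seed=args.seed + 1,
                           replicates=design.replicates_per_sample)

write_reference_table(refs, args.out / "reference.csv")
write_spectra(spectra, args.out / "spectra.csv")

print(f"samples: {len(refs)}  spectra: {spectra.n_spectra}  channels: {spectra.n_channels}")
print(f"SH range {refs.SH_umol_g.min():.3f}-{refs.SH_umol_g.max():.3f} umol/g, "
      f"SS range {refs.SS_umol_g.min():.3f}-{refs.SS_umol_g.max():.3f} umol/g")
print(f"written: {args.out}/reference.csv, {args.out}/spectra.csv")
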