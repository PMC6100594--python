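"""Compare spectral preprocessing methods by full-spectrum PLS RMSECV.

Reads the simulated tables written by 01_simulate.py (or regenerates them),
averages replicates, and ranks raw/SNV/MSC/1st/2nd-derivative preprocessing
for each analyte by the minimum cross-validated error of a full-spectrum
PLS model. On scatter-corrupted suspension spectra the scatter-correcting
methods (SNV, MSC) come out ahead of the raw spectra.
"""

import argparse
from pathlib import Path

from gluten_nir.io import build_dataset, read_reference_table, read_spectra
from gluten_nir.pls import CVScheme
from gluten_nir.preprocess import PreprocessSpec, compare_preprocessing

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

if not (args.data / "spectra.csv").exists():
    raise SystemExit(f"run analysis/01_simulate.py first (no {args.data}/spectra.csv)")
spectra = read_spectra(args.data / "spectra.csv")
refs = read_reference_table(args.data / "reference.csv")
ds = build_dataset(spectra, refs, average_replicates=True)

specs = [
    PreprocessSpec(method="none"),
    PreprocessSpec(method="snv"),
    PreprocessSpec(method="msc"),
    PreprocessSpec(method="sg_derivative", derivative_order=1),
    PreprocessSpec(method="sg_derivative", derivative_order=2),
]
args.out.mkdir(parents=True, exist_ok=True)
for analyte in ("SH", "SS"):
    table = compare_preprocessing(ds.X, ds.y(analyte), specs, max_pc=10,
                                  scheme=CVScheme(kind="kfold", k=5))
    path = args.out / f"preprocessing_{analyte}.tsv"
    table.to_csv(path, sep="\t", index=False)
    print(f"\n{analyte} (umol/g), best first:")
    print(table.to_string(index=False))
    print(f"written: {path}")
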