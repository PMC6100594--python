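"""Train the PCA-fed backpropagation network on the Si-PLS-selected channels.

Loads each analyte's winning interval combination from 03_sipls_search.py,
chooses the PCA input width by cross-validated network RMSECV, trains the
final three-layer network on the calibration set and reports prediction-set
metrics alongside the serialized model.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from gluten_nir.bpann import ANNConfig, fit_ann, predict_ann, select_pc_count
from gluten_nir.evaluate import compute_metrics, split_one_in_three
from gluten_nir.io import build_dataset, read_reference_table, read_spectra
from gluten_nir.pls import CVScheme
from gluten_nir.preprocess import PreprocessSpec, apply_preprocess
from gluten_nir.sipls import partition_intervals

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--max-pc", type=int, default=8)
args = ap.parse_args()

spectra = read_spectra(args.data / "spectra.csv")
refs = read_reference_table(args.data / "reference.csv")
ds = build_dataset(spectra, refs, average_replicates=True)
X = apply_preprocess(ds.X, PreprocessSpec(method="snv"))
ids = list(ds.metadata["sample_id"])
cal_ids, pred_ids = split_one_in_three(ids)
cal = np.array([ids.index(s) for s in cal_ids])
pred = np.array([ids.index(s) for s in pred_ids])

for analyte in ("SH", "SS"):
    winner_path = args.out / f"sipls_winner_{analyte}.json"
    if not winner_path.exists():
        raise SystemExit(f"run analysis/03_sipls_search.py first (no {winner_path})")
    winner = json.loads(winner_path.read_text())
    part = partition_intervals(X.shape[1], winner["n_intervals"])
    cols = part.combo_channels(tuple(i - 1 for i in winner["selected"]))
    y = ds.y(analyte)

    n_pc, curve = select_pc_count(X[cal][:, cols], y[cal], max_pc=args.max_pc,
                                  scheme=CVScheme(kind="kfold", k=5), seed=args.seed)
    model = fit_ann(X[cal][:, cols], y[cal], n_pc, config=ANNConfig(), seed=args.seed)
    metrics = compute_metrics(y[cal], predict_ann(model, X[cal][:, cols]),
                              y[pred], predict_ann(model, X[pred][:, cols]),
                              rmsecv=float(curve[n_pc - 1]))
    model.to_json(args.out / f"bpann_model_{analyte}.json")
    (args.out / f"bpann_metrics_{analyte}.json").write_text(json.dumps(metrics.as_dict(), indent=2))
    print(f"{analyte}: input PCs {n_pc} (RMSECV curve argmin), "
          f"Rc {metrics.rc:.4f}, RMSEC {metrics.rmsec:.3f}, Rp {metrics.rp:.4f}, "
          f"RMSEP {metrics.rmsep:.3f}, RPD {metrics.rpd:.2f}")
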