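"""Calibration/prediction split and regression-quality metrics.

The split takes every third sample (ordered by power density, then time)
into the prediction set — 64 samples give 43 calibration / 21 prediction.
Models are judged by Pearson correlations (Rc calibration, Rp prediction),
root-mean-square errors (RMSEC/RMSECV/RMSEP, umol/g) and the residual
prediction deviation RPD = SD(prediction-set reference) / RMSEP; RPD > 2 is
the conventional screening-quality bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsRecord",
    "split_one_in_three",
    "compute_metrics",
    "compare_models",
    "rpd",
    "pearson",
    "rmse",
]


class SplitSizeError(ValueError):
    """Too few samples to split."""


class ComparabilityError(ValueError):
    """Models were not fitted on the same split."""


def split_one_in_three(sample_ids: list | np.ndarray) -> tuple[list, list]:
    """Every third sample (1-based positions 3, 6, 9, ...) goes to prediction.

    The input order is significant and must already be deterministic
    (power density ascending, then time ascending).
    """
    ids = list(sample_ids)
    if len(ids) < 3:
        raise SplitSizeError(f"need >= 3 samples, got {len(ids)}")
    prediction = [ids[i] for i in range(2, len(ids), 3)]
    calibration = [ids[i] for i in range(len(ids)) if (i + 1) % 3 != 0]
    return calibration, prediction


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def rmse(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_ref) ** 2)))


def rpd(sd_reference: float, rmsep: float) -> float:
    """Residual prediction deviation: prediction-set reference SD over RMSEP.

    Returns inf when RMSEP is zero (perfect prediction).
    """
    if sd_reference <= 0:
        raise ValueError("reference SD must be positive")
    if rmsep == 0:
        return math.inf
    return sd_reference / rmsep


@dataclass
class MetricsRecord:
    """Evaluation metrics of one fitted model on one calibration/prediction split."""

    rc: float
    rp: float
    rp_squared: float
    rmsec: float  # umol/g
    rmsecv: float  # umol/g
    rmsep: float  # umol/g
    rpd: float  # dimensionless; inf flags RMSEP == 0
    n_cal: int
    n_pred: int

    def as_dict(self) -> dict:
        return {
            "Rc": self.rc,
            "Rp": self.rp,
            "Rp2": self.rp_squared,
            "RMSEC": self.rmsec,
            "RMSECV": self.rmsecv,
            "RMSEP": self.rmsep,
            "RPD": self.rpd,
            "n_cal": self.n_cal,
            "n_pred": self.n_pred,
        }


def compute_metrics(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_pred: np.ndarray,
    yhat_pred: np.ndarray,
    rmsecv: float = float("nan"),
) -> MetricsRecord:
    """Assemble the full metrics record from reference and predicted values.

    RPD uses the (n-1) sample SD of the prediction set's reference values —
    the convention that reproduces published RPDs from published SDs and
    RMSEPs.
    """
    y_cal = np.asarray(y_cal, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_cal.size < 2 or y_pred.size < 2:
        raise ValueError("need >= 2 samples in each set")
    rmsep_val = rmse(y_pred, yhat_pred)
    sd_pred = float(np.std(y_pred, ddof=1))
    return MetricsRecord(
        rc=pearson(y_cal, yhat_cal),
        rp=pearson(y_pred, yhat_pred),
        rp_squared=pearson(y_pred, yhat_pred) ** 2,
        rmsec=rmse(y_cal, yhat_cal),
        rmsecv=float(rmsecv),
        rmsep=rmsep_val,
        rpd=rpd(sd_pred, rmsep_val),
        n_cal=int(y_cal.size),
        n_pred=int(y_pred.size),
    )


def compare_models(
    sipls_metrics: MetricsRecord,
    ann_metrics: MetricsRecord,
    labels: tuple[str, str] = ("Si-PLS", "BP-ANN"),
) -> dict:
    """Side-by-side comparison; winner by higher Rp, ties by lower RMSEP."""
    if (sipls_metrics.n_cal, sipls_metrics.n_pred) != (ann_metrics.n_cal, ann_metrics.n_pred):
        raise ComparabilityError(
            "models evaluated on different splits: "
            f"{(sipls_metrics.n_cal, sipls_metrics.n_pred)} vs {(ann_metrics.n_cal, ann_metrics.n_pred)}"
        )
    table = pd.DataFrame(
        [sipls_metrics.as_dict(), ann_metrics.as_dict()], index=list(labels)
    )
    if ann_metrics.rp > sipls_metrics.rp:
        winner = labels[1]
    elif ann_metrics.rp < sipls_metrics.rp:
        winner = labels[0]
    else:
        winner = labels[1] if ann_metrics.rmsep < sipls_metrics.rmsep else labels[0]
    return {"table": table, "winner": winner}
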