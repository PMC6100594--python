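"""Synergy-interval PLS (Si-PLS) wavelength-region selection.

The full spectrum is split into k near-equal contiguous intervals
(k typically 15-30); every combination of 2, 3 or 4 intervals is scored by a
PLS model whose component count is chosen by cross-validated RMSECV on the
calibration set. The winning combination per k (and globally) is the one
with the lowest RMSECV; prediction-set metrics are reported for winners only
and never drive the selection. Removing channels that carry starch, water or
temperature interference rather than thiol signal is the point: irrelevant
variables dilute the PLS covariance structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from gluten_nir.pls import CVScheme, fit_pls, predict, rmsecv, select_n_components

__all__ = [
    "IntervalScheme",
    "SiPLSResult",
    "partition_intervals",
    "interval_to_wavelengths",
    "sipls_search",
    "n_combinations",
]


@dataclass(frozen=True)
class IntervalScheme:
    """Partition of the channel axis into k contiguous intervals.

    ``boundaries`` holds half-open 0-based channel ranges [start, end),
    ordered, disjoint, covering all channels, with sizes differing by at
    most one (larger intervals first).
    """

    n_channels: int
    n_intervals: int
    boundaries: tuple[tuple[int, int], ...]

    def channels(self, index: int) -> np.ndarray:
        """Channel indices of one interval (0-based interval index)."""
        start, end = self.boundaries[index]
        return np.arange(start, end)

    def combo_channels(self, combo: tuple[int, ...]) -> np.ndarray:
        """Concatenated channel indices of a combination of intervals."""
        return np.concatenate([self.channels(i) for i in sorted(combo)])


def partition_intervals(n_channels: int, k: int) -> IntervalScheme:
    """Split n channels into k contiguous intervals of near-equal size.

    The first (n mod k) intervals get ceil(n/k) channels, the rest floor(n/k).
    """
    if not 1 <= k <= n_channels:
        raise ValueError(f"k={k} must be in [1, {n_channels}]")
    base, extra = divmod(n_channels, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return IntervalScheme(n_channels=n_channels, n_intervals=k, boundaries=tuple(bounds))


def interval_to_wavelengths(
    scheme: IntervalScheme, index: int, wavelengths: np.ndarray
) -> tuple[float, float]:
    """Wavelengths (nm) of the first and last channel of interval ``index`` (0-based)."""
    if not 0 <= index < scheme.n_intervals:
        raise IndexError(f"interval index {index} outside [0, {scheme.n_intervals})")
    start, end = scheme.boundaries[index]
    return float(wavelengths[start]), float(wavelengths[end - 1])


def n_combinations(k: int, combo_sizes: tuple[int, ...] = (2, 3, 4)) -> int:
    """Number of interval combinations the exhaustive search evaluates."""
    from math import comb

    return sum(comb(k, s) for s in combo_sizes if s <= k)


@dataclass
class SiPLSResult:
    """Best interval combination for one interval count k.

    ``selected`` is reported 1-based, ascending. Calibration metrics (Rc,
    RMSEC, RMSECV) come from the calibration set; Rp/RMSEP from the
    independent prediction set.
    """

    n_intervals: int
    selected: tuple[int, ...]  # 1-based
    n_components: int
    rc: float
    rmsec: float
    rmsecv: float
    rp: float
    rmsep: float
    wavelength_ranges: tuple[tuple[float, float], ...]

    def as_dict(self) -> dict:
        return {
            "n_intervals": self.n_intervals,
            "selected": list(self.selected),
            "n_components": self.n_components,
            "Rc": self.rc,
            "RMSEC": self.rmsec,
            "RMSECV": self.rmsecv,
            "Rp": self.rp,
            "RMSEP": self.rmsep,
            "wavelength_ranges_nm": [list(r) for r in self.wavelength_ranges],
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def sipls_search(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    wavelengths: np.ndarray,
    k_range: range | tuple[int, ...] = range(15, 31),
    combo_sizes: tuple[int, ...] = (2, 3, 4),
    max_pc: int = 10,
    scheme: CVScheme | None = None,
) -> tuple[list[SiPLSResult], SiPLSResult]:
    """Exhaustive synergy-interval search.

    For each interval count k and every combination of ``combo_sizes``
    intervals, concatenates the combination's channels, selects the PLS
    component count by RMSECV on the calibration set, and keeps the
    combination with the lowest RMSECV. Ties break toward fewer components,
    then fewer intervals, then the lexicographically smallest index set, so
    the winner is independent of enumeration order. Returns the per-k
    winners (with prediction metrics) and the global winner.
    """
    scheme = scheme or CVScheme()
    X_cal = np.asarray(X_cal, dtype=float)
    X_pred = np.asarray(X_pred, dtype=float)
    if X_cal.shape[1] != X_pred.shape[1]:
        raise ValueError("calibration and prediction sets have different channel counts")
    if not combo_sizes:
        raise ValueError("combo_sizes must be non-empty")
    results: list[SiPLSResult] = []
    for k in k_range:
        if min(combo_sizes) > k:
            raise ValueError(f"smallest combination size {min(combo_sizes)} exceeds k={k}")
        part = partition_intervals(X_cal.shape[1], k)
        best = None  # (rmsecv, n_comp, len(combo), combo)
        for size in combo_sizes:
            if size > k:
                continue
            for combo in combinations(range(k), size):
                cols = part.combo_channels(combo)
                n_pc, curve = select_n_components(X_cal[:, cols], y_cal, max_pc=max_pc, scheme=scheme)
                key = (float(curve[n_pc - 1]), n_pc, len(combo), combo)
                if best is None or key < best:
                    best = key
        cv, n_pc, _, combo = best
        cols = part.combo_channels(combo)
        model = fit_pls(X_cal[:, cols], y_cal, n_pc)
        yhat_cal = predict(model, X_cal[:, cols])
        yhat_pred = predict(model, X_pred[:, cols])
        results.append(
            SiPLSResult(
                n_intervals=k,
                selected=tuple(i + 1 for i in combo),
                n_components=n_pc,
                rc=_pearson(y_cal, yhat_cal),
                rmsec=float(np.sqrt(np.mean((yhat_cal - y_cal) ** 2))),
                rmsecv=cv,
                rp=_pearson(y_pred, yhat_pred),
                rmsep=float(np.sqrt(np.mean((yhat_pred - y_pred) ** 2))),
                wavelength_ranges=tuple(
                    interval_to_wavelengths(part, i, wavelengths) for i in combo
                ),
            )
        )
    global_best = min(results, key=lambda r: (r.rmsecv, r.n_components, len(r.selected), r.selected))
    return results, global_best


def results_table(results: list[SiPLSResult]) -> pd.DataFrame:
    """Per-k report mirroring the interval-selection summary table."""
    return pd.DataFrame(
        [
            {
                "n_intervals": r.n_intervals,
                "selected_subintervals": str(list(r.selected)),
                "PCs": r.n_components,
                "Rc": r.rc,
                "RMSEC": r.rmsec,
                "RMSECV": r.rmsecv,
                "Rp": r.rp,
                "RMSEP": r.rmsep,
            }
            for r in results
        ]
    )
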