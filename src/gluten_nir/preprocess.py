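"""Spectral preprocessing: SNV, MSC and Savitzky-Golay derivatives.

These remove the scatter artefacts typical of in-situ fibre-optic NIR on a
stirred protein suspension: multiplicative gain from particle scattering,
additive baseline offsets and drift. SNV standardises each spectrum to zero
mean and unit (n-1) standard deviation; MSC regresses each spectrum on a
reference (the calibration-set mean) and removes the fitted slope/intercept;
derivatives suppress smooth baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessSpec",
    "snv",
    "msc",
    "sg_derivative",
    "apply_preprocess",
    "compare_preprocessing",
    "ZeroVarianceError",
    "DegenerateReferenceError",
]


class ZeroVarianceError(ValueError):
    """A spectrum has zero variance and cannot be SNV-scaled."""


class DegenerateReferenceError(ValueError):
    """MSC reference spectrum has zero variance."""


@dataclass(frozen=True)
class PreprocessSpec:
    """Configuration of one preprocessing method.

    ``method`` is one of ``none``, ``snv``, ``msc``, ``sg_derivative``. For
    derivatives, ``window_length`` must be odd and exceed ``poly_order``, and
    ``derivative_order`` is 1 or 2.
    """

    method: str = "snv"
    derivative_order: int = 1
    window_length: int = 11
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.method not in ("none", "snv", "msc", "sg_derivative"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.method == "sg_derivative":
            if self.window_length % 2 == 0:
                raise ValueError("window_length must be odd")
            if self.window_length <= self.poly_order:
                raise ValueError("window_length must exceed poly_order")
            if self.derivative_order not in (1, 2):
                raise ValueError("derivative_order must be 1 or 2")
            if self.poly_order < self.derivative_order:
                raise ValueError("poly_order must be >= derivative_order")

    @property
    def label(self) -> str:
        if self.method == "sg_derivative":
            return f"d{self.derivative_order}(w{self.window_length},p{self.poly_order})"
        return self.method


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to unit sample SD.

    Accepts a single spectrum (1-D) or a matrix (rows = spectra).
    """
    x = np.asarray(spectra, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("SNV requires at least 2 channels")
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ZeroVarianceError(f"spectrum {bad} is constant; SNV undefined")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if one_d else out


def msc(spectra: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is replaced by (x - b) / a where a, b are the
    least-squares slope and intercept of x regressed on the reference. When
    no reference is given the mean spectrum of the batch is used (requires
    >= 2 spectra). Correct prediction spectra against the calibration-set
    mean to avoid leakage.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if reference is None:
        if x.shape[0] < 2:
            raise ValueError("MSC without an explicit reference needs >= 2 spectra")
        reference = x.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateReferenceError("MSC reference spectrum has zero variance")
    a = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(a == 0):
        raise DegenerateReferenceError("fitted slope is zero for some spectrum")
    b = x.mean(axis=1) - a * ref.mean()
    out = (x - b[:, None]) / a[:, None]
    return out[0] if np.asarray(spectra).ndim == 1 else out


def sg_derivative(spectra: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Savitzky-Golay smoothed derivative (per channel index).

    Output length equals input length; edges use a polynomial fit on the
    truncated window (scipy's ``interp`` mode).
    """
    if spec.method != "sg_derivative":
        raise ValueError("spec.method must be 'sg_derivative'")
    x = np.asarray(spectra, dtype=float)
    if x.shape[-1] < spec.window_length:
        raise ValueError(
            f"window_length {spec.window_length} exceeds channel count {x.shape[-1]}"
        )
    return savgol_filter(
        x,
        window_length=spec.window_length,
        polyorder=spec.poly_order,
        deriv=spec.derivative_order,
        delta=1.0,
        axis=-1,
        mode="interp",
    )


def apply_preprocess(
    X: np.ndarray,
    spec: PreprocessSpec,
    msc_reference: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one preprocessing method to a spectra matrix."""
    if spec.method == "none":
        return np.asarray(X, dtype=float).copy()
    if spec.method == "snv":
        return snv(X)
    if spec.method == "msc":
        return msc(X, reference=msc_reference)
    return sg_derivative(X, spec)


def compare_preprocessing(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[PreprocessSpec],
    max_pc: int = 10,
    scheme=None,
):
    """Rank preprocessing methods by full-spectrum PLS cross-validation error.

    For each method, preprocesses X, selects the PLS component count by
    RMSECV and records the minimum RMSECV. Returns a DataFrame sorted by
    RMSECV ascending (ties broken by input order).
    """
    import pandas as pd

    from gluten_nir.pls import CVScheme, select_n_components

    if len(specs) < 1:
        raise ValueError("at least one preprocessing method required")
    scheme = scheme or CVScheme()
    rows = []
    for i, spec in enumerate(specs):
        Xp = apply_preprocess(X, spec)
        n_pc, curve = select_n_components(Xp, y, max_pc=max_pc, scheme=scheme)
        rows.append(
            {"method": spec.label, "n_components": n_pc, "rmsecv": float(curve[n_pc - 1]), "order_in": i}
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["rmsecv", "order_in"], kind="stable")
        .drop(columns="order_in")
        .reset_index(drop=True)
    )
    return table
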