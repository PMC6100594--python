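"""CSV dialects for spectra and reference tables, and dataset assembly.

Spectra are stored wide: ``sample_id,replicate,<wavelength>,...`` with one
column per channel, wavelengths printed with two decimals in the header.
Reference tables use the fixed header
``sample_id,power_density_W_per_L,time_min,SH_umol_g,SS_umol_g``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "Dataset",
    "ParseError",
    "AlignmentError",
    "read_spectra",
    "write_spectra",
    "read_reference_table",
    "write_reference_table",
    "build_dataset",
]


class ParseError(ValueError):
    """Malformed spectra or reference CSV."""


class AlignmentError(ValueError):
    """Spectra and reference tables cannot be aligned."""


@dataclass
class SpectraSet:
    """Replicate absorbance spectra on a common wavelength grid."""

    wavelengths: np.ndarray  # (n_channels,) nm, strictly increasing
    absorbance: np.ndarray  # (n_spectra, n_channels)
    sample_id: np.ndarray  # (n_spectra,) object
    replicate: np.ndarray  # (n_spectra,) int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ParseError("wavelengths must be strictly increasing")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ParseError(
                f"absorbance has {self.absorbance.shape[1]} channels, "
                f"wavelength grid has {self.wavelengths.size}"
            )
        if self.absorbance.shape[0] != self.sample_id.size or self.sample_id.size != self.replicate.size:
            raise ParseError("row metadata length does not match spectrum count")
        if not np.all(np.isfinite(self.absorbance)):
            raise ParseError("absorbance matrix contains non-finite values")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]


@dataclass
class Dataset:
    """Aligned modelling dataset: one X row per y entry."""

    X: np.ndarray  # (n_samples, n_channels)
    y_sh: np.ndarray  # umol/g
    y_ss: np.ndarray  # umol/g
    wavelengths: np.ndarray
    metadata: pd.DataFrame  # per-row sample_id, power_density_W_per_L, time_min

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (self.y_sh.size == n and self.y_ss.size == n and len(self.metadata) == n):
            raise AlignmentError("X rows, y entries and metadata rows must align one-to-one")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ParseError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y_sh)) and np.all(np.isfinite(self.y_ss))):
            raise ParseError("dataset contains non-finite values")

    def y(self, analyte: str) -> np.ndarray:
        if analyte == "SH":
            return self.y_sh
        if analyte == "SS":
            return self.y_ss
        raise KeyError(f"unknown analyte {analyte!r} (expected 'SH' or 'SS')")


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as wide CSV (header wavelengths at 2 decimals)."""
    cols = ["sample_id", "replicate"] + [f"{w:.2f}" for w in spectra.wavelengths]
    df = pd.DataFrame(spectra.absorbance, columns=cols[2:])
    df.insert(0, "replicate", spectra.replicate)
    df.insert(0, "sample_id", spectra.sample_id)
    df.to_csv(path, index=False)


def read_spectra(path: str | Path) -> SpectraSet:
    """Read the wide spectra CSV; validates numeric cells and wavelength order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if list(df.columns[:2]) != ["sample_id", "replicate"]:
        raise ParseError(f"{path}: header must start with sample_id,replicate")
    try:
        wavelengths = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric wavelength in header: {exc}") from exc
    if wavelengths.size < 1:
        raise ParseError(f"{path}: no wavelength columns")
    if np.any(np.diff(wavelengths) <= 0):
        bad = int(np.argmax(np.diff(wavelengths) <= 0)) + 1
        raise ParseError(f"{path}: header wavelengths not strictly increasing at column {bad + 2}")
    block = df.iloc[:, 2:]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(f"{path}: non-numeric or missing cell at data row {r + 1}, column {block.columns[c]!r}")
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=numeric.to_numpy(dtype=float),
        sample_id=df["sample_id"].to_numpy(dtype=object),
        replicate=pd.to_numeric(df["replicate"]).to_numpy(dtype=int),
    )


def write_reference_table(refs: pd.DataFrame, path: str | Path) -> None:
    from gluten_nir.synthetic import REFERENCE_COLUMNS

    refs[list(REFERENCE_COLUMNS)].to_csv(path, index=False)


def read_reference_table(path: str | Path) -> pd.DataFrame:
    from gluten_nir.synthetic import REFERENCE_COLUMNS

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing reference columns {missing}")
    for col in REFERENCE_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            r = int(vals.isna().idxmax())
            raise ParseError(f"{path}: non-numeric cell at row {r + 1}, column {col!r}")
        df[col] = vals
    return df[list(REFERENCE_COLUMNS)]


def build_dataset(
    spectra: SpectraSet,
    refs: pd.DataFrame,
    average_replicates: bool = True,
) -> Dataset:
    """Align spectra with reference chemistry into a modelling dataset.

    With ``average_replicates`` (the default) the triplicate spectra of each
    aliquot are averaged to a single X row, so the calibration works on
    samples rather than spectra. Otherwise each replicate keeps its own row
    and the reference values repeat.
    """
    ref_ids = set(refs["sample_id"].astype(str))
    spec_ids = [str(s) for s in spectra.sample_id]
    unmatched = sorted({s for s in spec_ids if s not in ref_ids})
    if unmatched:
        raise AlignmentError(f"sample_ids in spectra without reference rows: {unmatched}")

    ref_indexed = refs.set_index(refs["sample_id"].astype(str))
    if average_replicates:
        # preserve the order of first appearance in the spectra set
        order = list(dict.fromkeys(spec_ids))
        X = np.vstack(
            [spectra.absorbance[[i for i, s in enumerate(spec_ids) if s == sid]].mean(axis=0) for sid in order]
        )
        meta = ref_indexed.loc[order].reset_index(drop=True)
    else:
        X = spectra.absorbance.copy()
        meta = ref_indexed.loc[spec_ids].reset_index(drop=True)
        meta["replicate"] = spectra.replicate
    return Dataset(
        X=X,
        y_sh=meta["SH_umol_g"].to_numpy(dtype=float),
        y_ss=meta["SS_umol_g"].to_numpy(dtype=float),
        wavelengths=spectra.wavelengths.copy(),
        metadata=meta.drop(columns=["SH_umol_g", "SS_umol_g"]),
    )
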