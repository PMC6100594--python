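"""YAML/JSON configuration for the experiment design and instrument model.

A config file holds up to three top-level sections — ``design``,
``trajectory``, ``instrument`` — whose keys mirror the dataclass fields;
instrument band libraries are lists of ``[center_nm, width_nm, label,
loading]`` entries. Omitted sections fall back to the defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from gluten_nir.synthetic import ExperimentDesign, InstrumentModel, SpectralBand, TrajectoryParams

__all__ = ["load_config", "load_design", "load_instrument", "load_trajectory"]


def _read(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_design(section: dict) -> ExperimentDesign:
    if "power_densities" in section:
        section = {**section, "power_densities": tuple(section["power_densities"])}
    return ExperimentDesign(**section)


def load_trajectory(section: dict) -> TrajectoryParams:
    return TrajectoryParams(**section)


def load_instrument(section: dict) -> InstrumentModel:
    section = dict(section)
    if "band_library" in section:
        section["band_library"] = tuple(
            SpectralBand(float(c), float(w), str(lab), float(load))
            for c, w, lab, load in section["band_library"]
        )
    if "baseline_coeffs" in section:
        section["baseline_coeffs"] = tuple(section["baseline_coeffs"])
    return InstrumentModel(**section)


def load_config(path: str | Path) -> dict:
    """Load a full simulation config; returns dict with design, trajectory,
    instrument objects (defaults where the file is silent)."""
    raw = _read(path)
    unknown = set(raw) - {"design", "trajectory", "instrument"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {
        "design": load_design(raw.get("design", {})),
        "trajectory": load_trajectory(raw.get("trajectory", {})),
        "instrument": load_instrument(raw.get("instrument", {})),
    }
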