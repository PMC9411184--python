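"""JSON configuration loading for device, medium and schedule files."""

from __future__ import annotations

import json
from pathlib import Path

from .field_engine import ArrayGeometry, Medium, WATER, build_circular_array

__all__ = ["load_config", "geometry_from_config", "medium_from_config"]


def load_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def medium_from_config(cfg: dict) -> Medium:
    block = cfg.get("medium")
    if not block:
        return WATER
    return Medium(
        c0=float(block.get("c0", WATER.c0)),
        rho0=float(block.get("rho0", WATER.rho0)),
        mu0=float(block.get("mu0", WATER.mu0)),
    )


def geometry_from_config(cfg: dict) -> ArrayGeometry:
    """Build the array from an ``array`` block (mm / MHz units).

    Keys: ``n_elements``, ``chamber_diameter_mm``, ``element_width_mm``
    (optional), ``frequency_MHz``; a top-level ``lambda_override_mm``
    pins the operating wavelength (e.g. the device's printed 0.644 mm).
    """
    arr = cfg.get("array", {})
    medium = medium_from_config(cfg)
    wavelength = cfg.get("lambda_override_mm")
    ew = arr.get("element_width_mm")
    return build_circular_array(
        n_elements=int(arr.get("n_elements", 64)),
        chamber_diameter=float(arr.get("chamber_diameter_mm", 10.98)) * 1e-3,
        element_width=float(ew) * 1e-3 if ew is not None else None,
        frequency=float(arr.get("frequency_MHz", 2.35)) * 1e6,
        medium=medium,
        wavelength=float(wavelength) * 1e-3 if wavelength is not None else None,
    )
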