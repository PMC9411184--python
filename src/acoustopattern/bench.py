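"""Seeded ensembles, shape masks, contrast metrics and experiment benches.

The benches regenerate, at desk scale, the simulated studies that
characterize impulse control: the regime sweep (motion per cycle vs
applied impulse on the 1D bench), the switched-vs-summed low-impulse
equivalence on a twin-trap line, and letter patterning with clearing.

Contrast is measured by ``fraction_outside``: the percentage of
particles that are neither within the inclusion tolerance of the target
skeleton nor within the edge margin of the chamber boundary.  Defaults
(tolerance lambda/4, edge margin 2 lambda) are free parameters of the
metric and are reported in every output header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .field_engine import (
    CENTRAL_REGION_RADIUS,
    DEVICE_WAVELENGTH,
    ArrayGeometry,
    Medium,
    WATER,
    device_array,
    make_grid,
)
from .impulse_control import (
    RegimeReport,
    SwitchingSchedule,
    TwoStateBench,
    regime_sweep,
    simulate_switched,
    summed_field,
)
from .mechanics import F_MAX_DEFAULT, ParticleMaterial, POLYSTYRENE, Workspace
from .patterning import (
    execute_recipe,
    form_letter,
    letter_patterning_schedule,
    letter_skeleton,
    line_of_twin_traps,
    polyline_distance,
)

__all__ = [
    "Ensemble",
    "random_ensemble",
    "ShapeMask",
    "fraction_outside",
    "run_fig1_bench",
    "run_fig3b_bench",
    "run_letter_bench",
    "default_workspace",
]


@dataclass(frozen=True)
class Ensemble:
    """Particle positions/velocities plus the chamber they live in."""

    positions: np.ndarray  # (n, 2) m
    velocities: np.ndarray  # (n, 2) m/s
    material: ParticleMaterial = POLYSTYRENE
    chamber_radius: float = 5.49e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", np.atleast_2d(np.asarray(self.positions, dtype=float))
        )
        object.__setattr__(
            self, "velocities", np.atleast_2d(np.asarray(self.velocities, dtype=float))
        )
        if self.positions.size == 0:
            object.__setattr__(self, "positions", np.zeros((0, 2)))
            object.__setattr__(self, "velocities", np.zeros((0, 2)))
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must match in shape")
        r = np.hypot(self.positions[:, 0], self.positions[:, 1])
        if np.any(r > self.chamber_radius):
            raise ValueError("particles must start inside the chamber")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def with_state(self, positions, velocities) -> "Ensemble":
        return replace(
            self,
            positions=np.asarray(positions, dtype=float),
            velocities=np.asarray(velocities, dtype=float),
        )


def random_ensemble(
    n: int,
    seed: int,
    chamber_radius: float = 5.49e-3,
    region_radius: float = CENTRAL_REGION_RADIUS,
    material: ParticleMaterial = POLYSTYRENE,
) -> Ensemble:
    """Uniform random ensemble over the central patterning region.

    Bit-for-bit reproducible from ``(seed, n, region)``; initial
    velocities are zero.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    r = region_radius * np.sqrt(rng.random(n))
    th = 2.0 * np.pi * rng.random(n)
    pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    return Ensemble(
        positions=pos,
        velocities=np.zeros((n, 2)),
        material=material,
        chamber_radius=chamber_radius,
        seed=seed,
    )


@dataclass(frozen=True)
class ShapeMask:
    """Target skeleton with an inclusion tolerance and an edge margin."""

    polylines: list
    tolerance: float = DEVICE_WAVELENGTH / 4.0
    edge_margin: float = 2.0 * DEVICE_WAVELENGTH
    chamber_radius: float = 5.49e-3

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def outside(self, positions: np.ndarray) -> np.ndarray:
        """True where a particle is off-shape AND away from the edge."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        d_skel = polyline_distance(pos, self.polylines)
        d_edge = self.chamber_radius - np.hypot(pos[:, 0], pos[:, 1])
        return (d_skel > self.tolerance) & (d_edge > self.edge_margin)


def fraction_outside(ensemble: Ensemble, mask: ShapeMask) -> float:
    """Percentage of particles neither on the shape nor at the edge."""
    if ensemble.n == 0:
        raise ValueError("fraction_outside is undefined for an empty ensemble")
    return 100.0 * float(mask.outside(ensemble.positions).mean())


def default_workspace(
    half_width: float | None = None,
    full_chamber: bool = False,
    medium: Medium = WATER,
    material: ParticleMaterial = POLYSTYRENE,
    f_max: float = F_MAX_DEFAULT,
    geometry: ArrayGeometry | None = None,
) -> Workspace:
    """Device geometry + default grid bound into a :class:`Workspace`.

    The default grid covers the central 4 mm patterning region at
    lambda/20; ``full_chamber`` extends it to the whole chamber (needed
    by clearing tools that transport particles to the walls).
    """
    geometry = device_array(medium) if geometry is None else geometry
    if half_width is None:
        half_width = geometry.radius - 0.29e-3 if full_chamber else CENTRAL_REGION_RADIUS
    grid = make_grid(half_width, wavelength=geometry.wavelength)
    return Workspace(geometry, grid, material=material, medium=medium, f_max=f_max)


# ---------------------------------------------------------------------------
# benches
# ---------------------------------------------------------------------------


def _write_report(path, df: pd.DataFrame, header: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def run_fig1_bench(
    f_max_list=(2.5e-9, 5e-9, 10e-9),
    dt_min: float = 0.1e-3,
    dt_max: float = 100e-3,
    n_dt: int = 10,
    bench: TwoStateBench | None = None,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Regime characterization sweep on the 1D two-state bench.

    Sweeps the switching time over [0.1, 100] ms for each force ceiling;
    returns one row per (F_max, dt_s) with the applied impulse, motion
    per cycle and regime label.
    """
    bench = TwoStateBench() if bench is None else bench
    dts = np.geomspace(dt_min, dt_max, n_dt)
    reports = regime_sweep(f_max_list, dts, bench)
    df = pd.DataFrame(
        {
            "f_max_nN": [r.f_max * 1e9 for r in reports],
            "dt_s_ms": [r.dt_s * 1e3 for r in reports],
            "I_app_pNs": [r.applied_impulse * 1e12 for r in reports],
            "motion_um": [r.motion_per_cycle * 1e6 for r in reports],
            "motion_over_separation": [
                r.motion_per_cycle / bench.separation for r in reports
            ],
            "regime": [r.regime for r in reports],
        }
    )
    if out is not None:
        _write_report(
            out,
            df,
            {
                "bench": "two-state 1D regime sweep",
                "separation_um": bench.separation * 1e6,
                "n_cycles": bench.n_cycles,
            },
        )
    return df


def run_fig3b_bench(
    n: int = 50,
    seed: int = 0,
    duration: float = 0.5,
    dwell: float = 1e-3,
    f_max: float = F_MAX_DEFAULT,
    workspace: Workspace | None = None,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Switched vs summed-field end positions on the 2 mm twin-trap line.

    Runs the same seeded ensemble once under the switched 10-trap
    schedule (low impulse: 10 nN, 1 ms dwells) and once under the static
    dwell-weighted summed field, and reports the paired end-position
    discrepancies.
    """
    ws = default_workspace(f_max=f_max) if workspace is None else workspace
    ens = random_ensemble(n, seed)
    sched = line_of_twin_traps((-1e-3, 0.0), (1e-3, 0.0), ws.geometry, dwell=dwell)
    switched = simulate_switched(ens, sched, duration, ws, f_max=f_max)
    mean_fg = summed_field(sched, ws, f_max=f_max)
    static = SwitchingSchedule([mean_fg], np.array([dwell]), label="summed")
    summed = simulate_switched(ens, static, duration, ws, f_max=f_max)
    disc = np.linalg.norm(switched.final_positions - summed.final_positions, axis=1)
    df = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "x_switched": switched.final_positions[:, 0],
            "y_switched": switched.final_positions[:, 1],
            "x_summed": summed.final_positions[:, 0],
            "y_summed": summed.final_positions[:, 1],
            "discrepancy_um": disc * 1e6,
        }
    )
    if out is not None:
        _write_report(
            out,
            df,
            {
                "bench": "switched vs summed twin-trap line",
                "seed": seed,
                "duration_ms": duration * 1e3,
                "dwell_ms": dwell * 1e3,
                "f_max_nN": f_max * 1e9,
                "mean_discrepancy_um": float(disc.mean() * 1e6),
            },
        )
    return df


def run_letter_bench(
    letter: str = "A",
    n: int = 500,
    seeds=(0,),
    duration_pattern_only: float = 0.5,
    workspace: Workspace | None = None,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Letter contrast before and after clearing, over seeds.

    For each seed: form the letter by low-impulse skeleton traps alone
    (500 ms) and measure the off-pattern fraction; then run the full
    clearing-plus-patterning recipe on a fresh copy of the same ensemble
    and measure again.
    """
    ws = (
        default_workspace(full_chamber=True) if workspace is None else workspace
    )
    skel = letter_skeleton(letter)
    mask = ShapeMask(
        polylines=skel,
        tolerance=ws.geometry.wavelength / 4.0,
        edge_margin=2.0 * ws.geometry.wavelength,
        chamber_radius=ws.geometry.radius,
    )
    sched = letter_patterning_schedule(letter, ws.geometry)
    recipe = form_letter(letter, ws.geometry, f_max=ws.f_max)
    rows = []
    for seed in seeds:
        ens = random_ensemble(n, seed, chamber_radius=ws.geometry.radius)
        res = simulate_switched(ens, sched, duration_pattern_only, ws)
        frac_before = fraction_outside(
            ens.with_state(res.final_positions, res.final_velocities), mask
        )
        log: list = []
        cleared = execute_recipe(ens, recipe, ws, log=log)
        frac_after = fraction_outside(cleared, mask)
        rows.append(
            {
                "letter": letter,
                "seed": seed,
                "n": n,
                "pattern_only_outside_pct": frac_before,
                "full_recipe_outside_pct": frac_after,
            }
        )
    df = pd.DataFrame(rows)
    if out is not None:
        _write_report(
            out,
            df,
            {
                "bench": "letter contrast",
                "tolerance_um": mask.tolerance * 1e6,
                "edge_margin_um": mask.edge_margin * 1e6,
                "f_max_nN": ws.f_max * 1e9,
                "dwell_ms": 1.0,
            },
        )
    return df
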