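"""Impulse computation, field switching and the three-regime analysis.

The control variable of switched-field manipulation is the applied
impulse ``I_app = max(F_ac) * dt_s``: the maximum force of a state times
the dwell for which it is applied.  Three regimes emerge:

* **low** -- switching much faster than the particle response; the
  particle feels the dwell-weighted mean of the constituent force fields
  ``F_sum = sum_q F_ac,q dt_q / sum_q dt_q`` and settles at its single
  equilibrium,
* **high** -- the particle reaches each state's own equilibrium before
  the next state arrives and oscillates between them,
* **intermediate** -- partial excursions between the two.

``regime_sweep`` reproduces the characterization experiment on a 1D
two-state standing-wave bench: motion per cycle vs applied impulse
collapses onto a single curve whether the impulse is varied through the
force amplitude or through the switching time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .field_engine import DriveState, Grid, Medium, WATER
from .mechanics import (
    BilinearForce,
    ForceGrid,
    ParticleMaterial,
    POLYSTYRENE,
    Workspace,
    default_timestep,
    integrate_ensemble,
    virtual_mass,
    viscous_relaxation_time,
)

__all__ = [
    "SwitchingSchedule",
    "RegimeReport",
    "applied_impulse",
    "exerted_impulse",
    "summed_field",
    "simulate_switched",
    "motion_per_cycle",
    "TwoStateBench",
    "regime_sweep",
    "classify_regime",
]


@dataclass
class SwitchingSchedule:
    """Ordered sequence of acoustic states with dwell times.

    ``states`` may hold :class:`DriveState` objects (converted to force
    grids by a :class:`Workspace` at simulation time) or precomputed
    :class:`ForceGrid` objects.
    """

    states: list
    dwells: np.ndarray  # (Q,) s
    label: str = ""
    loop_count: int = 1

    def __post_init__(self) -> None:
        self.dwells = np.atleast_1d(np.asarray(self.dwells, dtype=float))
        if self.dwells.size == 1 and len(self.states) > 1:
            self.dwells = np.full(len(self.states), float(self.dwells[0]))
        if len(self.states) != self.dwells.size:
            raise ValueError("one dwell per state required")
        if len(self.states) >= 1 and np.any(self.dwells <= 0):
            raise ValueError("dwells must be positive")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def cycle_time(self) -> float:
        return float(self.dwells.sum())

    def rotated(self, shift: int) -> "SwitchingSchedule":
        idx = list(range(self.n_states))
        idx = idx[shift:] + idx[:shift]
        return SwitchingSchedule(
            [self.states[i] for i in idx], self.dwells[idx], self.label, self.loop_count
        )

    def to_records(self) -> list[dict]:
        recs = []
        for st, dw in zip(self.states, self.dwells):
            label = st.label if hasattr(st, "label") else ""
            recs.append({"state_label": label, "dwell_ms": dw * 1e3})
        return recs


@dataclass(frozen=True)
class RegimeReport:
    """One point of the motion-per-cycle vs applied-impulse curve."""

    f_max: float  # N
    dt_s: float  # s
    applied_impulse: float  # N s
    motion_per_cycle: float  # m
    regime: str  # low | intermediate | high


def applied_impulse(f_max: float, dt_s: float) -> float:
    """``I_app = max(F_ac) * dt_s`` (N s)."""
    if f_max < 0:
        raise ValueError("f_max must be >= 0")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    return f_max * dt_s


def exerted_impulse(times, positions, force_lookup, dwell: float) -> np.ndarray:
    """Impulse actually exerted on a moving particle over one dwell.

    Trapezoidal integral of ``F_ac(x(t))`` over ``[0, dwell]`` along the
    sampled trajectory.  ``times`` must cover the dwell.
    """
    times = np.asarray(times, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if times[-1] < dwell - 1e-12:
        raise ValueError("trajectory does not cover the dwell")
    m = times <= dwell + 1e-12
    t = times[m]
    forces = np.atleast_2d(force_lookup(positions[m]))
    return np.trapezoid(forces, t, axis=0)


def _as_force_grid(state, workspace: Workspace | None, f_max: float | None) -> ForceGrid:
    if isinstance(state, ForceGrid):
        return state
    if isinstance(state, DriveState):
        if workspace is None:
            raise ValueError("a Workspace is required to convert DriveStates")
        return workspace.force_grid(state, f_max)
    raise TypeError(f"unsupported schedule state type {type(state)!r}")


def summed_field(
    schedule: SwitchingSchedule,
    workspace: Workspace | None = None,
    f_max: float | None = None,
) -> ForceGrid:
    """Dwell-weighted mean force field (the low-impulse effective field).

    With equal dwells this reduces to the plain mean of the constituent
    fields.  All state grids must be congruent.
    """
    grids = [_as_force_grid(s, workspace, f_max) for s in schedule.states]
    g0 = grids[0].grid
    for g in grids[1:]:
        if g.grid.shape != g0.shape or abs(g.grid.spacing - g0.spacing) > 1e-15:
            raise ValueError("incongruent force grids in schedule")
    w = schedule.dwells / schedule.dwells.sum()
    force = np.tensordot(w, np.stack([g.force for g in grids]), axes=(0, 0))
    pot = np.tensordot(w, np.stack([g.potential for g in grids]), axes=(0, 0))
    return ForceGrid(grid=g0, potential=pot, force=force)


@dataclass
class SimulationResult:
    """Trajectory container returned by :func:`simulate_switched`."""

    times: np.ndarray  # (n_frames,) s
    positions: np.ndarray  # (n_frames, m, 2)
    final_positions: np.ndarray  # (m, 2)
    final_velocities: np.ndarray  # (m, 2)

    def to_dataframe(self):
        import pandas as pd

        n_frames, m, _ = self.positions.shape
        t = np.repeat(self.times, m)
        pid = np.tile(np.arange(m), n_frames)
        xy = self.positions.reshape(-1, 2)
        return pd.DataFrame({"t": t, "particle_id": pid, "x": xy[:, 0], "y": xy[:, 1]})


def _state_sequence(dwells: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Active-state index at the midpoint of every step."""
    edges = np.concatenate([[0.0], np.cumsum(dwells)])
    cycle = edges[-1]
    t_mid = (np.arange(n_steps) + 0.5) * dt
    phase = np.mod(t_mid, cycle)
    return np.clip(np.searchsorted(edges, phase, side="right") - 1, 0, dwells.size - 1)


def validate_switching_period(dt_s: float, frequency: float) -> None:
    """Warn when switching approaches the acoustic period.

    The quasi-static field model requires the dwell to exceed the
    acoustic period by orders of magnitude (>= 100x enforced here as a
    warning)."""
    if dt_s < 100.0 / frequency:
        warnings.warn(
            "switching period is within 100 acoustic periods; the "
            "time-averaged force model is not valid there",
            stacklevel=2,
        )


def simulate_switched(
    ensemble,
    schedule: SwitchingSchedule,
    duration: float,
    workspace: Workspace | None = None,
    dt: float | None = None,
    record_stride: int = 0,
    f_max: float | None = None,
) -> SimulationResult:
    """Integrate an ensemble under a cyclically switched force field.

    ``ensemble`` is anything with ``positions``, ``velocities``,
    ``material`` and ``chamber_radius`` attributes (see
    :class:`acoustopattern.bench.Ensemble`); it is not modified.
    """
    m = ensemble.positions.shape[0]
    grids = [_as_force_grid(s, workspace, f_max) for s in schedule.states]
    grid = grids[0].grid
    medium = workspace.medium if workspace is not None else WATER
    if schedule.n_states > 0:
        validate_switching_period(
            float(schedule.dwells.min()),
            workspace.geometry.frequency if workspace is not None else 2.35e6,
        )
    if m == 0 or schedule.n_states == 0 or duration <= 0:
        return SimulationResult(
            times=np.zeros(0),
            positions=np.zeros((0, m, 2)),
            final_positions=np.array(ensemble.positions, dtype=float),
            final_velocities=np.array(ensemble.velocities, dtype=float),
        )
    if dt is None:
        dt = default_timestep(float(schedule.dwells.min()), ensemble.material, medium)
        # land state boundaries exactly when dwells are uniform
        if np.allclose(schedule.dwells, schedule.dwells[0]):
            dw = float(schedule.dwells[0])
            dt = dw / int(np.ceil(dw / dt))
    n_steps = int(np.round(duration / dt))
    seq = _state_sequence(schedule.dwells, dt, n_steps)
    stack = np.stack([g.force for g in grids])
    pos, vel, rec = integrate_ensemble(
        ensemble.positions,
        ensemble.velocities,
        stack,
        seq,
        grid,
        dt,
        material=ensemble.material,
        medium=medium,
        chamber_radius=ensemble.chamber_radius,
        record_stride=record_stride,
    )
    if record_stride > 0:
        times = dt * record_stride * (1 + np.arange(rec.shape[0]))
    else:
        times = np.zeros(0)
    return SimulationResult(
        times=times, positions=rec, final_positions=pos, final_velocities=vel
    )


def motion_per_cycle(
    times: np.ndarray,
    positions: np.ndarray,
    cycle_time: float,
    settle_fraction: float = 0.2,
    axis: np.ndarray | None = None,
) -> float:
    """Mean per-cycle position range after settling.

    Positions are projected onto ``axis`` (default: the principal axis of
    the trajectory); the trajectory is cut into full schedule cycles, the
    first ``settle_fraction`` of cycles is discarded, and the mean of the
    per-cycle ranges (max - min) is returned.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        coord = positions
    else:
        if axis is None:
            centered = positions - positions.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        coord = positions @ axis
    n_cycles = int(np.floor((times[-1] - times[0]) / cycle_time))
    if n_cycles < 1:
        return 0.0
    start = times[0]
    idx = np.minimum(
        ((times - start) / cycle_time).astype(int), n_cycles - 1
    )
    first = int(np.ceil(settle_fraction * n_cycles))
    ranges = []
    for c in range(first, n_cycles):
        sel = idx == c
        if sel.any():
            seg = coord[sel]
            ranges.append(seg.max() - seg.min())
    return float(np.mean(ranges)) if ranges else 0.0


# ---------------------------------------------------------------------------
# the 1D two-state bench (regime characterization)
# ---------------------------------------------------------------------------

try:  # pragma: no cover
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _two_state_1d_kernel(
    x0, f_max, k2, shift, dwell, dt, n_cycles, c1, c2, m_v, ranges
):
    x = x0
    v = 0.0
    dt2 = dt * dt
    steps_per_dwell = int(round(dwell / dt))
    for c in range(n_cycles):
        lo = x
        hi = x
        for state in range(2):
            xq = shift * state
            for _ in range(steps_per_dwell):
                f_ac = -f_max * np.sin(k2 * (x - xq))
                speed = v if v >= 0.0 else -v
                a = (f_ac - c1 * (1.0 + c2 * speed) ** 0.5 * v) / m_v
                x += v * dt + a * dt2
                v += a * dt
                if x < lo:
                    lo = x
                if x > hi:
                    hi = x
        ranges[c] = hi - lo
    return x


@dataclass
class TwoStateBench:
    """1D two-state standing-wave configuration used for Fig-1-style sweeps.

    Each state q applies the force ``F_q(x) = -F_max sin(2k (x - x_q))``
    of an ideal standing wave normalized to ``F_max``; the two state
    equilibria sit at ``x_1 = 0`` and ``x_2 = shift``.  The pattern shift
    defaults to lambda/8 (ideal counter-propagating-source physics: a
    pi/2 source phase offset shifts the intensity pattern by lambda/8 and
    leaves a nonzero summed field with its equilibrium midway).  All
    regime measures are expressed relative to the actual equilibria
    separation so conclusions are shift-independent.
    """

    wavelength: float = 0.644e-3
    shift: float | None = None  # m; default lambda/8
    material: ParticleMaterial = POLYSTYRENE
    medium: Medium = WATER
    n_cycles: int = 100
    settle_fraction: float = 0.2
    start_offset_fraction: float = 0.25  # of the shift, from the summed eq.

    def __post_init__(self) -> None:
        if self.shift is None:
            self.shift = self.wavelength / 8.0

    @property
    def separation(self) -> float:
        """Distance between the two state equilibria."""
        return float(self.shift)

    @property
    def k2(self) -> float:
        return 2.0 * (2.0 * np.pi / self.wavelength)

    def motion(self, f_max: float, dt_s: float) -> float:
        """Motion per switching cycle (m) after settling."""
        med, mat = self.medium, self.material
        dt = min(viscous_relaxation_time(mat, med) / 50.0, dt_s / 20.0)
        steps = max(1, int(round(dt_s / dt)))
        dt = dt_s / steps
        c1 = 6.0 * np.pi * med.mu0 * mat.radius
        c2 = 3.0 / 16.0 * 2.0 * mat.radius * med.rho0 / med.mu0
        ranges = np.zeros(self.n_cycles)
        x0 = 0.5 * self.shift + self.start_offset_fraction * self.shift
        _two_state_1d_kernel(
            x0,
            f_max,
            self.k2,
            self.shift,
            dt_s,
            dt,
            self.n_cycles,
            c1,
            c2,
            virtual_mass(mat, med),
            ranges,
        )
        first = int(np.ceil(self.settle_fraction * self.n_cycles))
        return float(ranges[first:].mean())


def classify_regime(
    motion: float,
    separation: float,
    low_fraction: float = 0.05,
    high_fraction: float = 0.95,
) -> str:
    """Label a motion-per-cycle measurement.

    low: < ``low_fraction`` of the equilibria separation (particle holds
    the summed-field equilibrium); high: > ``high_fraction`` (full
    oscillation between the state equilibria); else intermediate.
    """
    if separation <= 0:
        raise ValueError("equilibria separation must be positive")
    frac = motion / separation
    if frac < low_fraction:
        return "low"
    if frac > high_fraction:
        return "high"
    return "intermediate"


def regime_sweep(
    f_max_list,
    dt_s_list,
    bench: TwoStateBench | None = None,
    low_fraction: float = 0.05,
    high_fraction: float = 0.95,
) -> list[RegimeReport]:
    """Sweep (F_max, dt_s) pairs on the 1D bench, sorted by I_app."""
    if bench is None:
        bench = TwoStateBench()
    reports = []
    for f_max in f_max_list:
        for dt_s in dt_s_list:
            m = bench.motion(f_max, dt_s)
            reports.append(
                RegimeReport(
                    f_max=f_max,
                    dt_s=dt_s,
                    applied_impulse=applied_impulse(f_max, dt_s),
                    motion_per_cycle=m,
                    regime=classify_regime(
                        m, bench.separation, low_fraction, high_fraction
                    ),
                )
            )
    reports.sort(key=lambda r: r.applied_impulse)
    return reports
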