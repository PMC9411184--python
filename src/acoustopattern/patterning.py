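"""Patterning, clearing and reshaping built from switched acoustic states.

Building blocks
---------------
* **Twin-trap lines** -- a line feature is a rapid low-impulse cycle of
  twin traps equally distributed along the line, their count set by the
  trap-count rule ``N_TT = round(3 L / lambda) + 1`` (nearest-integer;
  spacing approximately lambda/3).
* **Standing-wave conveyor** -- a looped 3-step progression of
  sub-aperture standing waves in the high-impulse regime; the node lines
  (and trapped particles) advance lambda/6 per step, lambda/2 per loop.
* **Focus sweep** -- a unidirectional raster of focused points in the
  intermediate-impulse regime pushes particles out of a rectangular
  region (positive-contrast particles are repelled from the focal
  pressure maximum).
* **Bessel-order cycling** -- stepping the vortex order moves the first
  high-pressure ring in or out; decreasing orders sweep particles inward
  into an agglomeration, increasing orders plough the annulus between
  the initial and final ring radii outward while the core (and any
  pattern inside it) is protected.

Recipes chain these tools into staged procedures (isolated line, circle,
C, letters); :func:`execute_recipe` runs a recipe on an ensemble,
including the adaptive per-particle vortex removal used for the final
stragglers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import jnp_zeros

from .field_engine import (
    ArrayGeometry,
    CENTRAL_REGION_RADIUS,
    DriveState,
    OutOfBoundsError,
    bessel_drive,
    standing_wave_drive,
    twin_trap_drive,
)
from .impulse_control import SwitchingSchedule, simulate_switched
from .mechanics import F_MAX_DEFAULT, Workspace

__all__ = [
    "n_twin_traps",
    "line_of_twin_traps",
    "polyline_trap_schedule",
    "conveyor_schedule",
    "focus_sweep_schedule",
    "bessel_cycle_schedule",
    "vortex_ring_radius",
    "Stage",
    "Recipe",
    "reshape",
    "form_isolated_line",
    "form_circle",
    "form_C",
    "form_letter",
    "letter_skeleton",
    "letter_patterning_schedule",
    "voltage_to_force",
    "polyline_distance",
    "execute_recipe",
    "LETTER_SKELETONS",
]

DWELL_LOW = 1e-3  # s; the reference low-impulse dwell (10 pN s at 10 nN)
DWELL_INTERMEDIATE = 74e-3  # s; the device's printed clearing dwell
DWELL_HIGH = 0.15  # s; comfortably beyond the ~0.8 ms particle response


def voltage_to_force(volts: float, v_ref: float = 20.0, f_ref: float = F_MAX_DEFAULT) -> float:
    """Map an experimental drive voltage to a simulation force ceiling.

    Pressure amplitude scales with voltage and force with pressure
    squared, so ``F = f_ref (V / v_ref)^2`` with the calibration that the
    maximum experimental voltage (20 V) corresponds to the 10 nN
    simulation ceiling.
    """
    if volts < 0:
        raise ValueError("voltage must be >= 0")
    return f_ref * (volts / v_ref) ** 2


def n_twin_traps(line_length: float, wavelength: float) -> int:
    """Twin-trap count for a line: ``round(3 L / lambda) + 1``.

    Nearest-integer rounding; a zero-length line takes a single trap.
    """
    if line_length < 0:
        raise ValueError("line length must be >= 0")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return int(np.rint(3.0 * line_length / wavelength)) + 1


def line_of_twin_traps(
    start,
    end,
    geometry: ArrayGeometry,
    dwell: float = DWELL_LOW,
    region_radius: float = CENTRAL_REGION_RADIUS,
    reverse: bool = False,
    label: str | None = None,
) -> SwitchingSchedule:
    """Twin traps equally distributed from ``start`` to ``end`` inclusive.

    The cancellation axis of every trap lies along the line, so the
    summed field's low-force valley follows the line.  ``reverse`` flips
    the sweep order (used to alternate sweep directions between stages).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for p in (start, end):
        if np.hypot(p[0], p[1]) > region_radius + 1e-12:
            raise OutOfBoundsError("line endpoint outside the patterning region")
    length = float(np.linalg.norm(end - start))
    n = n_twin_traps(length, geometry.wavelength)
    if n == 1 or length == 0.0:
        pts = [0.5 * (start + end)]
        axis = 0.0
    else:
        frac = np.linspace(0.0, 1.0, n)
        pts = [start + f * (end - start) for f in frac]
        axis = float(np.arctan2(*(end - start)[::-1]))
    states = [twin_trap_drive(geometry, p, axis) for p in pts]
    if reverse:
        states = states[::-1]
    return SwitchingSchedule(
        states,
        np.full(len(states), dwell),
        label=label or f"line[{len(states)} traps]",
    )


def polyline_trap_schedule(
    polylines,
    geometry: ArrayGeometry,
    dwell: float = DWELL_LOW,
    region_radius: float = CENTRAL_REGION_RADIUS,
    reverse: bool = False,
    label: str = "skeleton traps",
) -> SwitchingSchedule:
    """Twin-trap cycle tracing a set of polylines (a shape skeleton)."""
    states = []
    for poly in polylines:
        poly = np.asarray(poly, dtype=float)
        for a, b in zip(poly[:-1], poly[1:]):
            seg = line_of_twin_traps(
                a, b, geometry, dwell=dwell, region_radius=region_radius
            )
            states.extend(seg.states)
    if reverse:
        states = states[::-1]
    if not states:
        raise ValueError("empty shape skeleton")
    return SwitchingSchedule(states, np.full(len(states), dwell), label=label)


def conveyor_schedule(
    geometry: ArrayGeometry,
    axis_angle: float = 0.0,
    aperture_half_count: int = 11,
    n_loops: int = 1,
    dwell: float = DWELL_HIGH,
    offset_sign: int = 1,
) -> SwitchingSchedule:
    """High-impulse 3-step standing-wave conveyor, ``n_loops`` loops.

    Each loop displaces trapped particles by lambda/2 along the axis;
    flipping ``offset_sign`` reverses the transport direction.
    """
    if n_loops < 0:
        raise ValueError("n_loops must be >= 0")
    states = [
        standing_wave_drive(geometry, aperture_half_count, axis_angle, s, offset_sign)
        for _ in range(n_loops)
        for s in range(3)
    ]
    return SwitchingSchedule(
        states,
        np.full(len(states), dwell) if states else np.zeros(0),
        label=f"conveyor x{n_loops}",
    )


def focus_sweep_schedule(
    geometry: ArrayGeometry,
    region,
    step: float = 0.1e-3,
    direction: int = 1,
    dwell: float = DWELL_INTERMEDIATE,
) -> SwitchingSchedule:
    """Unidirectional raster of m=0 focus states over a rectangle.

    ``region`` is ``(xmin, xmax, ymin, ymax)`` in metres; ``step``
    (default 0.1 mm, 0.16 lambda) spaces both the points along each line
    and the lines themselves.  The sweep direction along each line is
    constant (``direction`` = +-1) -- reversing directions between lines
    draws particles back into cleared areas.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    xmin, xmax, ymin, ymax = (float(v) for v in region)
    if xmax < xmin or ymax < ymin:
        raise ValueError("malformed region")
    states = []
    if xmax > xmin and ymax > ymin:
        ys = np.arange(ymin, ymax + 0.5 * step, step)
        xs = np.arange(xmin, xmax + 0.5 * step, step)
        if direction < 0:
            xs = xs[::-1]
        for y in ys:
            for x in xs:
                if np.hypot(x, y) < geometry.radius:
                    states.append(bessel_drive(geometry, 0, (x, y)))
    return SwitchingSchedule(
        states,
        np.full(len(states), dwell) if states else np.zeros(0),
        label=f"sweep[{len(states)} pts]",
    )


def vortex_ring_radius(order: int, wavelength: float) -> float:
    """Radius of the first high-pressure ring of an order-m vortex.

    First maximum of ``J_m(kr)``; the central low-intensity core grows
    with the order.  Order 0 focuses at the origin (radius 0).
    """
    if order == 0:
        return 0.0
    k = 2.0 * np.pi / wavelength
    return float(jnp_zeros(order, 1)[0]) / k


def bessel_cycle_schedule(
    geometry: ArrayGeometry,
    origin=(0.0, 0.0),
    order_from: int = 20,
    order_to: int = 9,
    chirality_alternation: bool = True,
    repetitions: int = 1,
    dwell: float = DWELL_HIGH,
    off_centre_boost: bool = True,
) -> SwitchingSchedule:
    """High-impulse Bessel-order cycle (agglomeration or clearing).

    Orders step from ``order_from`` to ``order_to`` (either direction);
    with ``chirality_alternation`` the vortex handedness flips between
    repetitions for more uniform action.  Off-centre origins (outside the
    central 1 mm) double the repetition count, mirroring the weaker
    off-centre forces of the device.
    """
    if order_from < 0 or order_to < 0:
        raise ValueError("orders must be >= 0")
    if repetitions < 0:
        raise ValueError("repetitions must be >= 0")
    origin = np.asarray(origin, dtype=float)
    if off_centre_boost and np.hypot(origin[0], origin[1]) > 1e-3:
        repetitions *= 2
    step_dir = 1 if order_to >= order_from else -1
    orders = list(range(order_from, order_to + step_dir, step_dir))
    states = []
    chi = 1
    for _ in range(repetitions):
        for m in orders:
            states.append(bessel_drive(geometry, m, origin, chirality=chi))
        if chirality_alternation:
            chi = -chi
    return SwitchingSchedule(
        states,
        np.full(len(states), dwell) if states else np.zeros(0),
        label=f"bessel {order_from}->{order_to} x{repetitions}",
    )


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


@dataclass
class Stage:
    """One stage of a recipe: a schedule with its impulse setting."""

    label: str
    schedule: SwitchingSchedule | None
    f_max: float  # N
    duration: float  # s of simulated time (>= one full cycle)
    regime: str  # declared regime: low | intermediate | high
    tool: str = "traps"
    params: dict = dc_field(default_factory=dict)

    @property
    def dwell(self) -> float:
        if self.schedule is None or self.schedule.n_states == 0:
            return float(self.params.get("dwell", 0.0))
        return float(self.schedule.dwells[0])


@dataclass
class Recipe:
    """Ordered stages realizing a patterning / clearing procedure."""

    stages: list
    label: str = ""

    def stage_labels(self) -> list[str]:
        return [s.label for s in self.stages]


def _cycle_stage(label, schedule, f_max, regime, n_cycles=1, tool="traps", **params):
    return Stage(
        label=label,
        schedule=schedule,
        f_max=f_max,
        duration=n_cycles * schedule.cycle_time if schedule.n_states else 0.0,
        regime=regime,
        tool=tool,
        params=params,
    )


# printed reshape increments
TRANSLATE_STEP = 0.1e-3  # m per step
ROTATE_STEP = np.radians(5.0)  # per step
ARC_RADIUS_STEPS = ((5e-3, 3e-3, 0.5e-3), (3e-3, 1e-3, 0.25e-3), (1e-3, 0.0, 0.12e-3))


def _arc_radius_schedule(r_target: float, r_start: float = 5e-3) -> list[float]:
    radii = []
    r = r_start
    while r > r_target + 1e-9:
        for hi, lo, stp in ARC_RADIUS_STEPS:
            if r <= hi + 1e-9 and r > lo:
                r = max(r - stp, r_target)
                break
        radii.append(r)
    return radii


def _arc_points(center, radius, arc_length, phase, n_pts=33):
    half = 0.5 * arc_length / radius
    ang = phase + np.linspace(-half, half, n_pts)
    return center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def reshape(
    line,
    operation: str,
    geometry: ArrayGeometry,
    params: dict | None = None,
    f_max: float | None = None,
    dwell: float = DWELL_LOW,
) -> Recipe:
    """Incremental low-impulse deformation of a formed line.

    ``line`` is ``(start, end)`` in metres.  Operations:

    ``translate``  params: ``vector`` (m), ``step`` (default 0.1 mm)
    ``rotate``     params: ``angle`` (rad), ``step`` (default 5 deg),
                   ``center`` (default line midpoint)
    ``arc``        params: ``radius`` (m); radius stepped 0.5 mm/step
                   down to 3 mm, 0.25 mm to 1 mm, 0.12 mm below; the
                   centre of the line stays in place
    ``circle``     arc down to ``radius`` then a low-impulse switch of
                   2nd and 6th order Bessel fields centred on the circle
    ``split_rotate`` params: ``angle``, ``step``; the two half-lines
                   rotate in opposite senses about their own centres

    Trap sweep direction alternates between consecutive steps; moving the
    target by more than the printed increments triggers a warning.
    """
    params = dict(params or {})
    f_max = F_MAX_DEFAULT if f_max is None else f_max
    start = np.asarray(line[0], dtype=float)
    end = np.asarray(line[1], dtype=float)
    stages: list[Stage] = []

    def add_line(a, b, i, tag):
        sched = line_of_twin_traps(a, b, geometry, dwell=dwell, reverse=bool(i % 2))
        stages.append(
            _cycle_stage(f"{tag}[{i}]", sched, f_max, "low", n_cycles=8)
        )

    if operation == "translate":
        vec = np.asarray(params.get("vector", (0.0, 0.0)), dtype=float)
        step = float(params.get("step", TRANSLATE_STEP))
        if step > TRANSLATE_STEP + 1e-12:
            warnings.warn("translation step exceeds the 0.1 mm fidelity bound")
        dist = float(np.linalg.norm(vec))
        n = int(np.ceil(dist / step - 1e-9))
        for i in range(1, n + 1):
            frac = min(1.0, i * step / dist) if dist > 0 else 0.0
            add_line(start + frac * vec, end + frac * vec, i, "translate")
    elif operation in ("rotate", "split_rotate"):
        angle = float(params.get("angle", 0.0))
        step = float(params.get("step", ROTATE_STEP))
        if step > ROTATE_STEP + 1e-12:
            warnings.warn("rotation step exceeds the 5 degree fidelity bound")
        n = int(np.ceil(abs(angle) / step - 1e-9))
        sgn = np.sign(angle) if angle else 1.0

        def rot(p, c, th):
            d = p - c
            cs, sn = np.cos(th), np.sin(th)
            return c + np.array([cs * d[0] - sn * d[1], sn * d[0] + cs * d[1]])

        if operation == "rotate":
            center = np.asarray(params.get("center", 0.5 * (start + end)), dtype=float)
            for i in range(1, n + 1):
                th = sgn * min(abs(angle), i * step)
                add_line(rot(start, center, th), rot(end, center, th), i, "rotate")
        else:
            mid = 0.5 * (start + end)
            c1 = 0.5 * (start + mid)
            c2 = 0.5 * (mid + end)
            for i in range(1, n + 1):
                th = sgn * min(abs(angle), i * step)
                a1, b1 = rot(start, c1, th), rot(mid, c1, th)
                a2, b2 = rot(mid, c2, -th), rot(end, c2, -th)
                s1 = line_of_twin_traps(a1, b1, geometry, dwell=dwell, reverse=bool(i % 2))
                s2 = line_of_twin_traps(a2, b2, geometry, dwell=dwell, reverse=bool(i % 2))
                sched = SwitchingSchedule(
                    s1.states + s2.states,
                    np.full(s1.n_states + s2.n_states, dwell),
                    label=f"split[{i}]",
                )
                stages.append(
                    _cycle_stage(f"split_rotate[{i}]", sched, f_max, "low", n_cycles=8)
                )
    elif operation in ("arc", "circle"):
        length = float(np.linalg.norm(end - start))
        mid = 0.5 * (start + end)
        u = (end - start) / length
        nrm = np.array([-u[1], u[0]])
        r_target = float(params.get("radius", 1e-3))
        for i, r in enumerate(_arc_radius_schedule(r_target), start=1):
            center = mid - r * nrm  # arc centre at distance r from the line centre
            phase = float(np.arctan2(nrm[1], nrm[0]))
            pts = _arc_points(center, r, length, phase)
            sched = polyline_trap_schedule(
                [pts], geometry, dwell=dwell, reverse=bool(i % 2), label=f"arc r={r*1e3:.2f}mm"
            )
            stages.append(_cycle_stage(f"arc[{i}]", sched, f_max, "low", n_cycles=8))
        if operation == "circle":
            center = mid - r_target * nrm
            finale = SwitchingSchedule(
                [
                    bessel_drive(geometry, 2, center, chirality=1),
                    bessel_drive(geometry, 6, center, chirality=-1),
                ],
                np.full(2, dwell),
                label="bessel 2/6 finale",
            )
            stages.append(
                _cycle_stage("circle_finale", finale, f_max, "low", n_cycles=50, tool="bessel")
            )
    else:
        raise ValueError(f"unknown reshape operation {operation!r}")
    return Recipe(stages=stages, label=f"reshape:{operation}")


# ---------------------------------------------------------------------------
# shape skeletons (documented approximations; metres)
# ---------------------------------------------------------------------------


def _letter_A(height=2.6e-3, width=2.0e-3, bar_y=-0.3e-3):
    h, w = 0.5 * height, 0.5 * width
    apex = np.array([0.0, h])
    bl = np.array([-w, -h])
    br = np.array([w, -h])

    def leg_x(y):
        return w * (h - y) / (2.0 * h)

    bar = np.array([[-leg_x(bar_y), bar_y], [leg_x(bar_y), bar_y]])
    return [np.stack([bl, apex]), np.stack([br, apex]), bar]


def _letter_B(height=2.6e-3, width=1.4e-3):
    h = 0.5 * height
    x0 = -0.5 * width
    spine = np.array([[x0, -h], [x0, h]])
    r = 0.5 * h
    th = np.linspace(np.pi / 2, -np.pi / 2, 17)
    upper = np.stack([x0 + 0.9 * r * np.cos(th), 0.5 * h + r * np.sin(th)], axis=1)
    lower = np.stack([x0 + 1.1 * r * np.cos(th), -0.5 * h + r * np.sin(th)], axis=1)
    return [spine, upper, lower]


def _letter_C(radius=1.3e-3, gap_half_angle=np.radians(40.0)):
    th = np.linspace(gap_half_angle, 2.0 * np.pi - gap_half_angle, 49)
    return [radius * np.stack([np.cos(th), np.sin(th)], axis=1)]


LETTER_SKELETONS = {
    "A": _letter_A(),
    "B": _letter_B(),
    "C": _letter_C(),
}


def letter_skeleton(letter: str) -> list[np.ndarray]:
    if not letter or letter.upper() not in LETTER_SKELETONS:
        raise ValueError(f"no skeleton defined for {letter!r}")
    return [p.copy() for p in LETTER_SKELETONS[letter.upper()]]


def nearest_on_polylines(point, polylines):
    """Nearest point on a set of polylines and its distance."""
    p = np.asarray(point, dtype=float)
    best, bd = None, np.inf
    for poly in polylines:
        poly = np.asarray(poly, dtype=float)
        for a, b in zip(poly[:-1], poly[1:]):
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0.0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
            q = a + t * ab
            d = float(np.linalg.norm(p - q))
            if d < bd:
                bd, best = d, q
    return best, bd


def polyline_distance(points: np.ndarray, polylines) -> np.ndarray:
    """Distance from each point to the nearest polyline segment."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    best = np.full(pts.shape[0], np.inf)
    for poly in polylines:
        poly = np.asarray(poly, dtype=float)
        for a, b in zip(poly[:-1], poly[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                d = np.linalg.norm(pts - a, axis=1)
            else:
                t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
                proj = a + t[:, None] * ab
                d = np.linalg.norm(pts - proj, axis=1)
            best = np.minimum(best, d)
    return best


def letter_patterning_schedule(
    letter: str, geometry: ArrayGeometry, dwell: float = DWELL_LOW
) -> SwitchingSchedule:
    """Low-impulse twin-trap cycle tracing a letter skeleton."""
    return polyline_trap_schedule(
        letter_skeleton(letter), geometry, dwell=dwell, label=f"{letter} traps"
    )


def form_isolated_line(
    geometry: ArrayGeometry,
    start=(-1.0e-3, 0.0),
    end=(1.0e-3, 0.0),
    standing_wave_duration: float = 2.0,
) -> Recipe:
    """The staged single-line recipe: local sweeps, counter-swept traps,
    Bessel-up clearing with trap reinforcement, final traps and a static
    standing wave.

    Voltages of the reference procedure are mapped to force ceilings via
    :func:`voltage_to_force`.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    lo_y = min(start[1], end[1])
    hi_y = max(start[1], end[1])
    span = (min(start[0], end[0]), max(start[0], end[0]))
    below = (span[0] - 0.3e-3, span[1] + 0.3e-3, lo_y - 1.2e-3, lo_y - 0.25e-3)
    above = (span[0] - 0.3e-3, span[1] + 0.3e-3, hi_y + 0.25e-3, hi_y + 1.2e-3)
    axis = float(np.arctan2(*(end - start)[::-1]))
    stages = [
        _cycle_stage(
            "sweep_below",
            focus_sweep_schedule(geometry, below, direction=1, dwell=74e-3),
            voltage_to_force(9.0),
            "intermediate",
            tool="sweep",
        ),
    ]
    for rep in range(2):
        stages.append(
            _cycle_stage(
                f"sweep_above[{rep}]",
                focus_sweep_schedule(geometry, above, direction=1, dwell=74e-3),
                voltage_to_force(7.0),
                "intermediate",
                tool="sweep",
            )
        )
    stages.append(
        _cycle_stage(
            "counter_swept_traps",
            line_of_twin_traps(start, end, geometry, dwell=74e-3, reverse=True),
            voltage_to_force(10.0),
            "intermediate",
            n_cycles=4,
        )
    )
    up = bessel_cycle_schedule(
        geometry, 0.5 * (start + end), 9, 20, repetitions=1, dwell=0.3
    )
    stages.append(
        _cycle_stage("bessel_up_9_20", up, voltage_to_force(12.0), "high", tool="bessel")
    )
    stages.append(
        _cycle_stage(
            "trap_reinforce",
            line_of_twin_traps(start, end, geometry, dwell=74e-3),
            voltage_to_force(10.0),
            "intermediate",
            n_cycles=4,
        )
    )
    sw = SwitchingSchedule(
        [standing_wave_drive(geometry, 11, axis + np.pi / 2, 0, 1)],
        np.array([standing_wave_duration]),
        label="static standing wave",
    )
    stages.append(
        Stage(
            label="static_standing_wave",
            schedule=sw,
            f_max=voltage_to_force(20.0),
            duration=standing_wave_duration,
            regime="high",
            tool="standing",
        )
    )
    return Recipe(stages=stages, label="isolated line")


def form_circle(geometry: ArrayGeometry, center=(0.0, 0.0), dwell: float = DWELL_LOW) -> Recipe:
    """Circle: Bessel agglomeration / clearing, then a low-impulse switch
    of 5th and 9th order Bessel fields."""
    center = np.asarray(center, dtype=float)
    stages = [
        _cycle_stage(
            "agglomerate",
            bessel_cycle_schedule(geometry, center, 20, 9, repetitions=2),
            F_MAX_DEFAULT,
            "high",
            tool="bessel",
        ),
        _cycle_stage(
            "bessel_5_9",
            SwitchingSchedule(
                [
                    bessel_drive(geometry, 5, center, chirality=1),
                    bessel_drive(geometry, 9, center, chirality=-1),
                ],
                np.full(2, dwell),
                label="bessel 5/9",
            ),
            F_MAX_DEFAULT,
            "low",
            n_cycles=150,
            tool="bessel",
        ),
    ]
    return Recipe(stages=stages, label="circle")


def form_C(geometry: ArrayGeometry) -> Recipe:
    """C-shape: circular agglomeration, offset Bessel-up gap clearing,
    then a collection of twin traps along the C skeleton."""
    skel = letter_skeleton("C")
    radius = float(np.linalg.norm(skel[0][0]))
    stages = [
        _cycle_stage(
            "agglomerate",
            bessel_cycle_schedule(geometry, (0, 0), 20, 9, repetitions=2),
            F_MAX_DEFAULT,
            "high",
            tool="bessel",
        ),
        _cycle_stage(
            "gap_clear",
            bessel_cycle_schedule(
                geometry, (radius, 0.0), 1, 5, repetitions=1, dwell=0.1
            ),
            F_MAX_DEFAULT,
            "high",
            tool="bessel",
        ),
        _cycle_stage(
            "c_traps",
            polyline_trap_schedule(skel, geometry, label="C traps"),
            F_MAX_DEFAULT,
            "low",
            n_cycles=12,
        ),
    ]
    return Recipe(stages=stages, label="C")


def form_letter(
    letter: str,
    geometry: ArrayGeometry,
    f_max: float = F_MAX_DEFAULT,
    dwell: float = DWELL_LOW,
    include_removal: bool = True,
    removal_target_radius: float = 4.6e-3,
    tolerance: float | None = None,
) -> Recipe:
    """Full clearing-plus-patterning recipe for a letter shape.

    Stages: high-impulse Bessel-down agglomeration to letter size,
    low-impulse skeleton traps, then adaptive per-particle clearing in
    the upper intermediate regime: stragglers inside the pattern radius
    are nudged onto the nearest skeleton line by brief focused-point
    pushes (the focal pressure maximum repels positive-contrast
    particles), stragglers outside it are dragged radially to the
    chamber edge by an order-1 vortex trap; skeleton-trap reinforcement
    is interleaved between batches and a reinforcement pass ends the
    recipe.  Bulk vortex clearing across the formed pattern is
    deliberately absent: the rings of a chamber-spanning vortex displace
    patterned particles faster than low-impulse traps can recover them.
    """
    skel = letter_skeleton(letter)
    tol = geometry.wavelength / 4.0 if tolerance is None else tolerance
    pattern_sched = polyline_trap_schedule(
        skel, geometry, dwell=dwell, label=f"{letter} traps"
    )
    stages = [
        _cycle_stage(
            "agglomerate_20_7",
            bessel_cycle_schedule(geometry, (0, 0), 20, 7, repetitions=2),
            f_max,
            "high",
            tool="bessel",
        ),
        _cycle_stage("pattern", pattern_sched, f_max, "low", n_cycles=12),
    ]
    if include_removal:
        stages.append(
            Stage(
                label="vortex_removal",
                schedule=None,
                f_max=f_max,
                duration=0.0,
                regime="intermediate",
                tool="vortex_removal",
                params={
                    "skeleton": skel,
                    "tolerance": tol,
                    "target_radius": removal_target_radius,
                    "step": 0.1e-3,
                    "dwell": 12e-3,
                    "max_rounds": 4,
                    "reinforce_schedule": pattern_sched,
                    "reinforce_every": 8,
                },
            )
        )
        stages.append(
            _cycle_stage("final_reinforce", pattern_sched, f_max, "low", n_cycles=6)
        )
    return Recipe(stages=stages, label=f"letter {letter}")


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def _drag_states(geometry, start, target_radius, step):
    """Vortex foci along the radial path from a straggler to the edge."""
    start = np.asarray(start, dtype=float)
    r0 = float(np.hypot(start[0], start[1]))
    u = start / r0 if r0 > 1e-9 else np.array([1.0, 0.0])
    radii = np.arange(r0, target_radius + 0.5 * step, step)
    radii = radii[radii < geometry.radius - 0.3e-3]
    return [bessel_drive(geometry, 1, u * r) for r in radii]


def execute_recipe(
    ensemble,
    recipe: Recipe,
    workspace: Workspace,
    log: list | None = None,
):
    """Run a recipe stage by stage; returns the final ensemble.

    The adaptive ``vortex_removal`` stage re-detects off-pattern
    particles between rounds and drags each one radially outward with an
    order-1 vortex trap in the intermediate/high impulse range.
    """
    from .bench import Ensemble  # local import; bench sits above patterning

    current = ensemble
    for stage in recipe.stages:
        if stage.tool == "vortex_removal":
            current = _run_removal(current, stage, workspace, log)
            continue
        if stage.schedule is None or stage.schedule.n_states == 0 or stage.duration <= 0:
            continue
        res = simulate_switched(
            current, stage.schedule, stage.duration, workspace, f_max=stage.f_max
        )
        disp = np.linalg.norm(res.final_positions - current.positions, axis=1)
        if log is not None:
            log.append(
                {
                    "stage": stage.label,
                    "regime": stage.regime,
                    "I_app_pNs": stage.f_max * stage.dwell * 1e12,
                    "mean_disp_um": float(disp.mean() * 1e6) if disp.size else 0.0,
                    "max_disp_um": float(disp.max() * 1e6) if disp.size else 0.0,
                }
            )
        current = current.with_state(res.final_positions, res.final_velocities)
    return current


def _run_removal(ensemble, stage: Stage, workspace: Workspace, log):
    p = stage.params
    skel = p["skeleton"]
    tol = p["tolerance"]
    target = p["target_radius"]
    dwell = p["dwell"]
    reinforce = p.get("reinforce_schedule")
    reinforce_every = int(p.get("reinforce_every", 0))
    geometry = workspace.geometry
    pattern_radius = max(float(np.max(np.hypot(q[:, 0], q[:, 1]))) for q in skel)
    current = ensemble

    def one_state(drive, ens):
        sched = SwitchingSchedule([drive], np.array([dwell]))
        res = simulate_switched(ens, sched, dwell, workspace, f_max=stage.f_max)
        return ens.with_state(res.final_positions, res.final_velocities)

    for round_i in range(int(p["max_rounds"])):
        pos = current.positions
        r = np.hypot(pos[:, 0], pos[:, 1])
        stray = (polyline_distance(pos, skel) > tol) & (r < target)
        idx = np.nonzero(stray)[0]
        if idx.size == 0:
            break
        idx = idx[np.argsort(r[idx])]  # innermost first
        n_pushed = n_dragged = 0
        for count, i in enumerate(idx, start=1):
            if np.hypot(*current.positions[i]) < pattern_radius + 0.2e-3:
                # interior straggler: nudge it onto the nearest skeleton
                # line with brief focused-point pushes
                for _ in range(12):
                    pp = current.positions[i]
                    q, d = nearest_on_polylines(pp, skel)
                    if d <= tol:
                        break
                    focus = pp + 0.1e-3 * (pp - q) / d
                    current = one_state(bessel_drive(geometry, 0, focus), current)
                n_pushed += 1
            else:
                # exterior straggler: vortex-drag radially to the edge
                for drive in _drag_states(
                    geometry, current.positions[i], target, p["step"]
                ):
                    current = one_state(drive, current)
                n_dragged += 1
            if reinforce is not None and reinforce_every and count % reinforce_every == 0:
                res = simulate_switched(
                    current, reinforce, 4 * reinforce.cycle_time, workspace
                )
                current = current.with_state(res.final_positions, res.final_velocities)
        if reinforce is not None:
            res = simulate_switched(
                current, reinforce, 6 * reinforce.cycle_time, workspace
            )
            current = current.with_state(res.final_positions, res.final_velocities)
        if log is not None:
            log.append(
                {
                    "stage": f"{stage.label}[round {round_i}]",
                    "regime": stage.regime,
                    "I_app_pNs": stage.f_max * dwell * 1e12,
                    "pushed_to_pattern": n_pushed,
                    "dragged_to_edge": n_dragged,
                }
            )
    return current
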