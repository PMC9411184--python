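"""Circular phased-array geometry and 2D pressure-field synthesis.

The device is a ring of N phase- and amplitude-controlled ultrasound
elements facing a water-filled chamber.  Complex pressure on a Cartesian
grid is obtained by Huygens matrix propagation: each element contributes a
cylindrically spreading wave ``exp(-i k r) / (2*pi*sqrt(r))`` shaped by a
piston (sinc) directivity, and the grid pressure is the propagation matrix
applied to the per-element complex drive.

Drive-state constructors implement the field types used for patterning:

* ``bessel_drive`` -- order-m vortex / focus phase law
  ``phi_n = chirality * 2*pi*m*(n-1)/N - k*r_n``,
* ``twin_trap_drive`` -- an m=0 focus with a pi phase inversion across a
  cancellation axis (two pressure lobes flanking a dark trap centre),
* ``standing_wave_drive`` -- two opposing sub-apertures synthesizing a
  plane standing wave whose nodes step by lambda/6 per 2*pi/3 phase
  increment (the "conveyor belt").

Sign conventions: time-harmonic factor ``exp(-i*omega*t)``, so a wave
that propagates away from a source carries phase ``exp(+i k r)``.  This
is the convention under which the focusing phase law ``-k r_n`` aligns
all element contributions at the focus; all time-averaged observables
(|p|, <p^2>, <v^2>, forces) are invariant under the conjugate choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GeometryError",
    "OutOfBoundsError",
    "ApertureError",
    "SingularDistanceError",
    "Medium",
    "WATER",
    "ArrayGeometry",
    "DriveState",
    "Grid",
    "FieldGrid",
    "PropagationOperator",
    "wrap_phase",
    "build_circular_array",
    "device_array",
    "make_grid",
    "transfer_matrix",
    "synthesize_pressure",
    "bessel_drive",
    "twin_trap_drive",
    "standing_wave_drive",
    "DEVICE_N_ELEMENTS",
    "DEVICE_CHAMBER_DIAMETER",
    "DEVICE_FREQUENCY",
    "DEVICE_WAVELENGTH",
    "CENTRAL_REGION_RADIUS",
]


class GeometryError(ValueError):
    """Invalid array geometry (non-positive dimensions, too few elements)."""


class OutOfBoundsError(ValueError):
    """A requested focus or line lies outside the chamber / region."""


class ApertureError(ValueError):
    """A sub-aperture request does not fit the array."""


class SingularDistanceError(ValueError):
    """A grid node coincides with an array element."""


# Device constants of the 64-element circular array (operating in water).
DEVICE_N_ELEMENTS = 64
DEVICE_CHAMBER_DIAMETER = 10.98e-3  # m
DEVICE_FREQUENCY = 2.35e6  # Hz
DEVICE_WAVELENGTH = 0.644e-3  # m, the device's printed operating wavelength
CENTRAL_REGION_RADIUS = 2.0e-3  # m, central 4 mm patterning region


def wrap_phase(phi: np.ndarray | float) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    out = np.asarray(-((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi))
    return out


@dataclass(frozen=True)
class Medium:
    """Host fluid acoustic properties.

    Parameters
    ----------
    c0 : float
        Sound speed (m/s).
    rho0 : float
        Density (kg/m^3).
    mu0 : float
        Dynamic viscosity (Pa s).
    """

    c0: float
    rho0: float
    mu0: float

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.rho0 <= 0 or self.mu0 <= 0:
            raise ValueError("medium properties must be positive")

    @property
    def kappa0(self) -> float:
        """Compressibility 1/(rho0 c0^2) (1/Pa)."""
        return 1.0 / (self.rho0 * self.c0 * self.c0)


#: Water at 25 C, the chamber fill used throughout.
WATER = Medium(c0=1500.0, rho0=997.0, mu0=0.89e-3)


@dataclass(frozen=True)
class ArrayGeometry:
    """A circular ring array of small piston elements facing inward."""

    n_elements: int
    chamber_diameter: float
    element_width: float
    frequency: float
    medium: Medium
    wavelength: float
    element_positions: np.ndarray = field(repr=False)  # (N, 2) m
    element_normals: np.ndarray = field(repr=False)  # (N, 2) unit, inward

    @property
    def radius(self) -> float:
        return 0.5 * self.chamber_diameter

    @property
    def k(self) -> float:
        """Wavenumber 2 pi / lambda (1/m)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def element_angles(self) -> np.ndarray:
        """Polar angle of each element centre (rad)."""
        p = self.element_positions
        return np.arctan2(p[:, 1], p[:, 0])

    @property
    def angular_pitch(self) -> float:
        return 2.0 * np.pi / self.n_elements

    def contains(self, point, margin: float = 0.0) -> bool:
        point = np.asarray(point, dtype=float)
        return float(np.hypot(point[0], point[1])) <= self.radius - margin


def build_circular_array(
    n_elements: int,
    chamber_diameter: float,
    element_width: float | None = None,
    frequency: float = DEVICE_FREQUENCY,
    medium: Medium = WATER,
    wavelength: float | None = None,
) -> ArrayGeometry:
    """Place ``n_elements`` equally around a circle, normals pointing inward.

    Parameters
    ----------
    element_width : float, optional
        Piston width ``a`` entering the directivity.  Defaults to the
        full chord pitch ``2 R sin(pi/N)`` (contiguous elements).
    wavelength : float, optional
        Override for the operating wavelength.  By default it is derived
        as ``c0 / frequency``; pass the device's printed value for
        device-matching runs (see :func:`device_array`).
    """
    if n_elements < 3:
        raise GeometryError("need at least 3 elements on the ring")
    if chamber_diameter <= 0 or frequency <= 0:
        raise GeometryError("chamber diameter and frequency must be positive")
    radius = 0.5 * chamber_diameter
    if element_width is None:
        element_width = 2.0 * radius * np.sin(np.pi / n_elements)
    if element_width <= 0:
        raise GeometryError("element width must be positive")
    if wavelength is None:
        wavelength = medium.c0 / frequency
    ang = 2.0 * np.pi * np.arange(n_elements) / n_elements
    positions = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    normals = -positions / radius
    return ArrayGeometry(
        n_elements=n_elements,
        chamber_diameter=chamber_diameter,
        element_width=element_width,
        frequency=frequency,
        medium=medium,
        wavelength=wavelength,
        element_positions=positions,
        element_normals=normals,
    )


def device_array(medium: Medium = WATER) -> ArrayGeometry:
    """The 64-element, 10.98 mm, 2.35 MHz device with its printed
    operating wavelength of 0.644 mm."""
    return build_circular_array(
        DEVICE_N_ELEMENTS,
        DEVICE_CHAMBER_DIAMETER,
        frequency=DEVICE_FREQUENCY,
        medium=medium,
        wavelength=DEVICE_WAVELENGTH,
    )


@dataclass(frozen=True)
class DriveState:
    """Per-element complex drive: non-negative amplitudes and phases.

    Phases are stored wrapped to (-pi, pi].
    """

    amplitudes: np.ndarray
    phases: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        phi = wrap_phase(np.asarray(self.phases, dtype=float))
        if amp.shape != phi.shape or amp.ndim != 1:
            raise ValueError("amplitudes and phases must be equal-length 1D")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "phases", phi)

    @property
    def n_elements(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def complex_drive(self) -> np.ndarray:
        return self.amplitudes * np.exp(1j * self.phases)

    def scaled(self, factor: float) -> "DriveState":
        return replace(self, amplitudes=self.amplitudes * factor)

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "amplitudes": self.amplitudes.tolist(),
            "phases": self.phases.tolist(),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "DriveState":
        return cls(
            amplitudes=np.asarray(rec["amplitudes"], dtype=float),
            phases=np.asarray(rec["phases"], dtype=float),
            label=rec.get("label", ""),
        )


def save_drives(path: str | Path, drives: list[DriveState]) -> None:
    Path(path).write_text(json.dumps([d.to_record() for d in drives], indent=1))


def load_drives(path: str | Path) -> list[DriveState]:
    return [DriveState.from_record(r) for r in json.loads(Path(path).read_text())]


@dataclass(frozen=True)
class Grid:
    """Uniform square Cartesian grid, origin at the array centre.

    ``x`` runs along axis 0 and ``y`` along axis 1 of all gridded arrays
    (matplotlib users should transpose before ``imshow``).
    """

    x: np.ndarray  # (nx,) m
    y: np.ndarray  # (ny,) m

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.x.size, self.y.size)

    @property
    def n_nodes(self) -> int:
        return self.x.size * self.y.size

    def points(self) -> np.ndarray:
        """All grid nodes as an (n_nodes, 2) array, x-major."""
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel()], axis=1)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")


def make_grid(
    half_width: float = CENTRAL_REGION_RADIUS,
    spacing: float | None = None,
    wavelength: float = DEVICE_WAVELENGTH,
) -> Grid:
    """Square grid covering ``[-half_width, half_width]^2``.

    Default spacing is ``lambda/20``; a spacing coarser than ``lambda/10``
    (the resolution floor for the force finite differences) is rejected.
    """
    if spacing is None:
        spacing = wavelength / 20.0
    if spacing > wavelength / 10.0 + 1e-15:
        raise ValueError("grid spacing must be <= lambda/10")
    n = int(np.floor(2.0 * half_width / spacing)) + 1
    x = -half_width + spacing * np.arange(n)
    return Grid(x=x, y=x.copy())


@dataclass(frozen=True)
class FieldGrid:
    """Complex pressure sampled on a grid (Pa per unit source amplitude)."""

    grid: Grid
    pressure: np.ndarray = field(repr=False)  # (nx, ny) complex
    frequency: float = DEVICE_FREQUENCY

    def __post_init__(self) -> None:
        if self.pressure.shape != self.grid.shape:
            raise ValueError("pressure array does not match grid shape")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    def to_dataframe(self):
        import pandas as pd

        pts = self.grid.points()
        p = self.pressure.ravel()
        return pd.DataFrame(
            {"x": pts[:, 0], "y": pts[:, 1], "re_p": p.real, "im_p": p.imag}
        )


@dataclass(frozen=True)
class PropagationOperator:
    """Huygens transfer matrix from element drives to grid pressure."""

    geometry: ArrayGeometry
    grid: Grid
    H: np.ndarray = field(repr=False)  # (n_nodes, N) complex


def _sinc_unnormalized(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the limit value 1 at x = 0."""
    return np.sinc(np.asarray(x) / np.pi)


def transfer_matrix(
    geometry: ArrayGeometry,
    grid: Grid,
    source_scale: float = 1.0,
) -> PropagationOperator:
    """Build the propagation matrix ``H``.

    Each entry is ``S_w exp(i k r) / (2 pi sqrt(r))`` times the piston
    directivity ``sinc(a pi^2 sin(theta) / lambda)`` where ``r`` and
    ``theta`` are the distance and off-normal angle from the element to
    the grid node.  ``source_scale`` is the free hydrophone-calibration
    constant S_w (irrelevant once forces are normalized; defaults to 1).
    """
    pts = grid.points()  # (M, 2)
    epos = geometry.element_positions  # (N, 2)
    enrm = geometry.element_normals
    d = pts[:, None, :] - epos[None, :, :]  # (M, N, 2), element -> node
    r = np.hypot(d[..., 0], d[..., 1])
    if np.any(r <= 0):
        raise SingularDistanceError("grid node coincides with an element")
    # angle from the inward normal
    cos_t = (d[..., 0] * enrm[None, :, 0] + d[..., 1] * enrm[None, :, 1]) / r
    sin_t = (d[..., 0] * enrm[None, :, 1] - d[..., 1] * enrm[None, :, 0]) / r
    theta = np.arctan2(sin_t, cos_t)
    arg = geometry.element_width * np.pi**2 * np.sin(theta) / geometry.wavelength
    directivity = _sinc_unnormalized(arg)
    H = (
        source_scale
        * np.exp(1j * geometry.k * r)
        / (2.0 * np.pi * np.sqrt(r))
        * directivity
    )
    return PropagationOperator(geometry=geometry, grid=grid, H=H.astype(np.complex128))


def synthesize_pressure(op: PropagationOperator, drive: DriveState) -> FieldGrid:
    """Linear field synthesis ``p = H a`` for a complex element drive."""
    if drive.n_elements != op.geometry.n_elements:
        raise ValueError(
            f"drive has {drive.n_elements} elements, "
            f"array has {op.geometry.n_elements}"
        )
    p = op.H @ drive.complex_drive
    return FieldGrid(
        grid=op.grid,
        pressure=p.reshape(op.grid.shape),
        frequency=op.geometry.frequency,
    )


def bessel_drive(
    geometry: ArrayGeometry,
    order: int,
    focus=(0.0, 0.0),
    chirality: int = 1,
    label: str | None = None,
) -> DriveState:
    """Vortex / focus phase law for a ring array.

    Element n (zero-based) receives phase
    ``chirality * 2 pi m n / N - k r_n`` with ``r_n`` the element-to-focus
    distance.  Order 0 is a plain focus; order m has a 2 pi m azimuthal
    phase winding whose dark core grows with m.
    """
    if order < 0:
        raise ValueError("Bessel order must be >= 0")
    if chirality not in (-1, 1):
        raise ValueError("chirality must be +1 or -1")
    focus = np.asarray(focus, dtype=float)
    if not geometry.contains(focus):
        raise OutOfBoundsError("focus lies outside the chamber")
    n = np.arange(geometry.n_elements)
    r_n = np.hypot(*(geometry.element_positions - focus[None, :]).T)
    phases = chirality * 2.0 * np.pi * order * n / geometry.n_elements - geometry.k * r_n
    if label is None:
        label = f"bessel(m={order},chi={chirality:+d})@({focus[0]*1e3:.2f},{focus[1]*1e3:.2f})mm"
    return DriveState(
        amplitudes=np.ones(geometry.n_elements), phases=phases, label=label
    )


def twin_trap_drive(
    geometry: ArrayGeometry,
    focus=(0.0, 0.0),
    axis_angle: float = 0.0,
    label: str | None = None,
) -> DriveState:
    """Twin trap: m=0 focus plus a pi inversion across a cancellation axis.

    The axis is the line through ``focus`` at ``axis_angle``.  Elements on
    one side of the axis are offset by pi; elements whose angular position
    falls within half an element pitch of the axis' intersections with the
    ring are switched off.  The result is two high-pressure lobes flanking
    a low-pressure centre at the focus.
    """
    focus = np.asarray(focus, dtype=float)
    if not geometry.contains(focus):
        raise OutOfBoundsError("focus lies outside the chamber")
    base = bessel_drive(geometry, 0, focus)
    u = np.array([np.cos(axis_angle), np.sin(axis_angle)])
    rel = geometry.element_positions - focus[None, :]
    side = u[0] * rel[:, 1] - u[1] * rel[:, 0]  # signed distance sign
    phases = base.phases + np.where(side > 0, np.pi, 0.0)

    # intersections of the axis line with the element circle
    # |focus + t*u| = R  ->  t^2 + 2 (f.u) t + |f|^2 - R^2 = 0
    fu = float(focus @ u)
    disc = fu * fu - (focus @ focus - geometry.radius**2)
    amplitudes = np.ones(geometry.n_elements)
    if disc > 0:
        for t in (-fu + np.sqrt(disc), -fu - np.sqrt(disc)):
            hit = focus + t * u
            ang = np.arctan2(hit[1], hit[0])
            dang = np.abs(wrap_phase(geometry.element_angles - ang))
            amplitudes[dang <= 0.5 * geometry.angular_pitch + 1e-12] = 0.0
    if label is None:
        label = (
            f"twin@({focus[0]*1e3:.3f},{focus[1]*1e3:.3f})mm,"
            f"axis={np.degrees(axis_angle):.1f}deg"
        )
    return DriveState(amplitudes=amplitudes, phases=phases, label=label)


def standing_wave_drive(
    geometry: ArrayGeometry,
    aperture_half_count: int = 11,
    axis_angle: float = 0.0,
    step_index: int = 0,
    offset_sign: int = 1,
    label: str | None = None,
) -> DriveState:
    """One state of the three-step standing-wave conveyor.

    Two opposing sub-apertures of ``aperture_half_count`` elements each are
    active.  Every element carries a curvature-correcting phase ``k r_sw``
    (``r_sw`` = distance from the element to the wavefront plane through
    the centre) so the apertures launch counter-propagating plane waves
    along ``axis_angle``.  ``step_index`` adds ``step * 2 pi / 3`` on one
    side and subtracts it on the other; three steps return the field to
    its initial state while the pressure-node lines advance by lambda/6
    per step (lambda/2 per loop), in the direction set by ``offset_sign``.
    """
    if aperture_half_count < 1 or aperture_half_count > geometry.n_elements // 2:
        raise ApertureError("aperture_half_count must be in [1, N/2]")
    if offset_sign not in (-1, 1):
        raise ValueError("offset_sign must be +1 or -1")
    u = np.array([np.cos(axis_angle), np.sin(axis_angle)])
    along = geometry.element_positions @ u  # signed coordinate along the axis
    order_a = np.argsort(-along)  # closest to +u aperture centre
    order_b = np.argsort(along)
    side_a = order_a[:aperture_half_count]
    side_b = order_b[:aperture_half_count]
    amplitudes = np.zeros(geometry.n_elements)
    amplitudes[side_a] = 1.0
    amplitudes[side_b] = 1.0
    # plane-wave correction: advance each element by its distance to the
    # wavefront plane through the centre (perpendicular to the axis)
    phases = geometry.k * np.abs(along)
    step = step_index % 3
    offset = offset_sign * step * 2.0 * np.pi / 3.0
    phases = phases.copy()
    phases[side_a] += offset
    phases[side_b] -= offset
    if label is None:
        label = (
            f"conveyor(axis={np.degrees(axis_angle):.1f}deg,step={step},"
            f"sign={offset_sign:+d})"
        )
    return DriveState(amplitudes=amplitudes, phases=phases, label=label)
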