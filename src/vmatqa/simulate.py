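"""Synthetic VMAT delivery and measurement on a two-plane cylindrical diode array.

This module stands in for the clinical data source of a patient-specific QA
workflow: a treatment planning system computing 3D dose on a 2.5 mm grid, a
linac delivering full-arc VMAT plans, and a cylindrical phantom with two
inclined diode planes sampling the delivered dose.  The dose engine is a
deliberately simplified analytic model -- beam's-eye-view fluence built from
MLC apertures, a Gaussian penumbra blur, and exponential attenuation with
depth inside the cylindrical phantom -- chosen so that each simulated delivery
error (MLC offsets, gantry rotation, output scaling, setup shifts) perturbs
the planar dose with the same geometric/scaling structure as on a real device.

Axis convention (right handed, isocenter at origin, mm):
    x = lateral, y = longitudinal (couch axis == gantry rotation axis),
    z = vertical.
Detector plane k contains the y axis and the unit vector
``e1 = (sin(alpha_k), 0, cos(alpha_k))`` where ``alpha_k`` is the signed
inclination from vertical; in-plane coordinates are ``(p, y)`` with
``world = p * e1 + y * yhat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DetectorConfig",
    "DetectorGeometry",
    "make_detector_geometry",
    "ControlPoint",
    "VMATPlan",
    "sample_plan",
    "DoseEngineParams",
    "DoseGrid",
    "PlanarDose",
    "compute_dose",
    "dose_at_points",
    "ErrorSpec",
    "ERROR_KINDS",
    "inject_error",
    "NoiseConfig",
    "simulate_measurement",
    "BeamRecord",
    "Dataset",
    "generate_dataset",
]

ERROR_KINDS = (
    "none",
    "mlc_systematic",
    "mlc_random",
    "gantry_cw",
    "gantry_ccw",
    "output_plus",
    "output_minus",
    "setup_lat",
    "setup_lng",
    "setup_vrt",
)

#: default error magnitudes: 2 mm MLC offsets, 2 deg gantry, 3 % output,
#: 1 mm setup shifts
DEFAULT_MAGNITUDES = {
    "none": 0.0,
    "mlc_systematic": 2.0,
    "mlc_random": 2.0,
    "gantry_cw": 2.0,
    "gantry_ccw": 2.0,
    "output_plus": 0.03,
    "output_minus": 0.03,
    "setup_lat": 1.0,
    "setup_lng": 1.0,
    "setup_vrt": 1.0,
}


# ---------------------------------------------------------------------------
# Detector geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorConfig:
    """Layout of the two-plane diode array.

    The default emulates a cylindrical two-plane device: planes inclined 50
    and 40 degrees (opposite senses) from vertical, diodes on a square
    lattice with 5 mm pitch in the central 6x6 cm and 10 mm pitch outside,
    out to a 20x20 cm extent.
    """

    plane_angles: tuple[float, float] = (50.0, -40.0)
    central_pitch: float = 5.0
    outer_pitch: float = 10.0
    central_half_extent: float = 30.0
    half_extent: float = 100.0
    phantom_radius: float = 110.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Diode positions of a two-plane cylindrical detector.

    ``in_plane[k]`` is an (n_k, 2) array of (p, y) coordinates for plane k,
    ``world[k]`` the matching (n_k, 3) phantom-frame positions and
    ``pitch_map[k]`` the per-diode spacing class (5 central / 10 peripheral).
    """

    plane_angles: tuple[float, float]
    in_plane: tuple[np.ndarray, np.ndarray]
    world: tuple[np.ndarray, np.ndarray]
    pitch_map: tuple[np.ndarray, np.ndarray]
    phantom_radius: float
    config: DetectorConfig

    @property
    def n_planes(self) -> int:
        return len(self.in_plane)

    def plane_basis(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane basis (e1, e2) of plane ``k`` in world frame."""
        a = np.radians(self.plane_angles[k])
        e1 = np.array([np.sin(a), 0.0, np.cos(a)])
        e2 = np.array([0.0, 1.0, 0.0])
        return e1, e2

    def to_world(self, k: int, pq: np.ndarray) -> np.ndarray:
        """Map (m, 2) in-plane (p, y) coordinates of plane ``k`` to world xyz."""
        e1, e2 = self.plane_basis(k)
        pq = np.asarray(pq, dtype=float)
        return pq[..., :1] * e1 + pq[..., 1:2] * e2


def _plane_layout(cfg: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Square-lattice diode layout for one plane -> (coords (n,2), pitch (n,))."""
    c = np.arange(-cfg.central_half_extent, cfg.central_half_extent + 1e-9,
                  cfg.central_pitch)
    pc, yc = np.meshgrid(c, c, indexing="ij")
    central = np.column_stack([pc.ravel(), yc.ravel()])

    o = np.arange(-cfg.half_extent, cfg.half_extent + 1e-9, cfg.outer_pitch)
    po, yo = np.meshgrid(o, o, indexing="ij")
    outer = np.column_stack([po.ravel(), yo.ravel()])
    inside_central = (np.abs(outer[:, 0]) <= cfg.central_half_extent + 1e-9) & (
        np.abs(outer[:, 1]) <= cfg.central_half_extent + 1e-9
    )
    outer = outer[~inside_central]

    coords = np.vstack([central, outer])
    pitch = np.concatenate([
        np.full(len(central), cfg.central_pitch),
        np.full(len(outer), cfg.outer_pitch),
    ])
    keep = np.abs(coords[:, 0]) <= cfg.phantom_radius - 1e-9
    return coords[keep], pitch[keep]


def make_detector_geometry(config: DetectorConfig | None = None) -> DetectorGeometry:
    """Build the diode geometry; deterministic for a fixed config."""
    cfg = config or DetectorConfig()
    if len(cfg.plane_angles) != 2:
        raise ValueError("exactly two detector planes are required")
    if cfg.central_pitch <= 0 or cfg.outer_pitch <= 0:
        raise ValueError("diode pitch must be positive")
    if cfg.half_extent <= 0 or cfg.central_half_extent <= 0:
        raise ValueError("detector extent must be positive")
    if cfg.phantom_radius <= 0:
        raise ValueError("phantom radius must be positive")
    if cfg.half_extent > cfg.phantom_radius:
        raise ValueError("detector extent exceeds the phantom cross-section")

    coords, pitch = _plane_layout(cfg)
    geom = DetectorGeometry(
        plane_angles=tuple(cfg.plane_angles),
        in_plane=(coords, coords.copy()),
        world=(np.empty(0), np.empty(0)),  # placeholder, filled below
        pitch_map=(pitch, pitch.copy()),
        phantom_radius=cfg.phantom_radius,
        config=cfg,
    )
    world = tuple(geom.to_world(k, geom.in_plane[k]) for k in range(2))
    return replace(geom, world=world)


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass
class ControlPoint:
    gantry_deg: float
    mu_weight: float
    #: (n_pairs, 2) leaf tips (a, b) in mm at the isocenter plane, a <= b
    leaves: np.ndarray


@dataclass
class VMATPlan:
    control_points: list[ControlPoint]
    leaf_pitch: float = 5.0
    prescription_scale: float = 1.0

    @property
    def n_leaf_pairs(self) -> int:
        return self.control_points[0].leaves.shape[0]

    def leaf_row_edges(self) -> np.ndarray:
        half = self.n_leaf_pairs * self.leaf_pitch / 2.0
        return np.arange(self.n_leaf_pairs + 1) * self.leaf_pitch - half

    def validate(self) -> None:
        if not self.control_points:
            raise ValueError("plan has no control points")
        for cp in self.control_points:
            if not (0.0 <= cp.gantry_deg < 360.0):
                raise ValueError("gantry angle outside [0, 360)")
            if cp.mu_weight <= 0:
                raise ValueError("mu_weight must be positive")
            if np.any(cp.leaves[:, 0] > cp.leaves[:, 1] + 1e-12):
                raise ValueError("leaf pair with a > b")


def sample_plan(
    seed: int,
    n_control_points: int = 24,
    n_leaf_pairs: int = 28,
    engine: "DoseEngineParams | None" = None,
    target_isocenter_dose: float = 2.0,
) -> VMATPlan:
    """Draw a random full-arc plan with a smoothly modulated elliptical aperture.

    The prescription scale is calibrated so the error-free isocenter dose is
    ``target_isocenter_dose`` (Gy), emulating a ~2 Gy/fraction prostate plan.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    engine = engine or DoseEngineParams()

    pitch = 5.0
    half = n_leaf_pairs * pitch / 2.0
    v_centers = (np.arange(n_leaf_pairs) + 0.5) * pitch - half

    r_ap = rng.uniform(28.0, 40.0)
    drift_amp = rng.uniform(0.0, 5.0)
    drift_phase = rng.uniform(0.0, 2 * np.pi)
    mod_amp = rng.uniform(2.0, 7.0)
    mod_freq = rng.integers(2, 5)
    mod_phase = rng.uniform(0.0, 2 * np.pi, size=2)
    leaf_noise = rng.normal(0.0, 1.0, size=(n_leaf_pairs, 2))
    mu_phase = rng.uniform(0.0, 2 * np.pi)

    step = 360.0 / n_control_points
    start = rng.uniform(0.0, step)
    cps: list[ControlPoint] = []
    for i in range(n_control_points):
        gantry = (start + i * step) % 360.0
        t = 2 * np.pi * i / n_control_points
        center = drift_amp * np.sin(t + drift_phase)
        w = np.sqrt(np.maximum(r_ap**2 - v_centers**2, 0.0))
        open_rows = w > 0
        mod_a = mod_amp * 0.5 * (
            1 + np.sin(mod_freq * t + mod_phase[0] + v_centers / 40.0)
        )
        mod_b = mod_amp * 0.5 * (
            1 + np.sin(mod_freq * t + mod_phase[1] - v_centers / 40.0)
        )
        a = center - w - mod_a - leaf_noise[:, 0]
        b = center + w + mod_b + leaf_noise[:, 1]
        a[~open_rows] = center
        b[~open_rows] = center
        b = np.maximum(a, b)
        mu = 1.0 + 0.2 * np.sin(t + mu_phase)
        cps.append(ControlPoint(gantry, float(max(mu, 0.05)),
                                np.column_stack([a, b])))

    plan = VMATPlan(cps, leaf_pitch=pitch)
    plan.validate()
    d_iso = dose_at_points(plan, np.zeros((1, 3)), engine)[0]
    if d_iso <= 0:
        raise RuntimeError("sampled plan delivers no dose to the isocenter")
    plan.prescription_scale = target_isocenter_dose / d_iso
    return plan


# ---------------------------------------------------------------------------
# Dose engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEngineParams:
    """Parameters of the simplified analytic dose model."""

    grid_spacing: float = 2.5          # mm, 3D dose grid
    grid_half_extent: float = 110.0    # mm
    phantom_radius: float = 110.0      # mm, attenuation cylinder about y
    mu_attenuation: float = 0.004      # 1/mm, effective 10 MV attenuation
    penumbra_sigma: float = 3.0        # mm, Gaussian fluence blur
    transmission: float = 0.015        # MLC leakage fraction

    def grid_axes(self) -> np.ndarray:
        return np.arange(-self.grid_half_extent,
                         self.grid_half_extent + 1e-9, self.grid_spacing)


@dataclass
class DoseGrid:
    """Non-negative scalar dose on a regular isocenter-centered 3D grid."""

    values: np.ndarray               # (nx, ny, nz)
    spacing: float
    half_extent: float

    def axes(self) -> np.ndarray:
        return np.arange(-self.half_extent, self.half_extent + 1e-9,
                         self.spacing)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at (m, 3) world points; 0 outside."""
        ax = self.axes()
        interp = RegularGridInterpolator(
            (ax, ax, ax), self.values, method="linear",
            bounds_error=False, fill_value=0.0,
        )
        return interp(np.asarray(points, dtype=float))

    def isocenter_index(self) -> tuple[int, int, int]:
        i = int(round(self.half_extent / self.spacing))
        return (i, i, i)


@dataclass
class PlanarDose:
    """Per-diode dose values (Gy) on one detector plane."""

    plane: int
    values: np.ndarray


def _fluence_map(plan: VMATPlan, cp: ControlPoint,
                 engine: DoseEngineParams) -> np.ndarray:
    """Blurred BEV fluence of one control point on the (u, v) lattice.

    Leaf apertures are rasterized with partial-cell coverage so the fluence is
    continuous in the leaf positions (a 2 mm offset always moves the edge).
    """
    u = engine.grid_axes()
    nv = len(u)
    edges = plan.leaf_row_edges()
    row = np.searchsorted(edges, u, side="right") - 1
    in_stack = (row >= 0) & (row < plan.n_leaf_pairs)
    row_c = np.clip(row, 0, plan.n_leaf_pairs - 1)
    a = np.where(in_stack, cp.leaves[row_c, 0], 0.0)
    b = np.where(in_stack, cp.leaves[row_c, 1], 0.0)

    h = engine.grid_spacing / 2.0
    lo = np.maximum(a[None, :], u[:, None] - h)
    hi = np.minimum(b[None, :], u[:, None] + h)
    coverage = np.clip((hi - lo) / engine.grid_spacing, 0.0, 1.0)
    f = engine.transmission + (1.0 - engine.transmission) * coverage
    f[:, ~in_stack] = 0.0
    sigma = engine.penumbra_sigma / engine.grid_spacing
    return ndimage.gaussian_filter(f, sigma=sigma, mode="constant")


def _beam_coords(theta: float, x: np.ndarray, z: np.ndarray):
    """BEV lateral coordinate u and along-beam depth coordinate w.

    Gantry angle 0 places the source on the +z axis with the beam travelling
    toward -z; the gantry rotates about +y.
    """
    u = x * np.cos(theta) - z * np.sin(theta)
    w = -(x * np.sin(theta) + z * np.cos(theta))
    return u, w


def compute_dose(
    plan: VMATPlan,
    geometry: DetectorGeometry | None = None,
    engine: DoseEngineParams | None = None,
) -> tuple[DoseGrid, tuple[PlanarDose, PlanarDose] | None]:
    """Accumulate dose over control points on the 3D grid.

    Per control point the dose at a voxel is
    ``mu_weight * F(u, v) * exp(-mu * depth)`` with F the blurred fluence,
    (u, v) the BEV coordinates and depth measured from the cylindrical phantom
    surface along the (parallel) beam.  Planar doses are the grid sampled at
    the diode positions by trilinear interpolation.
    """
    plan.validate()
    engine = engine or DoseEngineParams()
    ax = engine.grid_axes()
    n = len(ax)
    r2 = ax[:, None] ** 2 + ax[None, :] ** 2  # (x, z)
    in_phantom = r2 <= engine.phantom_radius**2 + 1e-9

    accum = np.zeros((n * n, n))  # (x*z, y)
    u0, du = ax[0], engine.grid_spacing
    rp2 = engine.phantom_radius**2
    for cp in plan.control_points:
        theta = np.radians(cp.gantry_deg)
        u, w = _beam_coords(theta, ax[:, None], ax[None, :])
        half_chord = np.sqrt(np.maximum(rp2 - u**2, 0.0))
        depth = w + half_chord
        att = np.where(in_phantom, np.exp(-engine.mu_attenuation * depth), 0.0)
        att *= cp.mu_weight

        f = _fluence_map(plan, cp, engine)  # (u, v) with v == grid y axis
        iu = (u.ravel() - u0) / du
        i0 = np.clip(np.floor(iu).astype(np.intp), 0, n - 2)
        frac = np.clip(iu - i0, 0.0, 1.0)
        fq = f[i0, :] * (1.0 - frac)[:, None] + f[i0 + 1, :] * frac[:, None]
        accum += att.ravel()[:, None] * fq

    values = accum.reshape(n, n, n).transpose(0, 2, 1) * plan.prescription_scale
    grid = DoseGrid(values, engine.grid_spacing, engine.grid_half_extent)
    planar = None
    if geometry is not None:
        planar = tuple(
            PlanarDose(k, grid.sample(geometry.world[k]))
            for k in range(geometry.n_planes)
        )
    return grid, planar


def dose_at_points(
    plan: VMATPlan,
    points: np.ndarray,
    engine: DoseEngineParams | None = None,
) -> np.ndarray:
    """Evaluate the analytic dose model directly at arbitrary world points."""
    plan.validate()
    engine = engine or DoseEngineParams()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    in_phantom = x**2 + z**2 <= engine.phantom_radius**2 + 1e-9

    ax = engine.grid_axes()
    n = len(ax)
    u0, du = ax[0], engine.grid_spacing
    rp2 = engine.phantom_radius**2

    iv = (y - u0) / du
    j0 = np.clip(np.floor(iv).astype(np.intp), 0, n - 2)
    fv = np.clip(iv - j0, 0.0, 1.0)

    total = np.zeros(len(pts))
    for cp in plan.control_points:
        theta = np.radians(cp.gantry_deg)
        u, w = _beam_coords(theta, x, z)
        depth = w + np.sqrt(np.maximum(rp2 - u**2, 0.0))
        att = np.where(in_phantom, np.exp(-engine.mu_attenuation * depth), 0.0)

        f = _fluence_map(plan, cp, engine)
        iu = (u - u0) / du
        i0 = np.clip(np.floor(iu).astype(np.intp), 0, n - 2)
        fu = np.clip(iu - i0, 0.0, 1.0)
        fq = (
            f[i0, j0] * (1 - fu) * (1 - fv)
            + f[i0 + 1, j0] * fu * (1 - fv)
            + f[i0, j0 + 1] * (1 - fu) * fv
            + f[i0 + 1, j0 + 1] * fu * fv
        )
        total += cp.mu_weight * att * fq
    return total * plan.prescription_scale


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    """One simulated delivery error.

    kind in ``ERROR_KINDS``; magnitude in mm (MLC, setup), degrees (gantry) or
    fraction (output).  ``seed`` drives the per-leaf draw of ``mlc_random``.
    """

    kind: str
    magnitude: float | None = None
    seed: int = 0

    def resolved_magnitude(self) -> float:
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"unknown error kind: {self.kind!r}")
        if self.magnitude is None:
            return DEFAULT_MAGNITUDES[self.kind]
        return self.magnitude


def default_error_suite(seed: int = 0) -> list[ErrorSpec]:
    """The nine default error conditions (2 mm MLC, 2 deg, 3 %, 1 mm)."""
    return [ErrorSpec(k, seed=seed) for k in ERROR_KINDS if k != "none"]


def perturb_plan(plan: VMATPlan, spec: ErrorSpec) -> VMATPlan:
    """Apply an MLC error to the plan (other kinds leave the plan unchanged)."""
    mag = spec.resolved_magnitude()
    if spec.kind == "mlc_systematic":
        # both leaf banks shifted the same in-plane direction (+u)
        cps = [ControlPoint(cp.gantry_deg, cp.mu_weight, cp.leaves + mag)
               for cp in plan.control_points]
    elif spec.kind == "mlc_random":
        # independent Gaussian offset per leaf per control point
        rng = np.random.default_rng(spec.seed)
        cps = []
        for cp in plan.control_points:
            offsets = rng.normal(0.0, mag, size=cp.leaves.shape)
            leaves = np.sort(cp.leaves + offsets, axis=1)
            cps.append(ControlPoint(cp.gantry_deg, cp.mu_weight, leaves))
    else:
        return plan
    return VMATPlan(cps, plan.leaf_pitch, plan.prescription_scale)


def error_source_positions(points: np.ndarray, spec: ErrorSpec) -> np.ndarray:
    """Positions at which the *error-free* dose equals the perturbed dose.

    For dose-editing error kinds (gantry rotation, setup shift) the perturbed
    field is ``dose'(p) = dose(T(p))``; this returns ``T(p)``.  Identity for
    kinds that do not edit the dose.
    """
    pts = np.asarray(points, dtype=float)
    mag = spec.resolved_magnitude()
    if spec.kind in ("gantry_cw", "gantry_ccw"):
        # cw = +rotation about +y (viewed from +y), ccw = -rotation
        delta = np.radians(mag if spec.kind == "gantry_cw" else -mag)
        c, s = np.cos(delta), np.sin(delta)
        out = pts.copy()
        out[:, 0] = c * pts[:, 0] + s * pts[:, 2]
        out[:, 2] = -s * pts[:, 0] + c * pts[:, 2]
        return out
    if spec.kind.startswith("setup_"):
        axis = {"setup_lat": 0, "setup_lng": 1, "setup_vrt": 2}[spec.kind]
        out = pts.copy()
        out[:, axis] += mag
        return out
    return pts


def _rotate_grid_about_y(values: np.ndarray, deg: float, axes: np.ndarray) -> np.ndarray:
    """Bilinearly resample a (nx, ny, nz) grid rotated by ``deg`` about +y.

    The rotation axis coincides with the y grid axis, so every y slice shares
    the same 2D source coordinates; this lets the resampling run as four
    fancy-indexed gathers instead of a full 3D interpolation.
    """
    n = len(axes)
    delta = np.radians(deg)
    c, s = np.cos(delta), np.sin(delta)
    x = axes[:, None]
    z = axes[None, :]
    xs = c * x + s * z        # source coords = inverse rotation of output pts
    zs = -s * x + c * z
    return _gather_xz(values, xs, zs, axes)


def _shift_grid(values: np.ndarray, shift: Sequence[float], axes: np.ndarray) -> np.ndarray:
    """Linear-interpolation resample after translating sample points by ``shift``."""
    n = len(axes)
    xs = (axes[:, None] + shift[0]) + 0.0 * axes[None, :]
    zs = (axes[None, :] + shift[2]) + 0.0 * axes[:, None]
    out = _gather_xz(values, xs, zs, axes)
    dy = shift[1]
    if dy != 0.0:
        step = axes[1] - axes[0]
        fshift = dy / step
        k = int(np.floor(fshift))
        f = fshift - k
        out = (1 - f) * _roll_zero(out, -k, axis=1) + f * _roll_zero(out, -(k + 1), axis=1)
    return out


def _roll_zero(a: np.ndarray, k: int, axis: int) -> np.ndarray:
    """np.roll with zero fill instead of wraparound."""
    out = np.zeros_like(a)
    if k == 0:
        return a.copy()
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if k > 0:
        src[axis] = slice(0, a.shape[axis] - k)
        dst[axis] = slice(k, None)
    else:
        src[axis] = slice(-k, None)
        dst[axis] = slice(0, a.shape[axis] + k)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _gather_xz(values: np.ndarray, xs: np.ndarray, zs: np.ndarray,
               axes: np.ndarray) -> np.ndarray:
    """Bilinear gather in the (x, z) plane, shared across all y slices."""
    n = len(axes)
    step = axes[1] - axes[0]
    ix = (xs - axes[0]) / step
    iz = (zs - axes[0]) / step
    inside = (ix >= 0) & (ix <= n - 1) & (iz >= 0) & (iz <= n - 1)
    i0 = np.clip(np.floor(ix).astype(np.intp), 0, n - 2)
    k0 = np.clip(np.floor(iz).astype(np.intp), 0, n - 2)
    fx = np.clip(ix - i0, 0.0, 1.0)
    fz = np.clip(iz - k0, 0.0, 1.0)

    flat = values.transpose(0, 2, 1).reshape(n * n, -1)  # (x*z, y)
    idx00 = (i0 * n + k0).ravel()
    idx10 = ((i0 + 1) * n + k0).ravel()
    idx01 = (i0 * n + k0 + 1).ravel()
    idx11 = ((i0 + 1) * n + k0 + 1).ravel()
    w00 = ((1 - fx) * (1 - fz)).ravel()[:, None]
    w10 = (fx * (1 - fz)).ravel()[:, None]
    w01 = ((1 - fx) * fz).ravel()[:, None]
    w11 = (fx * fz).ravel()[:, None]
    out = (flat[idx00] * w00 + flat[idx10] * w10
           + flat[idx01] * w01 + flat[idx11] * w11)
    out *= inside.ravel()[:, None]
    return out.reshape(n, n, -1).transpose(0, 2, 1)


def inject_error(
    plan: VMATPlan,
    dose: DoseGrid,
    spec: ErrorSpec,
    engine: DoseEngineParams | None = None,
) -> tuple[VMATPlan, DoseGrid]:
    """Produce the error-containing (plan, dose) pair for one error kind.

    MLC errors perturb the plan and recompute the dose (emulating a TPS
    recalculation); gantry and setup errors resample the error-free dose grid
    (emulating a dose edit); output errors rescale it.  ``kind='none'`` is the
    identity.
    """
    if spec.kind not in ERROR_KINDS:
        raise ValueError(f"unknown error kind: {spec.kind!r}")
    engine = engine or DoseEngineParams()
    mag = spec.resolved_magnitude()

    if spec.kind == "none":
        return plan, dose
    if spec.kind in ("mlc_systematic", "mlc_random"):
        plan2 = perturb_plan(plan, spec)
        grid2, _ = compute_dose(plan2, None, engine)
        return plan2, grid2
    if spec.kind in ("output_plus", "output_minus"):
        factor = 1.0 + mag if spec.kind == "output_plus" else 1.0 - mag
        return plan, DoseGrid(dose.values * factor, dose.spacing, dose.half_extent)
    axes = dose.axes()
    if spec.kind in ("gantry_cw", "gantry_ccw"):
        delta = mag if spec.kind == "gantry_cw" else -mag
        vals = _rotate_grid_about_y(dose.values, delta, axes)
    else:
        shift = {"setup_lat": (mag, 0.0, 0.0),
                 "setup_lng": (0.0, mag, 0.0),
                 "setup_vrt": (0.0, 0.0, mag)}[spec.kind]
        vals = _shift_grid(dose.values, shift, axes)
    return plan, DoseGrid(vals, dose.spacing, dose.half_extent)


# ---------------------------------------------------------------------------
# Measurement simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes of the synthetic measurement model.

    measured = true * daily_factor * (1 + correlated_field + iid);
    the returned values are corrected by the (imperfectly) measured daily
    output factor, as on a real measurement day.
    """

    diode_sd: float = 0.007        # iid per-diode, relative
    field_sd: float = 0.005        # spatially correlated, relative
    correlation_length: float = 20.0  # mm
    daily_sd: float = 0.003        # daily output factor
    calibration_sd: float = 0.0005  # error of the daily-factor measurement

    def validate(self) -> None:
        for name in ("diode_sd", "field_sd", "correlation_length",
                     "daily_sd", "calibration_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_measurement(
    planar_pair: Sequence[PlanarDose],
    geometry: DetectorGeometry,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> tuple[PlanarDose, PlanarDose]:
    """Noisy 'measured' planar doses for one delivery, daily-factor corrected.

    The correlated component is an isotropic Gaussian random field per plane
    (white noise on a coarse lattice smoothed to the configured correlation
    length).  Reproducible per seed; with all amplitudes zero the input is
    returned exactly.
    """
    noise = noise or NoiseConfig()
    noise.validate()
    rng = np.random.default_rng(seed)

    daily = 1.0 + noise.daily_sd * rng.standard_normal()
    daily_est = daily * (1.0 + noise.calibration_sd * rng.standard_normal())

    out = []
    ext = geometry.config.half_extent + 30.0
    lattice = np.arange(-ext, ext + 1e-9, 10.0)
    sigma = noise.correlation_length / 10.0
    for k, plane in enumerate(planar_pair):
        white = rng.standard_normal((len(lattice), len(lattice)))
        smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
        sd = smooth.std()
        field = np.zeros(len(plane.values))
        if noise.field_sd > 0 and sd > 0:
            interp = RegularGridInterpolator((lattice, lattice),
                                             smooth / sd, method="linear")
            field = noise.field_sd * interp(geometry.in_plane[k])
        iid = noise.diode_sd * rng.standard_normal(len(plane.values))
        raw = plane.values * daily * (1.0 + field + iid)
        out.append(PlanarDose(plane.plane, raw / daily_est))
    return tuple(out)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class BeamRecord:
    """All simulated data of one beam: calculated doses per condition and the
    single (error-free delivery) measured dose pair."""

    beam_id: int
    split: str
    plan_seed: int
    measurement_seed: int
    #: condition -> per-plane calculated diode doses
    calc: dict[str, tuple[np.ndarray, np.ndarray]]
    #: per-plane measured diode doses
    measured: tuple[np.ndarray, np.ndarray]
    #: condition -> per-plane calculated dose on the in-plane field lattice
    #: (test beams only; consumed by the gamma analysis)
    plane_fields: dict[str, tuple[np.ndarray, np.ndarray]] | None = None


@dataclass
class Dataset:
    """A full synthetic study: beams, conditions, geometry and provenance."""

    seed: int
    split: tuple[int, int, int]
    geometry: DetectorGeometry
    engine: DoseEngineParams
    noise: NoiseConfig
    beams: list[BeamRecord]
    field_axes: np.ndarray | None = None

    def by_split(self, split: str) -> list[BeamRecord]:
        return [b for b in self.beams if b.split == split]

    def manifest(self) -> dict:
        conditions = sorted({c for b in self.beams for c in b.calc})
        return {
            "seed": self.seed,
            "split": list(self.split),
            "n_beams": len(self.beams),
            "conditions": conditions,
            "beams": [
                {
                    "beam_id": b.beam_id,
                    "split": b.split,
                    "plan_seed": b.plan_seed,
                    "measurement_seed": b.measurement_seed,
                    "conditions": sorted(b.calc),
                }
                for b in self.beams
            ],
        }


def _beam_seed(root: int, beam: int, stream: int) -> int:
    """Deterministic per-beam, per-stream 31-bit seed."""
    ss = np.random.SeedSequence([root, beam, stream])
    return int(ss.generate_state(1)[0] % (2**31))


def _plane_field_points(geometry: DetectorGeometry, axes: np.ndarray, k: int) -> np.ndarray:
    pu, py = np.meshgrid(axes, axes, indexing="ij")
    pq = np.column_stack([pu.ravel(), py.ravel()])
    return geometry.to_world(k, pq)


def generate_dataset(
    n_beams: int = 161,
    split: tuple[int, int, int] = (100, 25, 36),
    error_suite: list[ErrorSpec] | None = None,
    seed: int = 0,
    geometry: DetectorGeometry | None = None,
    engine: DoseEngineParams | None = None,
    noise: NoiseConfig | None = None,
    train_errors: bool = True,
    n_control_points: int = 24,
) -> Dataset:
    """Simulate the full study: plans, calculated doses for every condition,
    and one measured (error-free delivery) dose pair per beam.

    ``split`` allocates beams to train/validation/test.  Every test beam
    carries the error-free condition plus the full error suite; train and
    validation beams carry the error conditions too when ``train_errors`` is
    set (they are consumed only by the supervised baseline).  Fully
    reproducible from (config, seed).
    """
    if sum(split) > n_beams:
        raise ValueError(f"split {split} exceeds n_beams={n_beams}")
    geometry = geometry or make_detector_geometry()
    engine = engine or DoseEngineParams()
    noise = noise or NoiseConfig()

    roles = (["train"] * split[0] + ["validation"] * split[1]
             + ["test"] * split[2] + ["unused"] * (n_beams - sum(split)))

    field_axes = engine.grid_axes()
    field_pts = [_plane_field_points(geometry, field_axes, k) for k in range(2)]
    nf = len(field_axes)

    beams: list[BeamRecord] = []
    for i, role in enumerate(roles):
        if role == "unused":
            continue
        plan_seed = _beam_seed(seed, i, 0)
        meas_seed = _beam_seed(seed, i, 1)
        suite = (error_suite if error_suite is not None
                 else default_error_suite(seed=_beam_seed(seed, i, 2)))
        plan = sample_plan(plan_seed, n_control_points=n_control_points,
                           engine=engine)

        calc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        fields: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

        if role == "test":
            grid0, planar0 = compute_dose(plan, geometry, engine)
            calc["none"] = tuple(p.values for p in planar0)
            fields = {"none": tuple(
                grid0.sample(field_pts[k]).reshape(nf, nf) for k in range(2))}
            for spec in suite:
                if spec.kind in ("mlc_systematic", "mlc_random"):
                    plan2, grid2 = inject_error(plan, grid0, spec, engine)
                    calc[spec.kind] = tuple(
                        grid2.sample(geometry.world[k]) for k in range(2))
                    fields[spec.kind] = tuple(
                        grid2.sample(field_pts[k]).reshape(nf, nf)
                        for k in range(2))
                elif spec.kind in ("output_plus", "output_minus"):
                    f = 1.0 + spec.resolved_magnitude() * (
                        1 if spec.kind == "output_plus" else -1)
                    calc[spec.kind] = tuple(v * f for v in calc["none"])
                    fields[spec.kind] = tuple(v * f for v in fields["none"])
                else:
                    _, grid2 = inject_error(plan, grid0, spec, engine)
                    calc[spec.kind] = tuple(
                        grid2.sample(geometry.world[k]) for k in range(2))
                    fields[spec.kind] = tuple(
                        grid2.sample(field_pts[k]).reshape(nf, nf)
                        for k in range(2))
        else:
            calc["none"] = tuple(
                dose_at_points(plan, geometry.world[k], engine)
                for k in range(2))
            if train_errors:
                for spec in suite:
                    if spec.kind in ("mlc_systematic", "mlc_random"):
                        plan2 = perturb_plan(plan, spec)
                        calc[spec.kind] = tuple(
                            dose_at_points(plan2, geometry.world[k], engine)
                            for k in range(2))
                    elif spec.kind in ("output_plus", "output_minus"):
                        f = 1.0 + spec.resolved_magnitude() * (
                            1 if spec.kind == "output_plus" else -1)
                        calc[spec.kind] = tuple(v * f for v in calc["none"])
                    else:
                        calc[spec.kind] = tuple(
                            dose_at_points(
                                plan,
                                error_source_positions(geometry.world[k], spec),
                                engine)
                            for k in range(2))

        planar_pair = [PlanarDose(k, calc["none"][k]) for k in range(2)]
        measured = simulate_measurement(planar_pair, geometry, noise, meas_seed)
        beams.append(BeamRecord(
            beam_id=i, split=role, plan_seed=plan_seed,
            measurement_seed=meas_seed, calc=calc,
            measured=tuple(m.values for m in measured),
            plane_fields=fields,
        ))

    return Dataset(seed=seed, split=split, geometry=geometry, engine=engine,
                   noise=noise, beams=beams, field_axes=field_axes)
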