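"""Gamma-index comparison of measured diode doses against calculated fields.

Global dose-difference / distance-to-agreement analysis on the two detector
planes: for each measured diode the evaluated (calculated) in-plane
distribution is searched over candidate offsets within a radius of 3 x DTA on
a lattice of step DTA/10, and

    gamma = min_r sqrt( (dose_diff(r) / (DD% * D_norm))^2 + (|r| / DTA)^2 ).

D_norm is the global normalization dose (maximum of the calculated
distribution by default).  Diodes below 10 % of the maximum reference dose
are excluded from the pass rate; both planes are pooled.  The module also
provides the phantom-position optimization used as measurement
preprocessing: a translation search maximizing the 3%/1 mm pass rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator

from .simulate import Dataset, DetectorGeometry, DoseGrid

__all__ = [
    "GammaCriteria", "GammaResult",
    "gamma_index", "pass_rate", "classify_gamma",
    "analyze_case", "analyze_dataset",
    "optimize_phantom_position",
]


@dataclass(frozen=True)
class GammaCriteria:
    dd_percent: float
    dta_mm: float
    low_dose_cutoff_fraction: float = 0.1
    #: search lattice step as a fraction of DTA
    search_step_fraction: float = 0.1
    #: search radius as a multiple of DTA
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("DD and DTA criteria must be positive")
        if not (0.0 < self.low_dose_cutoff_fraction < 1.0):
            raise ValueError("low-dose cutoff must be in (0, 1)")

    @property
    def label(self) -> str:
        return f"{self.dd_percent:g}%/{self.dta_mm:g}mm"


@dataclass
class GammaResult:
    """Per-diode gamma values of the evaluated diodes and the pooled pass rate."""

    gammas: np.ndarray
    pass_rate: float
    n_evaluated: int
    criteria: GammaCriteria


def _offsets(criteria: GammaCriteria) -> np.ndarray:
    step = criteria.dta_mm * criteria.search_step_fraction
    radius = criteria.dta_mm * criteria.search_radius_factor
    g = np.arange(-radius, radius + step / 2, step)
    ox, oy = np.meshgrid(g, g, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel()])
    return offs[np.hypot(offs[:, 0], offs[:, 1]) <= radius + 1e-9]


def _bilinear(ax_x: np.ndarray, ax_y: np.ndarray, field: np.ndarray,
              px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Clamped bilinear interpolation of a regular 2D field."""
    ix = np.clip((px - ax_x[0]) / (ax_x[1] - ax_x[0]), 0, len(ax_x) - 1)
    iy = np.clip((py - ax_y[0]) / (ax_y[1] - ax_y[0]), 0, len(ax_y) - 1)
    i0 = np.minimum(ix.astype(np.intp), len(ax_x) - 2)
    j0 = np.minimum(iy.astype(np.intp), len(ax_y) - 2)
    fx, fy = ix - i0, iy - j0
    return (field[i0, j0] * (1 - fx) * (1 - fy)
            + field[i0 + 1, j0] * fx * (1 - fy)
            + field[i0, j0 + 1] * (1 - fx) * fy
            + field[i0 + 1, j0 + 1] * fx * fy)


def gamma_index(
    ref_points: np.ndarray,
    ref_doses: np.ndarray,
    eval_axes: tuple[np.ndarray, np.ndarray],
    eval_field: np.ndarray,
    criteria: GammaCriteria,
    norm_dose: float | None = None,
) -> np.ndarray:
    """Per-reference-point gamma against an interpolable evaluated field.

    ``ref_points`` are (n, 2) in-plane positions with measured ``ref_doses``;
    ``eval_field`` is the calculated distribution on the regular lattice
    ``eval_axes``.  ``norm_dose`` defaults to the maximum of the evaluated
    field (global normalization).
    """
    ref_points = np.asarray(ref_points, dtype=float)
    ref_doses = np.asarray(ref_doses, dtype=float)
    if ref_points.size == 0 or eval_field.size == 0:
        raise ValueError("empty gamma inputs")
    if norm_dose is None:
        norm_dose = float(eval_field.max())
    if norm_dose <= 0:
        raise ValueError("normalization dose must be positive")

    offs = _offsets(criteria)
    dist2 = (np.hypot(offs[:, 0], offs[:, 1]) / criteria.dta_mm) ** 2
    dd_abs = criteria.dd_percent / 100.0 * norm_dose

    px = ref_points[:, 0, None] + offs[None, :, 0]
    py = ref_points[:, 1, None] + offs[None, :, 1]
    vals = _bilinear(eval_axes[0], eval_axes[1], eval_field, px, py)
    g2 = ((vals - ref_doses[:, None]) / dd_abs) ** 2 + dist2[None, :]
    return np.sqrt(g2.min(axis=1))


def pass_rate(gammas: np.ndarray, ref_doses: np.ndarray,
              criteria: GammaCriteria, max_dose: float | None = None) -> float:
    """Percentage of evaluated diodes with gamma <= 1.

    Diodes whose reference dose is below the low-dose cutoff (fraction of
    ``max_dose``, default the maximum reference dose) are excluded.
    """
    gammas = np.asarray(gammas, dtype=float)
    ref_doses = np.asarray(ref_doses, dtype=float)
    if max_dose is None:
        max_dose = float(ref_doses.max())
    keep = ref_doses >= criteria.low_dose_cutoff_fraction * max_dose
    if not np.any(keep):
        raise ValueError("all points fall below the low-dose cutoff")
    return 100.0 * float(np.mean(gammas[keep] <= 1.0))


def classify_gamma(rate: float, threshold: float) -> str:
    """'error-free' if the pass rate exceeds the threshold, else 'any-error'."""
    return "error-free" if rate > threshold else "any-error"


def analyze_case(
    measured: tuple[np.ndarray, np.ndarray],
    plane_fields: tuple[np.ndarray, np.ndarray],
    field_axes: np.ndarray,
    geometry: DetectorGeometry,
    criteria: GammaCriteria,
) -> GammaResult:
    """Pooled two-plane gamma result for one beam case.

    The global normalization dose is the maximum of the calculated
    distribution over both planes; the low-dose cutoff is taken on the
    measured (reference) doses, also pooled.
    """
    norm = max(float(f.max()) for f in plane_fields)
    max_ref = max(float(m.max()) for m in measured)
    cutoff = criteria.low_dose_cutoff_fraction * max_ref

    gammas = []
    doses = []
    for k in range(2):
        keep = measured[k] >= cutoff
        if not np.any(keep):
            continue
        g = gamma_index(
            geometry.in_plane[k][keep], measured[k][keep],
            (field_axes, field_axes), plane_fields[k], criteria, norm)
        gammas.append(g)
        doses.append(measured[k][keep])
    if not gammas:
        raise ValueError("all points fall below the low-dose cutoff")
    gammas = np.concatenate(gammas)
    rate = 100.0 * float(np.mean(gammas <= 1.0))
    return GammaResult(gammas, rate, len(gammas), criteria)


def analyze_dataset(dataset: Dataset,
                    criteria_list: list[GammaCriteria]) -> pd.DataFrame:
    """Gamma pass rates of every test (beam, condition) for each criterion."""
    rows = []
    for beam in dataset.by_split("test"):
        if beam.plane_fields is None:
            raise ValueError(f"test beam {beam.beam_id} has no plane fields")
        for cond, fields in beam.plane_fields.items():
            for crit in criteria_list:
                res = analyze_case(beam.measured, fields, dataset.field_axes,
                                   dataset.geometry, crit)
                rows.append({
                    "beam_id": beam.beam_id, "error": cond,
                    "criteria": crit.label, "n_evaluated": res.n_evaluated,
                    "pass_rate": res.pass_rate,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phantom-position optimization
# ---------------------------------------------------------------------------

def _slab_interpolators(calculated: DoseGrid, geometry: DetectorGeometry,
                        inplane_extent: float, perp_extent: float):
    """Per-plane trilinear interpolators of the calculated dose in
    (p, y, out-of-plane offset) coordinates."""
    interps = []
    ax_in = np.arange(-inplane_extent, inplane_extent + 1e-9, 1.0)
    ax_q = np.arange(-perp_extent, perp_extent + 1e-9, 0.5)
    for k in range(geometry.n_planes):
        e1, e2 = geometry.plane_basis(k)
        nvec = np.cross(e1, e2)
        pp, yy, qq = np.meshgrid(ax_in, ax_in, ax_q, indexing="ij")
        pts = (pp.ravel()[:, None] * e1 + yy.ravel()[:, None] * e2
               + qq.ravel()[:, None] * nvec)
        vals = calculated.sample(pts).reshape(len(ax_in), len(ax_in), len(ax_q))
        interps.append(((ax_in, ax_in, ax_q),
                        RegularGridInterpolator((ax_in, ax_in, ax_q), vals,
                                                bounds_error=False,
                                                fill_value=0.0),
                        (e1, e2, nvec)))
    return interps


def _shift_pass_rate(shift: np.ndarray, interps, geometry: DetectorGeometry,
                     measured, criteria: GammaCriteria, offs: np.ndarray,
                     norm: float, cutoff: float) -> tuple[float, float]:
    """(pass rate, mean gamma) of the shifted phantom against the slab fields."""
    dist2 = (np.hypot(offs[:, 0], offs[:, 1]) / criteria.dta_mm) ** 2
    dd_abs = criteria.dd_percent / 100.0 * norm
    n_pass = 0
    n_tot = 0
    gsum = 0.0
    for k in range(geometry.n_planes):
        _, interp, (e1, e2, nvec) = interps[k]
        keep = measured[k] >= cutoff
        if not np.any(keep):
            continue
        pq = geometry.in_plane[k][keep]
        t_par = np.array([shift @ e1, shift @ e2])
        t_perp = float(shift @ nvec)
        px = pq[:, 0, None] + t_par[0] + offs[None, :, 0]
        py = pq[:, 1, None] + t_par[1] + offs[None, :, 1]
        pts = np.stack([px.ravel(), py.ravel(),
                        np.full(px.size, t_perp)], axis=1)
        vals = interp(pts).reshape(px.shape)
        g2 = ((vals - measured[k][keep, None]) / dd_abs) ** 2 + dist2[None, :]
        gmin = np.sqrt(g2.min(axis=1))
        n_pass += int(np.sum(gmin <= 1.0))
        n_tot += int(np.sum(keep))
        gsum += float(gmin.sum())
    n_tot = max(n_tot, 1)
    return 100.0 * n_pass / n_tot, gsum / n_tot


def optimize_phantom_position(
    measured: tuple[np.ndarray, np.ndarray],
    calculated: DoseGrid,
    geometry: DetectorGeometry,
    search_mm: float = 3.0,
    coarse_step: float = 0.5,
    fine_step: float = 0.1,
    criteria: GammaCriteria | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Translation search maximizing the 3%/1 mm gamma pass rate.

    Returns the best 3D shift (ties broken by the smallest norm) and the
    measured diode values resampled at the in-plane projection of the shift
    (the out-of-plane component cannot be corrected from planar samples).
    """
    criteria = criteria or GammaCriteria(3.0, 1.0)
    interps = _slab_interpolators(
        calculated, geometry,
        inplane_extent=geometry.config.half_extent + search_mm + criteria.dta_mm + 2,
        perp_extent=search_mm + 1.0)

    norm = max(float(i[1].values.max()) for i in interps)
    max_ref = max(float(m.max()) for m in measured)
    cutoff = criteria.low_dose_cutoff_fraction * max_ref

    # pass/fail only needs offsets within one DTA
    step = criteria.dta_mm * 0.25
    g = np.arange(-criteria.dta_mm, criteria.dta_mm + step / 2, step)
    ox, oy = np.meshgrid(g, g, indexing="ij")
    offs_coarse = np.column_stack([ox.ravel(), oy.ravel()])
    offs_coarse = offs_coarse[
        np.hypot(offs_coarse[:, 0], offs_coarse[:, 1]) <= criteria.dta_mm + 1e-9]

    def search(center: np.ndarray, half: float, step_mm: float,
               offs: np.ndarray) -> np.ndarray:
        # maximize pass rate; ties broken by lower mean gamma, then by the
        # smallest shift norm
        if half <= 0:
            return center
        ax = np.arange(-half, half + step_mm / 2, step_mm)
        best_key, best_shift = None, center
        for dx in ax:
            for dy in ax:
                for dz in ax:
                    shift = center + np.array([dx, dy, dz])
                    rate, mean_g = _shift_pass_rate(
                        shift, interps, geometry, measured, criteria, offs,
                        norm, cutoff)
                    key = (round(rate, 6), round(-mean_g, 9),
                           round(-float(np.linalg.norm(shift)), 9))
                    if best_key is None or key > best_key:
                        best_key, best_shift = key, shift
        return best_shift

    if search_mm <= 0:
        best = np.zeros(3)
    else:
        best = search(np.zeros(3), search_mm, coarse_step, offs_coarse)
        step_f = criteria.dta_mm * 0.1
        gf = np.arange(-criteria.dta_mm, criteria.dta_mm + step_f / 2, step_f)
        ox, oy = np.meshgrid(gf, gf, indexing="ij")
        offs_fine = np.column_stack([ox.ravel(), oy.ravel()])
        offs_fine = offs_fine[
            np.hypot(offs_fine[:, 0], offs_fine[:, 1]) <= criteria.dta_mm + 1e-9]
        # coarse quantization puts the optimum within half a coarse step
        best = search(best, 0.3, fine_step, offs_fine)

    corrected = []
    for k in range(geometry.n_planes):
        e1, e2 = geometry.plane_basis(k)
        t_par = np.array([best @ e1, best @ e2])
        coords = geometry.in_plane[k]
        interp = LinearNDInterpolator(coords, measured[k])
        vals = interp(coords - t_par)
        nan = np.isnan(vals)
        vals[nan] = measured[k][nan]
        corrected.append(vals)
    return best, tuple(corrected)
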