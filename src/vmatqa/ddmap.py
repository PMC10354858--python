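"""Dose-difference (DD) maps on the detector planes.

A DD map is the per-diode difference (measured - calculated), both first
normalized by the measured isocenter dose, placed on the uniform 5 mm plane
lattice.  Lattice nodes not covered by a diode (the 10 mm peripheral region)
are filled by piecewise-linear interpolation from neighbouring diodes; nodes
coincident with a diode keep the exact diode difference.  The central
13 x 13 cm area (27 x 27 nodes) is extracted and clipped to +-0.2; the
resulting matrix is the unit of analysis for every detection method here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .simulate import Dataset, DetectorGeometry

__all__ = [
    "MAP_SIZE",
    "MAP_PITCH",
    "CLIP_LIMIT",
    "DDMap",
    "BeamCase",
    "normalize_by_isocenter",
    "measured_isocenter_dose",
    "build_dd_map",
    "augment_flips",
    "beam_case_maps",
    "assemble_vae_datasets",
]

MAP_SIZE = 27
MAP_PITCH = 5.0   # mm
CLIP_LIMIT = 0.2


@dataclass
class DDMap:
    """27x27 clipped fractional dose-difference matrix.

    Rows follow the in-plane transverse axis p (increasing), columns the
    longitudinal axis y (increasing); ``plane_id`` is 1 or 2.
    """

    values: np.ndarray
    plane_id: int
    beam_id: int = -1
    error: str = "none"

    def validate(self) -> None:
        if self.values.shape != (MAP_SIZE, MAP_SIZE):
            raise ValueError(f"DD map must be {MAP_SIZE}x{MAP_SIZE}")
        if np.any(np.abs(self.values) > CLIP_LIMIT + 1e-12):
            raise ValueError(f"DD map values outside +-{CLIP_LIMIT}")


@dataclass
class BeamCase:
    """One beam x one dose condition: the pair of plane maps plus its label."""

    beam_id: int
    error: str
    maps: tuple[DDMap, DDMap]
    split: str = "test"

    def __post_init__(self) -> None:
        if len(self.maps) != 2 or self.maps[0].plane_id == self.maps[1].plane_id:
            raise ValueError("a beam case needs one map per detector plane")


def lattice_axis() -> np.ndarray:
    half = (MAP_SIZE - 1) / 2 * MAP_PITCH
    return np.arange(MAP_SIZE) * MAP_PITCH - half


# Per-geometry interpolation structure: for every lattice node either the
# index of the coincident diode or barycentric weights over a Delaunay
# simplex of the scattered diode set (nearest diode outside the hull).
_interp_cache: dict[int, tuple[DetectorGeometry, list]] = {}


def _node_weights(geometry: DetectorGeometry, k: int):
    cached = _interp_cache.get(id(geometry))
    if cached is not None and cached[0] is geometry:
        return cached[1][k]

    structs = []
    ax = lattice_axis()
    pu, py = np.meshgrid(ax, ax, indexing="ij")
    nodes = np.column_stack([pu.ravel(), py.ravel()])
    for plane in range(geometry.n_planes):
        coords = geometry.in_plane[plane]
        tree = cKDTree(coords)
        dist, nearest = tree.query(nodes)
        tri = Delaunay(coords)
        simplex = tri.find_simplex(nodes)

        idx = np.zeros((len(nodes), 3), dtype=np.intp)
        w = np.zeros((len(nodes), 3))
        exact = dist < 1e-9
        outside = (simplex < 0) & ~exact
        interior = ~exact & ~outside

        if np.any(interior):
            s = simplex[interior]
            verts = tri.simplices[s]
            trans = tri.transform[s]
            delta = nodes[interior] - trans[:, 2]
            bary = np.einsum("nij,nj->ni", trans[:, :2], delta)
            full = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
            idx[interior] = verts
            w[interior] = full
        idx[exact, 0] = nearest[exact]
        w[exact, 0] = 1.0
        idx[outside, 0] = nearest[outside]
        w[outside, 0] = 1.0
        structs.append((idx, w))

    _interp_cache[id(geometry)] = (geometry, structs)
    return structs[k]


def normalize_by_isocenter(values: np.ndarray, isocenter_dose: float) -> np.ndarray:
    """Divide planar dose values by the measured isocenter dose."""
    if isocenter_dose <= 0:
        raise ValueError("isocenter dose must be positive")
    return np.asarray(values, dtype=float) / isocenter_dose


def measured_isocenter_dose(measured_plane1: np.ndarray,
                            geometry: DetectorGeometry) -> float:
    """Measured dose at the in-plane origin of plane 1 (a central diode)."""
    coords = geometry.in_plane[0]
    i = int(np.argmin(np.hypot(coords[:, 0], coords[:, 1])))
    return float(measured_plane1[i])


def build_dd_map(
    measured: np.ndarray,
    calculated: np.ndarray,
    geometry: DetectorGeometry,
    plane: int,
    beam_id: int = -1,
    error: str = "none",
) -> DDMap:
    """DD map of one plane from *normalized* measured/calculated diode doses.

    The per-diode difference (measured - calculated) is placed on the 5 mm
    lattice; uncovered nodes are linearly interpolated, diode-covered nodes
    keep the exact difference, and the result is clipped to +-0.2 last.
    """
    measured = np.asarray(measured, dtype=float)
    calculated = np.asarray(calculated, dtype=float)
    if measured.shape != calculated.shape:
        raise ValueError("measured/calculated shape mismatch (plane mismatch?)")
    if measured.shape[0] != geometry.in_plane[plane].shape[0]:
        raise ValueError("planar dose does not match the requested plane")

    diff = measured - calculated
    idx, w = _node_weights(geometry, plane)
    node_vals = (diff[idx] * w).sum(axis=1)
    values = node_vals.reshape(MAP_SIZE, MAP_SIZE)
    values = np.clip(values, -CLIP_LIMIT, CLIP_LIMIT)
    return DDMap(values, plane_id=plane + 1, beam_id=beam_id, error=error)


def augment_flips(ddmap: DDMap) -> list[DDMap]:
    """Original, horizontal flip, vertical flip and both (4-fold expansion)."""
    ddmap.validate()
    variants = [
        ddmap.values,
        ddmap.values[:, ::-1],
        ddmap.values[::-1, :],
        ddmap.values[::-1, ::-1],
    ]
    return [DDMap(v.copy(), ddmap.plane_id, ddmap.beam_id, ddmap.error)
            for v in variants]


def beam_case_maps(dataset: Dataset, splits: tuple[str, ...] = ("train", "validation", "test"),
                   conditions: tuple[str, ...] | None = None) -> list[BeamCase]:
    """Build DD-map beam cases for every requested (beam, condition).

    Both doses of a pair are normalized by the same measured plane-1
    isocenter dose of that beam.
    """
    geometry = dataset.geometry
    cases: list[BeamCase] = []
    for beam in dataset.beams:
        if beam.split not in splits:
            continue
        iso = measured_isocenter_dose(beam.measured[0], geometry)
        m_norm = [normalize_by_isocenter(beam.measured[k], iso) for k in range(2)]
        conds = conditions if conditions is not None else tuple(beam.calc)
        for cond in conds:
            if cond not in beam.calc:
                raise KeyError(
                    f"beam {beam.beam_id} is missing condition {cond!r}")
            maps = tuple(
                build_dd_map(
                    m_norm[k],
                    normalize_by_isocenter(beam.calc[cond][k], iso),
                    geometry, k, beam_id=beam.beam_id, error=cond,
                )
                for k in range(2)
            )
            cases.append(BeamCase(beam.beam_id, cond, maps, split=beam.split))
    return cases


def assemble_vae_datasets(dataset: Dataset, augment: bool = True):
    """(train maps, validation maps, test cases) for the unsupervised model.

    Train and validation use only error-free maps; with the default
    100/25/36 split this yields 200 training maps (800 after the 4-fold flip
    augmentation), 50 validation maps and 360 test cases of 2 maps each.
    """
    train_cases = beam_case_maps(dataset, splits=("train",), conditions=("none",))
    val_cases = beam_case_maps(dataset, splits=("validation",), conditions=("none",))
    test_cases = beam_case_maps(dataset, splits=("test",))

    def stack(cases, do_augment):
        maps = []
        for case in cases:
            for m in case.maps:
                if do_augment:
                    maps.extend(v.values for v in augment_flips(m))
                else:
                    maps.append(m.values)
        if not maps:
            raise ValueError("no maps found for the requested split")
        return np.stack(maps)

    return stack(train_cases, augment), stack(val_cases, False), test_cases
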