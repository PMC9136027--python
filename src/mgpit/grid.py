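"""Voxel specimen grid for hexahedral-element corrosion simulation.

The specimen is a regular grid of cubic elements of edge ``a`` (mm).  Each
element carries three pieces of state:

* a material label — intact magnesium, surface oxide, or void (corroded
  away / never material),
* an oxide attribute ``OA`` in [0, 1], the relative corrosion-speed factor
  (1 for bare Mg, ~0.07 for the passivating oxide film),
* an exposure attribute ``EA`` in {0..6}, the number of the element's six
  faces in contact with saline.  A face touches saline when the neighbour
  across it is void or lies outside the grid bounding box (the specimen is
  fully immersed, so the exterior is saline on all sides).

Exposure uses strict 6-face adjacency: diagonal contact does not expose a
face.  ``EA`` of a void element is kept at 0 and is meaningless; every
consumer filters on the material state.

Index convention: 0-based ``(i, j, k)`` with the element centre at
``((i + 0.5) a, (j + 0.5) a, (k + 0.5) a)``; ``z`` (axis ``k``) is the
specimen thickness axis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

# Material state labels (also the on-disk codes of the voxel text dump).
VOID = 0
INTACT_MG = 1
OXIDE = 2

STATE_NAMES = {VOID: "VOID", INTACT_MG: "INTACT_MG", OXIDE: "OXIDE"}

_AXIS_NAMES = ("length", "width", "thickness")


class ElementCoord(NamedTuple):
    """0-based element index triple ``(i, j, k)``."""

    i: int
    j: int
    k: int


@dataclass
class SpecimenGrid:
    """The voxel specimen: per-element state, OA, EA plus geometry constants.

    Attributes
    ----------
    a : float
        Element edge length in mm.
    density : float
        Material density in mg/mm^3.
    state, oa, ea : ndarray, shape (nx, ny, nz)
        Material label, oxide attribute and exposure attribute per element.
    initial_state : ndarray
        Material labels at build time; needed to tell corroded-away
        elements from never-material ones when quantifying pits.
    """

    a: float
    density: float
    state: np.ndarray
    oa: np.ndarray
    ea: np.ndarray
    initial_state: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.state.shape

    @property
    def nx(self) -> int:
        return self.state.shape[0]

    @property
    def ny(self) -> int:
        return self.state.shape[1]

    @property
    def nz(self) -> int:
        return self.state.shape[2]

    @property
    def n(self) -> int:
        """Total element count ``nx * ny * nz``."""
        return self.state.size

    @property
    def solid_mask(self) -> np.ndarray:
        return self.state != VOID

    @property
    def removed_mask(self) -> np.ndarray:
        """Elements that were material at build time and are void now."""
        return (self.initial_state != VOID) & (self.state == VOID)

    @property
    def element_mass(self) -> float:
        """Mass of a single element ``Me = a^3 * density`` in mg."""
        return self.a**3 * self.density

    @property
    def initial_surface_area(self) -> float:
        """Exposed surface area of the as-built specimen in mm^2."""
        return self._initial_surface_area

    @property
    def initial_mass(self) -> float:
        """Total mass of the as-built specimen in mg."""
        return int(np.count_nonzero(self.initial_state != VOID)) * self.element_mass

    def copy(self) -> "SpecimenGrid":
        g = SpecimenGrid(
            a=self.a,
            density=self.density,
            state=self.state.copy(),
            oa=self.oa.copy(),
            ea=self.ea.copy(),
            initial_state=self.initial_state.copy(),
        )
        g._initial_surface_area = self._initial_surface_area
        return g

    def checksum(self) -> str:
        """SHA-256 over the material and OA arrays (reproducibility audits)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.state).tobytes())
        h.update(np.ascontiguousarray(self.oa).tobytes())
        return h.hexdigest()

    # filled in by build_specimen / read_voxel_txt
    _initial_surface_area: float = field(default=0.0, repr=False)


def _element_count(dimension: float, element_size: float, axis: str) -> int:
    ratio = dimension / element_size
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"{axis} = {dimension} mm is not an integer multiple of the "
            f"element size {element_size} mm"
        )
    return int(n)


def build_specimen(
    length: float,
    width: float,
    thickness: float,
    element_size: float,
    density: float,
) -> SpecimenGrid:
    """Build a fresh intact specimen of ``length x width x thickness`` mm.

    Every dimension must be an integer multiple of ``element_size`` (exact
    divisors matter for mesh-refinement studies, so near-misses are an
    error, not silently rounded).  All elements start as intact Mg with
    ``OA = 1``; ``EA`` is the standard intact-block pattern (interior 0,
    faces 1, edges 2, corners 3).
    """
    if element_size <= 0:
        raise ValueError("element_size must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    nx = _element_count(length, element_size, "length")
    ny = _element_count(width, element_size, "width")
    nz = _element_count(thickness, element_size, "thickness")
    shape = (nx, ny, nz)
    state = np.full(shape, INTACT_MG, dtype=np.uint8)
    grid = SpecimenGrid(
        a=float(element_size),
        density=float(density),
        state=state,
        oa=np.ones(shape, dtype=np.float64),
        ea=np.zeros(shape, dtype=np.int16),
        initial_state=state.copy(),
    )
    compute_exposure(grid)
    grid._initial_surface_area = exposed_surface_area(grid)
    return grid


def compute_exposure(grid: SpecimenGrid) -> np.ndarray:
    """Recompute ``EA`` for every element from scratch.

    ``EA_i`` = number of the six face-neighbours that are void or outside
    the grid.  Idempotent; void elements get ``EA = 0``.
    """
    solid = grid.solid_mask
    p = np.pad(solid, 1, constant_values=False)
    neighbours = (
        p[2:, 1:-1, 1:-1].astype(np.int16)
        + p[:-2, 1:-1, 1:-1]
        + p[1:-1, 2:, 1:-1]
        + p[1:-1, :-2, 1:-1]
        + p[1:-1, 1:-1, 2:]
        + p[1:-1, 1:-1, :-2]
    )
    ea = (6 - neighbours).astype(np.int16)
    ea[~solid] = 0
    grid.ea = ea
    return ea


def _coerce_coords(removed: Iterable, shape: tuple[int, int, int]) -> np.ndarray:
    arr = np.asarray(sorted(removed) if isinstance(removed, set) else list(removed), dtype=np.intp)
    if arr.size == 0:
        return arr.reshape(0, 3)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError("removal coordinates must be (i, j, k) triples")
    for axis in range(3):
        bad = (arr[:, axis] < 0) | (arr[:, axis] >= shape[axis])
        if bad.any():
            raise ValueError(f"coordinate {tuple(arr[np.argmax(bad)])} outside grid {shape}")
    return arr


def apply_removals(grid: SpecimenGrid, removed: Iterable) -> SpecimenGrid:
    """Turn the given elements into void and update EA incrementally.

    Each removed element must currently be material with ``EA > 0`` —
    interior elements are shielded from saline and cannot corrode; trying
    to remove one signals a selection bug upstream.  Surviving
    face-neighbours of removed elements gain +1 EA per newly-voided face;
    the result is identical to a full :func:`compute_exposure`.
    """
    coords = _coerce_coords(removed, grid.shape)
    if coords.shape[0] == 0:
        return grid
    idx = (coords[:, 0], coords[:, 1], coords[:, 2])
    states = grid.state[idx]
    if (states == VOID).any():
        bad = coords[np.argmax(states == VOID)]
        raise ValueError(f"element {tuple(bad)} is already void")
    eas = grid.ea[idx]
    if (eas == 0).any():
        bad = coords[np.argmax(eas == 0)]
        raise ValueError(
            f"element {tuple(bad)} has EA = 0 (not in contact with saline) "
            "and cannot be corroded"
        )
    mask = np.zeros(grid.shape, dtype=bool)
    mask[idx] = True
    # +1 EA to each surviving face-neighbour per adjacent newly-voided element
    inc = np.zeros(grid.shape, dtype=np.int16)
    inc[:-1, :, :] += mask[1:, :, :]
    inc[1:, :, :] += mask[:-1, :, :]
    inc[:, :-1, :] += mask[:, 1:, :]
    inc[:, 1:, :] += mask[:, :-1, :]
    inc[:, :, :-1] += mask[:, :, 1:]
    inc[:, :, 1:] += mask[:, :, :-1]
    grid.state[mask] = VOID
    grid.oa[mask] = 0.0
    survivors = grid.state != VOID
    grid.ea[survivors & (inc > 0)] += inc[survivors & (inc > 0)]
    grid.ea[mask] = 0
    return grid


def exposed_surface_area(grid: SpecimenGrid) -> float:
    """Total saline-exposed surface ``S = (sum of EA over material) * a^2`` in mm^2."""
    return float(grid.ea[grid.solid_mask].sum(dtype=np.int64)) * grid.a**2


def element_mass(grid: SpecimenGrid) -> float:
    """Mass of one element ``Me = a^3 * density`` (mg)."""
    return grid.element_mass


def total_mass(grid: SpecimenGrid) -> float:
    """Remaining specimen mass ``M_N`` = (material element count) * Me (mg)."""
    return int(np.count_nonzero(grid.solid_mask)) * grid.element_mass
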