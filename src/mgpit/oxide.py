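"""Oxide surface layer and porous pit-initiation spots.

A freshly machined Mg-alloy specimen is covered by a thin passivating
oxide film that corrodes roughly an order of magnitude slower than the
bare alloy; pitting nucleates at locally defective ("porous") spots in
that film.  This module paints the one-element-thick oxide shell
(``OA = 0.07`` by default, against ``OA = 1`` for intact Mg) and places
the porous spots.

Real specimens get their spot locations from an early-exposure pit map
measured by micro-CT; :func:`generate_seed_map` is a synthetic stand-in
that scatters ``n_seeds`` spots uniformly over the surface with OA drawn
uniformly from [0.4, 0.6].  Measured maps can be supplied instead through
:func:`load_seed_map` (CSV ``i,j,k,oa`` or a binary image stack whose void
pixels mark the spots).

Newly exposed interior elements are never re-oxidised during a run: the
model has no repassivation, which is what lets pits accelerate once they
break through the shell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import INTACT_MG, OXIDE, VOID, ElementCoord, SpecimenGrid

FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class OxideConfig:
    """Parameters of the oxide shell and its porous seeding.

    ``oxide_oa`` is the relative corrosion speed of the film (default
    0.07 against 1.0 for intact Mg); porous spots draw their OA uniformly
    from ``[porous_oa_low, porous_oa_high]`` (default [0.4, 0.6]).
    ``n_seeds`` spots are placed on the faces named in ``seed_faces``;
    ``patch_radius > 0`` expands each seed to a square surface patch of
    Chebyshev radius ``patch_radius`` sharing the seed's OA (off by
    default — single-element spots).
    """

    oxide_oa: float = 0.07
    intact_oa: float = 1.0
    porous_oa_low: float = 0.4
    porous_oa_high: float = 0.6
    n_seeds: int = 30
    seed_faces: Sequence[str] = FACES
    patch_radius: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.oxide_oa <= self.porous_oa_low <= self.porous_oa_high
                <= self.intact_oa <= 1.0):
            raise ValueError(
                "OA ordering violated: need 0 < oxide_oa <= porous_oa_low "
                "<= porous_oa_high <= intact_oa <= 1"
            )
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")
        unknown = set(self.seed_faces) - set(FACES)
        if unknown:
            raise ValueError(f"unknown seed faces: {sorted(unknown)}")


@dataclass
class PorousSeedMap:
    """Surface coordinates with assigned OA values (the pit initiators)."""

    entries: list[tuple[ElementCoord, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def coords(self) -> np.ndarray:
        if not self.entries:
            return np.empty((0, 3), dtype=np.intp)
        return np.array([c for c, _ in self.entries], dtype=np.intp)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries], dtype=np.float64)


def assign_oxide_layer(grid: SpecimenGrid, config: OxideConfig,
                       allow_corroded: bool = False) -> SpecimenGrid:
    """Convert the exposed shell to oxide.

    Every element with ``EA > 0`` becomes OXIDE with ``OA = oxide_oa``;
    everything else stays intact Mg with ``OA = intact_oa``.  The shell is
    exactly one element thick.  By default the grid must be freshly built
    (no voids); pass ``allow_corroded=True`` to deliberately re-oxidise a
    corroded specimen.
    """
    if not allow_corroded and (grid.state == VOID).any():
        raise ValueError(
            "grid already contains void elements; pass allow_corroded=True "
            "to re-oxidise a corroded specimen"
        )
    shell = (grid.ea > 0) & (grid.state != VOID)
    interior = (grid.ea == 0) & (grid.state != VOID)
    grid.state[shell] = OXIDE
    grid.oa[shell] = config.oxide_oa
    grid.state[interior] = INTACT_MG
    grid.oa[interior] = config.intact_oa
    grid.initial_state = grid.state.copy()
    return grid


def _face_mask(grid: SpecimenGrid, faces: Sequence[str]) -> np.ndarray:
    nx, ny, nz = grid.shape
    m = np.zeros(grid.shape, dtype=bool)
    if "x-" in faces:
        m[0, :, :] = True
    if "x+" in faces:
        m[nx - 1, :, :] = True
    if "y-" in faces:
        m[:, 0, :] = True
    if "y+" in faces:
        m[:, ny - 1, :] = True
    if "z-" in faces:
        m[:, :, 0] = True
    if "z+" in faces:
        m[:, :, nz - 1] = True
    return m


def generate_seed_map(grid: SpecimenGrid, config: OxideConfig,
                      rng_seed) -> PorousSeedMap:
    """Draw a synthetic porous-spot map.

    ``n_seeds`` distinct surface elements are chosen uniformly without
    replacement from the eligible faces; each gets an OA drawn uniformly
    from ``[porous_oa_low, porous_oa_high]``.  Fully reproducible from
    ``rng_seed`` (an int or a ``numpy.random.Generator``).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    eligible = (grid.ea > 0) & (grid.state != VOID) & _face_mask(grid, config.seed_faces)
    coords = np.argwhere(eligible)
    if config.n_seeds > coords.shape[0]:
        raise ValueError(
            f"n_seeds = {config.n_seeds} exceeds the {coords.shape[0]} "
            "eligible surface elements"
        )
    if config.n_seeds == 0:
        return PorousSeedMap()
    pick = rng.choice(coords.shape[0], size=config.n_seeds, replace=False)
    values = rng.uniform(config.porous_oa_low, config.porous_oa_high,
                         size=config.n_seeds)
    entries: dict[ElementCoord, float] = {}
    for (i, j, k), v in zip(coords[pick], values):
        entries[ElementCoord(int(i), int(j), int(k))] = float(v)
        if config.patch_radius > 0:
            for c in _patch_neighbours(grid, eligible, int(i), int(j), int(k),
                                       config.patch_radius):
                entries.setdefault(c, float(v))
    return PorousSeedMap(list(entries.items()))


def _patch_neighbours(grid, eligible, i, j, k, radius):
    """Surface elements within Chebyshev `radius` of the seed (same shell)."""
    nx, ny, nz = grid.shape
    out = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            for dk in range(-radius, radius + 1):
                ii, jj, kk = i + di, j + dj, k + dk
                if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz \
                        and eligible[ii, jj, kk]:
                    out.append(ElementCoord(ii, jj, kk))
    return out


def apply_seed_map(grid: SpecimenGrid, seed_map: PorousSeedMap) -> SpecimenGrid:
    """Overwrite OA of the listed oxide-surface elements; states unchanged."""
    for coord, value in seed_map.entries:
        i, j, k = coord
        if grid.state[i, j, k] != OXIDE:
            raise ValueError(
                f"seed coordinate {tuple(coord)} is not on the oxide surface"
            )
        grid.oa[i, j, k] = value
    return grid


def save_seed_map(seed_map: PorousSeedMap, path: str) -> None:
    """Write the CSV dialect ``i,j,k,oa`` (header included)."""
    with open(path, "w") as fh:
        fh.write("i,j,k,oa\n")
        for (i, j, k), v in seed_map.entries:
            fh.write(f"{i},{j},{k},{v!r}\n")


def load_seed_map(path: str, grid: SpecimenGrid,
                  config: OxideConfig | None = None) -> PorousSeedMap:
    """Read a porous-spot map from CSV or a binary image stack.

    CSV rows are ``i,j,k,oa``.  A directory (or list of PNG paths) is read
    as a per-layer image stack whose void pixels mark spots; image-derived
    entries get the midpoint of ``[porous_oa_low, porous_oa_high]``.
    Every entry must lie on the current exposed surface and have OA in
    [0, 1]; violations are rejected with the offending line/coordinate.
    """
    config = config or OxideConfig()
    if isinstance(path, (list, tuple)) or os.path.isdir(path):
        return _seed_map_from_stack(path, grid, config)
    entries: list[tuple[ElementCoord, float]] = []
    seen: set[ElementCoord] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (lineno == 1 and line.lower().startswith("i,")):
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'i,j,k,oa', got {line!r}")
            try:
                coord = ElementCoord(int(parts[0]), int(parts[1]), int(parts[2]))
                value = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            _validate_entry(grid, coord, value, f"{path}:{lineno}")
            if coord in seen:
                raise ValueError(f"{path}:{lineno}: duplicate coordinate {tuple(coord)}")
            seen.add(coord)
            entries.append((coord, value))
    return PorousSeedMap(entries)


def _validate_entry(grid: SpecimenGrid, coord: ElementCoord, value: float,
                    where: str) -> None:
    i, j, k = coord
    nx, ny, nz = grid.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise ValueError(f"{where}: coordinate {tuple(coord)} outside grid {grid.shape}")
    if grid.state[i, j, k] == VOID or grid.ea[i, j, k] == 0:
        raise ValueError(f"{where}: coordinate {tuple(coord)} is not on the exposed surface")
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{where}: OA value {value} outside [0, 1]")


def _seed_map_from_stack(path, grid: SpecimenGrid, config: OxideConfig) -> PorousSeedMap:
    from .io_formats import read_section_stack

    material = read_section_stack(path)
    if material.shape != grid.shape:
        raise ValueError(
            f"stack shape {material.shape} does not match grid {grid.shape}"
        )
    midpoint = 0.5 * (config.porous_oa_low + config.porous_oa_high)
    spots = (~material) & (grid.state != VOID) & (grid.ea > 0)
    entries = [
        (ElementCoord(int(i), int(j), int(k)), midpoint)
        for i, j, k in np.argwhere(spots)
    ]
    return PorousSeedMap(entries)
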