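"""Interchange formats: STL surfaces, FE hexahedral decks, voxel dumps, stacks.

Dialects:

* **STL** — all saline-exposed boundary faces of the voxel volume, each
  quad split into two triangles with outward normals; binary by default
  (ASCII on request).  Voxel-faithful: no smoothing or marching cubes.
* **.inp** — a minimal generic FE input deck: ``*NODE`` table (mm),
  8-node brick ``*ELEMENT`` table, and one ``*ELSET`` per material state.
  Nodes shared between elements are deduplicated exactly via their
  integer lattice keys.  Brick connectivity is the standard
  counter-clockwise bottom face (viewed from +z) followed by the top
  face::

        8-------7          n1 = (i,   j,   k)    n5 = n1 + z
       /|      /|          n2 = (i+1, j,   k)    n6 = n2 + z
      5-------6 |          n3 = (i+1, j+1, k)    n7 = n3 + z
      | 4-----|-3          n4 = (i,   j+1, k)    n8 = n4 + z
      |/      |/
      1-------2

* **voxel txt** — header lines ``nx ny nz``, ``a_mm``,
  ``density_mg_mm3``, then one line per element ``i j k state OA``
  (state 0=VOID, 1=INTACT_MG, 2=OXIDE); round-trips exactly.
* **section stack** — one 8-bit PNG per k-layer, 0 = void,
  255 = material, rows = j (y), columns = i (x); the interchange format
  for micro-CT-derived binary segmentations.
* **history CSV** — one step record per row.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .grid import (
    INTACT_MG,
    OXIDE,
    VOID,
    SpecimenGrid,
    compute_exposure,
    exposed_surface_area,
)

# ---------------------------------------------------------------------------
# Boundary faces / STL

# For each face direction: (axis, side) with the 4 quad-corner offsets in
# outward-winding order (right-hand rule gives the outward normal).
_FACE_CORNERS = {
    ("x", +1): ((1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)),
    ("x", -1): ((0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)),
    ("y", +1): ((0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)),
    ("y", -1): ((0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)),
    ("z", +1): ((0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)),
    ("z", -1): ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)),
}
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def boundary_faces(grid: SpecimenGrid) -> list[tuple[np.ndarray, tuple]]:
    """Exposed (material|saline) faces, grouped by direction.

    Returns a list of ``(coords, direction)`` pairs where ``coords`` is an
    ``(m, 3)`` array of the owning material voxels and ``direction`` is an
    ``(axis, side)`` key of ``_FACE_CORNERS``.
    """
    solid = grid.solid_mask
    p = np.pad(solid, 1, constant_values=False)
    out = []
    shifts = {
        ("x", +1): p[2:, 1:-1, 1:-1], ("x", -1): p[:-2, 1:-1, 1:-1],
        ("y", +1): p[1:-1, 2:, 1:-1], ("y", -1): p[1:-1, :-2, 1:-1],
        ("z", +1): p[1:-1, 1:-1, 2:], ("z", -1): p[1:-1, 1:-1, :-2],
    }
    for direction, neighbour in shifts.items():
        exposed = solid & ~neighbour
        coords = np.argwhere(exposed)
        if coords.shape[0]:
            out.append((coords, direction))
    return out


def _face_triangles(grid: SpecimenGrid) -> np.ndarray:
    """(2 * n_faces, 3, 3) float array of triangle vertices in mm."""
    tris = []
    for coords, direction in boundary_faces(grid):
        corners = np.asarray(_FACE_CORNERS[direction], dtype=float)  # (4, 3)
        quads = (coords[:, None, :] + corners[None, :, :]) * grid.a  # (m, 4, 3)
        tris.append(quads[:, (0, 1, 2), :])
        tris.append(quads[:, (0, 2, 3), :])
    if not tris:
        return np.empty((0, 3, 3))
    return np.concatenate(tris, axis=0)


def write_stl(grid: SpecimenGrid, path: str, ascii: bool = False) -> int:
    """Write the exposed boundary surface as STL; returns the triangle count.

    Triangle count is exactly twice the exposed face count and the total
    STL area equals :func:`~mgpit.grid.exposed_surface_area`.
    """
    import trimesh

    if not grid.solid_mask.any():
        raise ValueError("cannot export an empty grid to STL")
    tris = _face_triangles(grid)
    n = tris.shape[0]
    vertices = tris.reshape(-1, 3)
    faces = np.arange(3 * n).reshape(-1, 3)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(path, file_type="stl_ascii" if ascii else "stl")
    return n


# ---------------------------------------------------------------------------
# FE .inp deck

_STATE_SETNAME = {INTACT_MG: "INTACT_MG", OXIDE: "OXIDE"}


def _hex_connectivity(grid: SpecimenGrid):
    """Deduplicated nodes + brick connectivity of all material elements."""
    coords = np.argwhere(grid.solid_mask)
    if coords.shape[0] == 0:
        raise ValueError("cannot export an empty grid")
    offsets = np.array([
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ], dtype=np.intp)
    corners = coords[:, None, :] + offsets[None, :, :]          # (m, 8, 3)
    flat = corners.reshape(-1, 3)
    # integer lattice keys: exact dedup, no float tolerance
    ny1, nz1 = grid.ny + 1, grid.nz + 1
    keys = (flat[:, 0] * ny1 + flat[:, 1]) * nz1 + flat[:, 2]
    unique_keys, inverse = np.unique(keys, return_inverse=True)
    k = unique_keys % nz1
    j = (unique_keys // nz1) % ny1
    i = unique_keys // (nz1 * ny1)
    nodes = np.stack([i, j, k], axis=1).astype(float) * grid.a   # (n_nodes, 3)
    connectivity = inverse.reshape(-1, 8)                        # 0-based
    return coords, nodes, connectivity


def write_inp(grid: SpecimenGrid, path: str) -> tuple[int, int]:
    """Write a minimal FE hexahedral input deck; returns (node count, element count)."""
    coords, nodes, connectivity = _hex_connectivity(grid)
    states = grid.state[coords[:, 0], coords[:, 1], coords[:, 2]]
    with open(path, "w") as fh:
        fh.write("*HEADING\nmgpit voxel specimen export\n")
        fh.write("*NODE\n")
        for idx, (x, y, z) in enumerate(nodes, start=1):
            fh.write(f"{idx}, {x:.6f}, {y:.6f}, {z:.6f}\n")
        fh.write("*ELEMENT, TYPE=C3D8\n")
        for idx, conn in enumerate(connectivity, start=1):
            fh.write(f"{idx}, " + ", ".join(str(c + 1) for c in conn) + "\n")
        for state, name in _STATE_SETNAME.items():
            members = np.nonzero(states == state)[0] + 1
            if members.size == 0:
                continue
            fh.write(f"*ELSET, ELSET={name}\n")
            for start in range(0, members.size, 16):
                fh.write(", ".join(map(str, members[start:start + 16])) + "\n")
    return nodes.shape[0], connectivity.shape[0]


def read_inp(path: str) -> dict:
    """Parse a deck written by :func:`write_inp`.

    Returns ``{"nodes": (n, 3) mm, "elements": (m, 8) 0-based,
    "elsets": {name: 0-based element indices}}``.
    """
    nodes, elements = [], []
    elsets: dict[str, list[int]] = {}
    section = None
    current_set = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("*"):
                upper = line.upper()
                if upper.startswith("*NODE"):
                    section = "node"
                elif upper.startswith("*ELEMENT"):
                    section = "element"
                elif upper.startswith("*ELSET"):
                    section = "elset"
                    m = re.search(r"ELSET=(\w+)", upper)
                    current_set = m.group(1) if m else "UNNAMED"
                    elsets[current_set] = []
                else:
                    section = None
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if section == "node":
                nodes.append([float(v) for v in parts[1:4]])
            elif section == "element":
                elements.append([int(v) - 1 for v in parts[1:9]])
            elif section == "elset":
                elsets[current_set].extend(int(v) - 1 for v in parts)
    return {
        "nodes": np.asarray(nodes, dtype=float),
        "elements": np.asarray(elements, dtype=np.intp),
        "elsets": {k: np.asarray(v, dtype=np.intp) for k, v in elsets.items()},
    }


# ---------------------------------------------------------------------------
# Voxel text dump

def write_voxel_txt(grid: SpecimenGrid, path: str) -> None:
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny} {nz}\n")
        fh.write(f"{grid.a!r}\n")
        fh.write(f"{grid.density!r}\n")
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    fh.write(f"{i} {j} {k} {int(grid.state[i, j, k])} "
                             f"{float(grid.oa[i, j, k])!r}\n")


def read_voxel_txt(path: str) -> SpecimenGrid:
    """Rebuild a grid from the text dump; EA is recomputed.

    The dump stores only the current (state, OA); the reconstructed grid's
    ``initial_state`` is taken as the current material mask, so pit
    quantification on a re-loaded grid needs the original grid (or the
    original dump) for the removed-voxel reference.
    """
    with open(path) as fh:
        try:
            nx, ny, nz = (int(v) for v in fh.readline().split())
            a = float(fh.readline())
            density = float(fh.readline())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed header: {exc}") from None
        state = np.zeros((nx, ny, nz), dtype=np.uint8)
        oa = np.zeros((nx, ny, nz), dtype=np.float64)
        count = 0
        for lineno, raw in enumerate(fh, start=4):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 'i j k state OA'")
            i, j, k, st = int(parts[0]), int(parts[1]), int(parts[2]), int(parts[3])
            if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                raise ValueError(f"{path}:{lineno}: coordinate out of range")
            if st not in (VOID, INTACT_MG, OXIDE):
                raise ValueError(f"{path}:{lineno}: unknown state code {st}")
            state[i, j, k] = st
            oa[i, j, k] = float(parts[4])
            count += 1
    if count != nx * ny * nz:
        raise ValueError(f"{path}: expected {nx * ny * nz} element lines, got {count}")
    grid = SpecimenGrid(
        a=a, density=density, state=state, oa=oa,
        ea=np.zeros((nx, ny, nz), dtype=np.int16),
        initial_state=state.copy(),
    )
    compute_exposure(grid)
    grid._initial_surface_area = exposed_surface_area(grid)
    return grid


# ---------------------------------------------------------------------------
# History CSV

def write_history_csv(history, path: str) -> None:
    history.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Binary section stacks (PNG per layer)

def write_section_stack(grid: SpecimenGrid, directory: str,
                        prefix: str = "layer") -> list[str]:
    """One 8-bit PNG per k-layer (0 = void, 255 = material); returns the paths."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    paths = []
    for k in range(grid.nz):
        img = np.where(grid.state[:, :, k].T != VOID, 255, 0).astype(np.uint8)
        p = os.path.join(directory, f"{prefix}_{k:04d}.png")
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def read_section_stack(path) -> np.ndarray:
    """Read a per-layer PNG stack back into an (nx, ny, nz) boolean material array."""
    import imageio.v3 as iio

    if isinstance(path, (list, tuple)):
        files = list(path)
    else:
        files = sorted(
            os.path.join(path, f) for f in os.listdir(path)
            if f.lower().endswith((".png", ".tif", ".tiff"))
        )
    if not files:
        raise ValueError(f"no image layers found in {path}")
    layers = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[..., 0]
        layers.append(img.T >= 128)
    shapes = {l.shape for l in layers}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent layer shapes in stack: {sorted(shapes)}")
    return np.stack(layers, axis=2)
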