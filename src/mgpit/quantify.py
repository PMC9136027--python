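"""Corrosion morphometrics: pits, depths, sections, projected areas, fits.

This mirrors the image-processing pipeline used to quantify micro-CT
scans of corroding specimens, applied to the simulated voxel volume (or
any binary volume):

* pits are 26-connected components of *removed* material (voxels that
  were material at the start and are void now),
* pit depth is the inclusive z-extent ``(k_max - k_min + 1) * a`` of a
  pit's voxels, so a single-voxel pit has depth ``a`` rather than 0;
  depth is measured along the thickness axis only,
* cross-sections are binary rasters of single element layers; the
  ``z``-planes are measured inward from the top face (``z = 0`` is the
  outermost as-built layer, index ``k = nz - 1``),
* the 2D pit mask of a section is obtained with Canny edge detection
  followed by contour closing and region filling — on clean sections the
  result provably equals the direct void mask, which is the regression
  oracle for the shipped defaults,
* the mass-loss curve is fitted by a line through the origin
  ``MLPA = c * T`` and the maximum-depth curve by the saturating
  exponential ``D(T) = A * (1 - exp(-k T))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import canny

from .grid import SpecimenGrid, VOID


# ---------------------------------------------------------------------------
# 3D pit labeling and depth

@dataclass
class PitLabeling:
    """Connected-component labeling of removed material (0 = not a pit)."""

    labels: np.ndarray
    count: int

    def voxels(self, pit: int) -> np.ndarray:
        """(m, 3) voxel coordinates of the given pit label (1-based)."""
        return np.argwhere(self.labels == pit)


@dataclass
class PitMetrics:
    """Global morphometrics of a corroded specimen."""

    pit_count: int
    depths: np.ndarray          # per-pit depth, mm
    max_depth: float            # D_m, mm
    plane_areas: dict           # z (mm) -> (A_C mm^2, A_C / A_O)
    plane_pit_counts: dict      # z (mm) -> 2D pit count


@dataclass
class CrossSection:
    """One element layer as a binary raster (True = material)."""

    axis: str
    position: float            # mm along the axis convention of extract_cross_section
    layer_index: int
    material: np.ndarray
    pixel_size: float


@dataclass
class FitResult:
    model: str
    params: dict
    residual_rms: float


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def label_pits(grid: SpecimenGrid, connectivity: int = 26) -> PitLabeling:
    """Label pits: connected components of removed (corroded-away) voxels.

    Default 26-connectivity (corner contact joins pits, matching their
    visual contiguity in sections); 6-connectivity is available for
    sensitivity checks.  Labels are assigned in raster-scan order of each
    component's first voxel, so the labeling is deterministic.
    """
    if connectivity == 26:
        structure = _STRUCT_26
    elif connectivity == 6:
        structure = _STRUCT_6
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, count = ndimage.label(grid.removed_mask, structure=structure)
    return PitLabeling(labels=labels, count=int(count))


def max_pit_depth(labeling: PitLabeling, grid: SpecimenGrid) -> tuple[np.ndarray, float]:
    """Per-pit depths and the global maximum ``D_m`` (mm).

    Depth is the inclusive z-extent of the pit's voxels,
    ``(k_max - k_min + 1) * a``.  Returns ``(depths, D_m)``; ``D_m = 0``
    with an empty depth array when there are no pits.
    """
    if labeling.count == 0:
        return np.empty(0), 0.0
    depths = np.empty(labeling.count)
    for idx, sl in enumerate(ndimage.find_objects(labeling.labels)):
        depths[idx] = (sl[2].stop - sl[2].start) * grid.a
    return depths, float(depths.max())


# ---------------------------------------------------------------------------
# Cross-sections

def z_plane_to_layer(grid: SpecimenGrid, z: float) -> int:
    """Map a z-plane depth (mm, measured inward from the top face) to a layer index.

    ``z = 0`` is the outermost as-built layer ``k = nz - 1``; successive
    planes step one element inward (0.125 mm apart at the default
    discretisation).
    """
    ratio = z / grid.a
    layer = round(ratio)
    if abs(ratio - layer) > 1e-9 or not (0 <= layer < grid.nz):
        raise ValueError(
            f"z = {z} mm does not map to an element layer; valid planes are "
            f"multiples of {grid.a} in [0, {(grid.nz - 1) * grid.a}]"
        )
    return grid.nz - 1 - int(layer)


def extract_cross_section(grid: SpecimenGrid, axis: str, position: float) -> CrossSection:
    """Binary material/void raster of one element layer.

    ``axis`` is 'x', 'y' or 'z' (position in mm).  For 'x'/'y' the
    position is measured from the specimen origin, half-open
    ``position / a in [0, n_axis)``; for 'z' it is the inward plane depth
    of :func:`z_plane_to_layer`.
    """
    if axis == "z":
        layer = z_plane_to_layer(grid, position)
        material = grid.state[:, :, layer] != VOID
    elif axis in ("x", "y"):
        n_axis = grid.nx if axis == "x" else grid.ny
        layer = int(position / grid.a)
        if not (0 <= layer < n_axis) or position < 0:
            raise ValueError(
                f"{axis} = {position} mm outside [0, {n_axis * grid.a}) mm"
            )
        if axis == "x":
            material = grid.state[layer, :, :] != VOID
        else:
            material = grid.state[:, layer, :] != VOID
    else:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    return CrossSection(axis=axis, position=float(position), layer_index=layer,
                        material=material.copy(), pixel_size=grid.a)


# ---------------------------------------------------------------------------
# 2D pit detection (Canny + fill)

def detect_pits_2d(section: CrossSection, sigma: float = 1.0,
                   upsample: int = 4) -> tuple[np.ndarray, int]:
    """Canny edge detection + contour filling on a section raster.

    The raster is upsampled (nearest-neighbour, factor ``upsample``) and
    framed with one upsampled ring of material so every pit boundary —
    including pits touching the raster edge — produces a closed gradient
    contour; Canny (Gaussian ``sigma`` in upsampled pixels, automatic
    hysteresis thresholds) marks the edges, a 3x3 binary closing seals
    single-pixel gaps, the enclosed regions are filled, and the filled
    mask is intersected with the void pixels and downsampled back.  On a
    clean (noise-free) raster the mask equals the direct void mask.

    Returns ``(pit_mask, count)`` where ``count`` is the number of
    8-connected components of the mask.
    """
    if section.material.size == 0:
        raise ValueError("empty section raster")
    u = int(upsample)
    mat = section.material
    big = np.kron(mat, np.ones((u, u), dtype=bool))
    framed = np.pad(big, u, constant_values=True)
    edges = canny(framed.astype(float), sigma=sigma)
    closed = ndimage.binary_closing(edges, structure=np.ones((3, 3), bool))
    filled = ndimage.binary_fill_holes(closed)
    mask_big = filled[u:-u, u:-u] & ~big
    # void blocks are uniform at the upsampled scale, so any() == all()
    mask = mask_big.reshape(mat.shape[0], u, mat.shape[1], u).any(axis=(1, 3))
    _, count = ndimage.label(mask, structure=np.ones((3, 3), bool))
    return mask, int(count)


def projected_corrosion_area(grid: SpecimenGrid, z: float) -> tuple[float, float]:
    """Projected corroded area ``A_C`` on a z-plane and its fraction of ``A_O``.

    ``A_C`` counts pixels of the layer that were material initially and
    are void now, times ``a^2``; ``A_O = nx * ny * a^2`` (225 mm^2 for the
    default 15 x 15 mm specimen).
    """
    layer = z_plane_to_layer(grid, z)
    removed = grid.removed_mask[:, :, layer]
    a_c = int(removed.sum()) * grid.a**2
    a_o = grid.nx * grid.ny * grid.a**2
    return a_c, a_c / a_o


def pit_metrics(grid: SpecimenGrid,
                planes: tuple[float, ...] = (0.0, 0.125, 0.25)) -> PitMetrics:
    """One-call morphometrics: 3D pits, D_m, and per-plane A_C and counts."""
    labeling = label_pits(grid)
    depths, d_m = max_pit_depth(labeling, grid)
    plane_areas = {}
    plane_counts = {}
    for z in planes:
        plane_areas[z] = projected_corrosion_area(grid, z)
        section = extract_cross_section(grid, "z", z)
        _, count = detect_pits_2d(section)
        plane_counts[z] = count
    return PitMetrics(
        pit_count=labeling.count,
        depths=depths,
        max_depth=d_m,
        plane_areas=plane_areas,
        plane_pit_counts=plane_counts,
    )


# ---------------------------------------------------------------------------
# Curve fits

def fit_mlpa_slope(history_or_times, mlpa: Optional[np.ndarray] = None) -> FitResult:
    """Least-squares line through the origin, ``MLPA = c * T``.

    Accepts a :class:`~mgpit.engine.CorrosionHistory` or explicit
    ``(times, mlpa)`` arrays.  The closed-form slope is
    ``sum(T * y) / sum(T^2)``.
    """
    if mlpa is None:
        times = history_or_times.times()
        mlpa = history_or_times.mlpa()
    else:
        times = np.asarray(history_or_times, dtype=float)
        mlpa = np.asarray(mlpa, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    slope = float(np.dot(times, mlpa) / np.dot(times, times))
    residuals = mlpa - slope * times
    return FitResult(
        model="mlpa_linear_origin",
        params={"slope": slope},
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
    )


def fit_depth_exponential(times, depths) -> FitResult:
    """Fit the saturating depth curve ``D(T) = A * (1 - exp(-k T))``.

    Nonlinear least squares with positivity bounds.  Initialisation:
    ``A0 = max(depth)``; ``k0 = ln 2 / t_half`` from the first time the
    depth reaches half its maximum (fallback ``1 / t_max``).  Degenerate
    inputs (constant or all-zero depths) are rejected with a diagnostic
    rather than silently returning a bogus fit.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(depths) == 0.0 or depths.max() <= 0.0:
        raise ValueError(
            "degenerate depth series (constant or non-positive); "
            "an exponential saturation fit is not identifiable"
        )
    a0 = depths.max()
    half_idx = np.argmax(depths >= 0.5 * a0)
    t_half = times[half_idx]
    k0 = np.log(2.0) / t_half if t_half > 0 else 1.0 / times.max()

    def model(t, a, k):
        return a * (1.0 - np.exp(-k * t))

    try:
        popt, _ = curve_fit(
            model, times, depths, p0=(a0, k0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            maxfev=10000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"exponential depth fit did not converge: {exc}") from exc
    residuals = depths - model(times, *popt)
    return FitResult(
        model="depth_exponential_saturation",
        params={"amplitude": float(popt[0]), "rate": float(popt[1])},
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
    )
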