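"""Density grids: map I/O, cropping, model rasterization and correlation.

A density grid is a regular isotropic-voxel 3D scalar field with an origin
in Å.  Real electron-microscopy maps are read/written in MRC/CCP4 2014
format (via gemmi); a plain-text dialect is provided so test fixtures stay
human-readable.

Rasterization places an isotropic Gaussian on each atom (amplitude ∝ atomic
mass) or sphere (amplitude ∝ volume) with σ chosen so that the Gaussian
FWHM equals the nominal map resolution: σ = resolution / (2·sqrt(2·ln 2)).
The fit of a model to a map segment is the Pearson cross-correlation over
voxels of the model's rasterization against the segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures import AtomicStructure

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class DensityGrid:
    """Regular 3D scalar field with isotropic voxels.

    ``values`` is indexed [ix, iy, iz]; voxel (i,j,k) is centered at
    ``origin + voxel_size * (i, j, k)``.
    """

    origin: np.ndarray
    voxel_size: float
    values: np.ndarray
    resolution: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_size * np.arange(self.values.shape[axis])

    def same_geometry(self, other: "DensityGrid", tol: float = 1e-6) -> bool:
        return (self.dims == other.dims
                and abs(self.voxel_size - other.voxel_size) <= tol
                and np.allclose(self.origin, other.origin, atol=tol))

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.voxel_size,
                           self.values.copy(), self.resolution)


# ------------------------------------------------------------------------ I/O

_TEXT_MAGIC = "# oligomodel density grid v1"


def write_map(g: DensityGrid, path: str | Path) -> None:
    """Write a grid: ``.txt``/``.grid`` → text dialect, else MRC/CCP4."""
    path = Path(path)
    if path.suffix.lower() in {".txt", ".grid"}:
        _write_text_grid(g, path)
    else:
        _write_mrc(g, path)


def read_map(path: str | Path) -> DensityGrid:
    """Read an MRC/CCP4 map or the text-grid dialect (axis order x,y,z)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with open(path, "rb") as fh:
        head = fh.read(len(_TEXT_MAGIC))
    if head == _TEXT_MAGIC.encode():
        return _read_text_grid(path)
    return _read_mrc(path)


def _write_text_grid(g: DensityGrid, path: Path) -> None:
    nx, ny, nz = g.dims
    with open(path, "w") as fh:
        fh.write(_TEXT_MAGIC + "\n")
        fh.write(f"dims {nx} {ny} {nz}\n")
        fh.write(f"origin {g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}\n")
        fh.write(f"voxel {g.voxel_size:.6f}\n")
        fh.write(f"resolution {g.resolution:.6f}\n")
        flat = g.values.ravel(order="C")
        for i in range(0, len(flat), 8):
            fh.write(" ".join(f"{v:.8g}" for v in flat[i:i + 8]) + "\n")


def _read_text_grid(path: Path) -> DensityGrid:
    with open(path) as fh:
        lines = fh.read().split("\n")
    if lines[0] != _TEXT_MAGIC:
        raise IOError(f"{path}: not a text grid")
    dims = tuple(int(x) for x in lines[1].split()[1:4])
    origin = np.array([float(x) for x in lines[2].split()[1:4]])
    voxel = float(lines[3].split()[1])
    resolution = float(lines[4].split()[1])
    values = np.array(" ".join(lines[5:]).split(), dtype=float)
    if values.size != np.prod(dims):
        raise IOError(f"{path}: expected {np.prod(dims)} voxels, got {values.size}")
    return DensityGrid(origin, voxel, values.reshape(dims, order="C"), resolution)


def _write_mrc(g: DensityGrid, path: Path) -> None:
    import gemmi

    ccp4 = gemmi.Ccp4Map()
    # gemmi FloatGrid is indexed (u,v,w) fastest-varying first in file order;
    # feed values with x fastest by transposing to (z,y,x) C-order
    grid = gemmi.FloatGrid(np.ascontiguousarray(g.values.astype(np.float32)))
    nx, ny, nz = g.dims
    grid.set_unit_cell(gemmi.UnitCell(nx * g.voxel_size, ny * g.voxel_size,
                                      nz * g.voxel_size, 90, 90, 90))
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    # encode the Å origin (ORIGIN words of the 2014 format)
    ccp4.set_header_float(50, float(g.origin[0]))
    ccp4.set_header_float(51, float(g.origin[1]))
    ccp4.set_header_float(52, float(g.origin[2]))
    ccp4.write_ccp4_map(str(path))


def _read_mrc(path: Path) -> DensityGrid:
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    arr = np.array(ccp4.grid, copy=True, dtype=float)
    cell = ccp4.grid.unit_cell
    nx = ccp4.grid.nu
    voxel = cell.a / nx
    origin = np.array([ccp4.header_float(50), ccp4.header_float(51),
                       ccp4.header_float(52)])
    return DensityGrid(origin, voxel, arr)


# ------------------------------------------------------------------- cropping

def crop_segment(g: DensityGrid, center: np.ndarray,
                 extent: np.ndarray) -> DensityGrid:
    """Axis-aligned sub-grid of half-width ``extent/2`` around ``center`` (Å)."""
    center = np.asarray(center, dtype=float)
    extent = np.asarray(extent, dtype=float)
    lo_idx = np.floor((center - extent / 2 - g.origin) / g.voxel_size).astype(int)
    hi_idx = np.ceil((center + extent / 2 - g.origin) / g.voxel_size).astype(int) + 1
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(g.dims))
    if np.any(hi_idx <= lo_idx):
        raise ValueError("requested crop does not intersect the grid")
    vals = g.values[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
    return DensityGrid(g.origin + lo_idx * g.voxel_size, g.voxel_size,
                       vals.copy(), g.resolution)


# -------------------------------------------------------------- rasterization

def _gaussian_splat(grid_template: DensityGrid, centers: np.ndarray,
                    amplitudes: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of normalized isotropic Gaussians evaluated on the template grid.

    Separable evaluation: per center, the 3D Gaussian is an outer product of
    three 1D Gaussians, accumulated with einsum.
    """
    xs = grid_template.axis_coords(0)
    ys = grid_template.axis_coords(1)
    zs = grid_template.axis_coords(2)
    out = np.zeros(grid_template.dims)
    norm = 1.0 / ((2 * math.pi) ** 1.5 * sigma ** 3)
    inv2s2 = 1.0 / (2 * sigma * sigma)
    for c, amp in zip(centers, amplitudes):
        gx = np.exp(-((xs - c[0]) ** 2) * inv2s2)
        gy = np.exp(-((ys - c[1]) ** 2) * inv2s2)
        gz = np.exp(-((zs - c[2]) ** 2) * inv2s2)
        out += (amp * norm) * np.einsum("i,j,k->ijk", gx, gy, gz)
    return out


def rasterize(model, template: DensityGrid, resolution: float) -> DensityGrid:
    """Simulate a density map of a model on the template's geometry.

    ``model`` may be an :class:`AtomicStructure` (amplitude ∝ atomic mass) or
    a sphere model with ``centers``/``radius`` (amplitude ∝ sphere volume).
    σ = resolution / (2·sqrt(2 ln 2)) so FWHM equals the nominal resolution.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if any(d == 0 for d in template.dims):
        raise ValueError("template grid has zero extent")
    sigma = resolution / FWHM_TO_SIGMA
    if isinstance(model, AtomicStructure):
        centers = model.coords
        amplitudes = model.masses()
    else:
        centers = np.asarray(model.centers, dtype=float).reshape(-1, 3)
        amplitudes = np.full(len(centers),
                             4.0 / 3.0 * math.pi * float(model.radius) ** 3)
    vals = _gaussian_splat(template, centers, amplitudes, sigma)
    return DensityGrid(template.origin.copy(), template.voxel_size, vals,
                       resolution)


def template_for(coords: np.ndarray, voxel_size: float,
                 padding: float) -> DensityGrid:
    """An empty grid covering ``coords`` with ``padding`` Å on every side."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 2)
    return DensityGrid(lo, voxel_size, np.zeros(dims))


def lowpass_filter(g: DensityGrid, resolution: float | None = None) -> DensityGrid:
    """Gaussian low-pass filter of a map at its nominal resolution.

    Matched filtering for correlation against simulated densities: voxel
    noise is white at the voxel scale while the structural signal lives at
    the resolution scale, so a Gaussian of σ = resolution/(2·sqrt(2 ln 2))
    suppresses the noise with little signal loss.
    """
    from scipy.ndimage import gaussian_filter

    res = resolution if resolution is not None else g.resolution
    if res <= 0:
        raise ValueError("resolution must be > 0 to filter")
    sigma_vox = res / FWHM_TO_SIGMA / g.voxel_size
    out = g.copy()
    out.values = gaussian_filter(g.values, sigma_vox, mode="constant")
    return out


# ---------------------------------------------------------------- correlation

def cross_correlation(a: DensityGrid, b: DensityGrid) -> float:
    """Pearson correlation of two grids over voxels (mean-subtracted)."""
    if not a.same_geometry(b):
        raise ValueError("grids have different geometry")
    x = a.values.ravel()
    y = b.values.ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("cross-correlation undefined for a constant grid")
    return float(np.dot(xc, yc) / (nx * ny))
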