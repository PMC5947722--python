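"""Detector images: mode filtering, geometric corrections, Ewald mapping,
rotation-series integration onto the reciprocal grid, reindexing, and image
simulation from 3D maps.

Geometry model: flat detector at normal incidence, beam along lab +z,
detector plane at z = distance; pixel (row i, column j) sits at
x = (j - cx) * pixel, y = (i - cy) * pixel in mm.  The crystal setting
matrix A maps fractional hkl to the laboratory scattering vector (A^-1);
a goniometer rotation about a stated lab axis is applied on top per image:
s_lab = R(phi) A hkl.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.transform import Rotation

from .diffuse import DiffuseMap, apply_index_op
from .lattice import Lattice, ReciprocalGrid

__all__ = [
    "DetectorGeometry",
    "OrientationSetting",
    "DetectorImage",
    "rotation_series",
    "geometry_factors",
    "mode_filter",
    "correct_geometry",
    "pixel_to_hkl",
    "hkl_to_pixel",
    "integrate",
    "reindex_map",
    "simulate_image",
]


@dataclass(frozen=True)
class DetectorGeometry:
    distance_mm: float
    pixel_mm: float
    wavelength: float               # A
    shape: tuple[int, int]          # (ny, nx) pixels
    beam_center: tuple[float, float]  # (cy, cx) fractional pixels
    polarization_fraction: float = 0.5
    polarization_azimuth_deg: float = 0.0
    saturation: int = 65535

    def __post_init__(self) -> None:
        if min(self.distance_mm, self.pixel_mm, self.wavelength) <= 0:
            raise ValueError("distance, pixel size and wavelength must be positive")
        cy, cx = self.beam_center
        ny, nx = self.shape
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise ValueError("beam center must lie inside the image")
        if not 0 <= self.polarization_fraction <= 1:
            raise ValueError("polarization fraction must lie in [0, 1]")

    def pixel_lab_coords(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """(..., 3) lab positions (mm) of pixel centres."""
        cy, cx = self.beam_center
        x = (np.asarray(j, dtype=float) - cx) * self.pixel_mm
        y = (np.asarray(i, dtype=float) - cy) * self.pixel_mm
        z = np.full_like(x, self.distance_mm)
        return np.stack([x, y, z], axis=-1)


@dataclass(frozen=True)
class OrientationSetting:
    """Crystal setting matrix plus per-image goniometer rotation."""

    matrix: np.ndarray              # 3x3, hkl -> lab scattering vector (A^-1)
    angle_deg: float = 0.0
    axis: str = "x"                 # lab rotation axis

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(M)) < 1e-15:
            raise ValueError("setting matrix must be invertible")
        object.__setattr__(self, "matrix", M)
        if self.axis not in ("x", "y", "z"):
            raise ValueError("goniometer axis must be one of 'x', 'y', 'z'")

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler(self.axis, self.angle_deg, degrees=True).as_matrix()

    @property
    def full_matrix(self) -> np.ndarray:
        """R(phi) @ A, the effective hkl -> lab mapping of this image."""
        return self.rotation @ self.matrix


def rotation_series(
    lattice: Lattice, angles_deg, axis: str = "x"
) -> list[OrientationSetting]:
    """Goniometer settings for a rotation series.

    The zero-angle setting matrix maps *physical* (unit-cell, possibly
    fractional) Miller indices to the lab scattering vector, so for a
    supercell lattice the underlying unit cell's reciprocal metric is used.
    """
    A = lattice.unit_cell().reciprocal_matrix
    return [OrientationSetting(matrix=A, angle_deg=float(a), axis=axis) for a in angles_deg]


@dataclass
class DetectorImage:
    pixels: np.ndarray              # (ny, nx) counts (ADU), float in memory
    mask: np.ndarray | None = None  # True = bad/overloaded/beamstop
    geometry: DetectorGeometry | None = None
    orientation: OrientationSetting | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel counts must be finite")
        if self.mask is None:
            self.mask = np.zeros(self.pixels.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must match the image")

    def as_uint16(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 65535).astype(np.uint16)


# -- mode filter -----------------------------------------------------------


def mode_filter(img: DetectorImage, kernel: int = 15, bin_width: float = 1.0) -> DetectorImage:
    """Replace each pixel by the most populated bin of its neighborhood.

    Values are binned in ``bin_width``-ADU bins; each unmasked pixel becomes
    the representative (lower edge) of the most populated bin among the
    unmasked values in its kernel x kernel neighborhood.  Borders use the
    truncated neighborhood; a pixel whose neighborhood is entirely masked is
    masked in the output.  Ties go to the lowest-valued bin, biasing toward
    background -- the point of the filter is to reject sharp Bragg outliers
    while passing the smooth diffuse signal.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd pixel count >= 3")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    vals = np.floor(img.pixels / bin_width)
    vals = np.where(img.mask, np.nan, vals).astype(np.float32)
    half = kernel // 2
    padded = np.pad(vals, half, mode="constant", constant_values=np.nan)
    ny, nx = vals.shape
    out = np.empty((ny, nx), dtype=float)
    out_masked = np.zeros((ny, nx), dtype=bool)
    # process in row strips to bound the (rows, nx, kernel^2) window memory
    strip = max(1, int(2e7 // (nx * kernel * kernel)))
    for r0 in range(0, ny, strip):
        r1 = min(r0 + strip, ny)
        win = sliding_window_view(padded[r0 : r1 + 2 * half], (kernel, kernel))
        flat = win.reshape(r1 - r0, nx, kernel * kernel)
        sw = np.sort(flat, axis=-1)  # NaNs sort to the end
        mode_bin, any_valid = _mode_of_sorted(sw)
        out[r0:r1] = mode_bin * bin_width
        out_masked[r0:r1] = ~any_valid
    out[out_masked] = 0.0
    return DetectorImage(
        pixels=out,
        mask=out_masked,
        geometry=img.geometry,
        orientation=img.orientation,
        meta={**img.meta, "mode_filter": {"kernel": kernel, "bin_width": bin_width}},
    )


def _mode_of_sorted(sw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Most frequent value along the last axis of a sorted array (NaNs last).

    Ties resolve to the smallest value (runs are in ascending order and the
    first maximal run wins).  Returns (mode values, any-valid mask).
    """
    m = sw.shape[-1]
    valid = ~np.isnan(sw)
    # run starts: position 0 or value change (NaN comparisons are change-like)
    with np.errstate(invalid="ignore"):
        change = np.empty(sw.shape, dtype=bool)
        change[..., 0] = True
        change[..., 1:] = sw[..., 1:] != sw[..., :-1]
    pos = np.arange(m)
    starts = np.maximum.accumulate(np.where(change, pos, 0), axis=-1)
    is_end = np.empty(sw.shape, dtype=bool)
    is_end[..., :-1] = change[..., 1:]
    is_end[..., -1] = True
    lengths = np.where(is_end & valid, pos - starts + 1, 0)
    best = np.argmax(lengths, axis=-1)
    mode = np.take_along_axis(sw, best[..., None], axis=-1)[..., 0]
    return mode, valid[..., 0]


# -- geometric corrections -------------------------------------------------


def geometry_factors(geom: DetectorGeometry) -> np.ndarray:
    """Per-pixel polarization x solid-angle factor, 1 at the beam center.

    P = xi (1 - sin^2 2theta cos^2(phi - phi0))
        + (1 - xi) (1 - sin^2 2theta sin^2(phi - phi0))
    reduces to the unpolarized (1 + cos^2 2theta)/2 at xi = 1/2.  The
    relative solid angle of a flat detector pixel is cos^3 of the obliquity
    angle (equal to 2theta at normal incidence).
    """
    ny, nx = geom.shape
    d = geom.pixel_lab_coords(*np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij"))
    r = np.linalg.norm(d, axis=-1)
    cos2t = d[..., 2] / r
    sin2t_sq = 1.0 - cos2t**2
    phi = np.arctan2(d[..., 1], d[..., 0]) - np.deg2rad(geom.polarization_azimuth_deg)
    xi = geom.polarization_fraction
    P = xi * (1.0 - sin2t_sq * np.cos(phi) ** 2) + (1.0 - xi) * (
        1.0 - sin2t_sq * np.sin(phi) ** 2
    )
    omega = cos2t**3
    return P * omega


def correct_geometry(img: DetectorImage) -> DetectorImage:
    """Divide out polarization and solid angle in one floating-point pass."""
    if img.geometry is None:
        raise ValueError("image carries no detector geometry")
    factors = geometry_factors(img.geometry)
    out = img.pixels / factors
    out[img.mask] = 0.0
    return DetectorImage(
        pixels=out,
        mask=img.mask.copy(),
        geometry=img.geometry,
        orientation=img.orientation,
        meta={**img.meta, "geometry_corrected": True},
    )


# -- Ewald-sphere mapping --------------------------------------------------


def pixel_to_hkl(
    pixels_ij: np.ndarray, geom: DetectorGeometry, setting: OrientationSetting
) -> np.ndarray:
    """Fractional Miller indices of pixel coordinates (..., 2) = (i, j)."""
    pix = np.asarray(pixels_ij, dtype=float)
    d = geom.pixel_lab_coords(pix[..., 0], pix[..., 1])
    k_out = d / np.linalg.norm(d, axis=-1, keepdims=True) / geom.wavelength
    s_lab = k_out - np.array([0.0, 0.0, 1.0 / geom.wavelength])
    Minv = np.linalg.inv(setting.full_matrix)
    return s_lab @ Minv.T


def hkl_to_pixel(
    hkl: np.ndarray, geom: DetectorGeometry, setting: OrientationSetting
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward Ewald projection of (..., 3) hkl.

    Returns (pixel (i, j), Ewald offset lambda*|k_out| - 1, visibility).
    A reflection is geometrically visible when its diffracted ray points
    toward the detector half-space and lands inside the raster.
    """
    s_lab = np.asarray(hkl, dtype=float) @ setting.full_matrix.T
    k_out = s_lab + np.array([0.0, 0.0, 1.0 / geom.wavelength])
    offset = geom.wavelength * np.linalg.norm(k_out, axis=-1) - 1.0
    kz = k_out[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = k_out[..., :2] * (geom.distance_mm / kz)[..., None]
    cy, cx = geom.beam_center
    j = xy[..., 0] / geom.pixel_mm + cx
    i = xy[..., 1] / geom.pixel_mm + cy
    ny, nx = geom.shape
    visible = (kz > 0) & (i >= 0) & (i <= ny - 1) & (j >= 0) & (j <= nx - 1)
    return np.stack([i, j], axis=-1), offset, visible


# -- integration and simulation --------------------------------------------


def integrate(
    images, grid: ReciprocalGrid, d_min: float | None = None
) -> tuple[DiffuseMap, np.ndarray]:
    """Merge a rotation series onto the grid by nearest-grid-point assignment.

    Each unmasked pixel is mapped to its fractional hkl and accumulated at
    the nearest integer supercell index (round half up); per-point
    count-weighted means and contributing-pixel counts are returned.
    """
    d_min = d_min if d_min is not None else grid.d_min
    sampling = np.asarray(grid.sampling, dtype=float)
    bounds = np.asarray(grid.bounds)
    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape, dtype=int)
    smax = 1.0 / d_min
    B = grid.lattice.reciprocal_matrix
    for img in images:
        if img.geometry is None or img.orientation is None:
            raise ValueError("each image needs geometry and orientation")
        ny, nx = img.pixels.shape
        ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        ij = np.stack([ii[~img.mask], jj[~img.mask]], axis=-1)
        vals = img.pixels[~img.mask]
        hkl = pixel_to_hkl(ij, img.geometry, img.orientation)
        idx = np.floor(hkl * sampling + 0.5).astype(int)  # half rounds up
        inb = np.all(np.abs(idx) <= bounds, axis=-1)
        idx, vals = idx[inb], vals[inb]
        s = np.linalg.norm(idx @ B.T, axis=-1)
        keep = s <= smax + 1e-12
        idx, vals = idx[keep], vals[keep]
        off = grid.to_dense_offset(idx)
        np.add.at(sums, off, vals)
        np.add.at(counts, off, 1)
    if counts.sum() == 0:
        raise ValueError("no pixel maps onto the grid within the resolution cutoff")
    measured = counts > 0
    values = np.divide(sums, counts, out=np.zeros_like(sums), where=measured)
    dmap = DiffuseMap(
        grid=grid, values=values, measured=measured, provenance="observed"
    )
    return dmap, counts


_REINDEX_OPS = {
    "identity": np.diag([1, 1, 1]),
    "2h": np.diag([1, -1, -1]),   # 180 deg about h: (h,k,l) -> (h,-k,-l)
    "2k": np.diag([-1, 1, -1]),
    "2l": np.diag([-1, -1, 1]),
}


def reindex_map(dmap: DiffuseMap, operation: str) -> DiffuseMap:
    """Apply a twofold reindexing; value at (h,k,l) moves to its image."""
    if operation not in _REINDEX_OPS:
        raise ValueError(
            f"unsupported reindex operation {operation!r}; one of {sorted(_REINDEX_OPS)}"
        )
    M = _REINDEX_OPS[operation]
    out = dmap.copy(provenance=f"reindexed:{operation}")
    out.values = apply_index_op(dmap.values, dmap.grid, M)
    out.measured = apply_index_op(dmap.measured, dmap.grid, M)
    return out


def simulate_image(
    dmap: DiffuseMap, geom: DetectorGeometry, setting: OrientationSetting
) -> DetectorImage:
    """Render one image: 8-nearest-grid-point interpolation at each pixel.

    Pixel values are the trilinear blend of the eight surrounding grid
    points in Miller-index space; unmeasured corners drop out with weight
    renormalization; pixels outside the map support are masked.
    """
    ny, nx = geom.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ij = np.stack([ii.ravel(), jj.ravel()], axis=-1)
    hkl = pixel_to_hkl(ij, geom, setting)
    cont = hkl * np.asarray(dmap.grid.sampling, dtype=float) + np.asarray(dmap.grid.bounds)
    base = np.floor(cont).astype(int)
    fracw = cont - base
    vals = np.zeros(len(ij))
    wsum = np.zeros(len(ij))
    shape = np.asarray(dmap.grid.shape)
    meas = dmap.measured
    for corner in range(8):
        dc = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = base + dc
        inb = np.all((idx >= 0) & (idx < shape), axis=-1)
        w = np.prod(np.where(dc == 1, fracw, 1.0 - fracw), axis=-1)
        i0, j0, k0 = idx[inb, 0], idx[inb, 1], idx[inb, 2]
        ok = meas[i0, j0, k0]
        sel = np.flatnonzero(inb)[ok]
        vals[sel] += w[sel] * dmap.values[i0[ok], j0[ok], k0[ok]]
        wsum[sel] += w[sel]
    masked = wsum <= 1e-12
    out = np.where(masked, 0.0, vals / np.where(masked, 1.0, wsum))
    return DetectorImage(
        pixels=out.reshape(ny, nx),
        mask=masked.reshape(ny, nx),
        geometry=geom,
        orientation=setting,
        meta={"simulated_from": dmap.provenance},
    )
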