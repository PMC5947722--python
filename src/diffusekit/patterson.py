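"""Patterson maps: zero-phase Fourier transforms of intensity maps.

The Patterson function P(u) = sum_hkl I(hkl) exp(2 pi i hkl . u) is the
autocorrelation of the (difference) charge density and reveals the distance
dependence of correlations: diffuse (variance) intensities produce a
Patterson that decays on the motion correlation length, while Bragg (mean)
intensities produce one that persists across the whole cell.

Unmeasured reciprocal points are zero-filled before the transform; only the
anisotropic component is normally transformed, which suppresses the
origin-dominated isotropic term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffuse import DiffuseMap, anisotropic_map, radial_profile
from .lattice import Lattice
from .structure_factors import BraggSet

__all__ = ["PattersonMap", "anisotropic_bragg", "patterson_fft", "section", "radial_abs_profile"]


@dataclass
class PattersonMap:
    """Real map on a fractional grid of the (super)cell.

    Normalization: ``values[0,0,0]`` equals the sum of input intensities
    (plain zero-phase Fourier sum, tag 'sum').
    """

    values: np.ndarray              # (n1, n2, n3) real, origin at [0,0,0]
    cell: Lattice                   # direct-space cell of the map
    normalization: str = "sum"
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def fractional_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.arange(n) / n for n in self.shape)

    def sigma_scaled(self) -> np.ndarray:
        """Map in units of its standard deviation (for contouring)."""
        sd = self.values.std()
        if sd == 0:
            return np.zeros_like(self.values)
        return self.values / sd


def anisotropic_bragg(bragg: BraggSet) -> BraggSet:
    """Subtract the spline-interpolated radial mean from Bragg intensities.

    Same shell/spline machinery as the diffuse decomposition; requires at
    least 4 populated resolution shells.
    """
    aniso = anisotropic_map(bragg.map, radial_profile(bragg.map))
    aniso.provenance = "bragg-anisotropic"
    return BraggSet(map=aniso)


def patterson_fft(
    source: DiffuseMap | BraggSet, out_shape: tuple[int, int, int] | None = None
) -> PattersonMap:
    """Zero-phase FFT of measured intensities (unmeasured points zero-filled).

    The default output grid doubles the reciprocal index range per axis
    (Nyquist-safe) and is even-sized.  The origin value equals the sum of
    the input intensities.
    """
    dmap = source.map if isinstance(source, BraggSet) else source
    if not dmap.measured.any():
        raise ValueError("all points unmeasured; nothing to transform")
    grid = dmap.grid
    if out_shape is None:
        out_shape = tuple(2 * n + (2 * n) % 2 for n in grid.shape)
    if any(o < s for o, s in zip(out_shape, grid.shape)):
        raise ValueError(f"output grid {out_shape} would alias the index range {grid.shape}")
    idx = grid.index_points()
    meas = dmap.measured.ravel()
    idx = idx[meas]
    vals = dmap.values.ravel()[meas]
    fill_fraction = 1.0 - meas.sum() / grid.in_sphere.sum()
    C = np.zeros(out_shape, dtype=complex)
    np.add.at(C, (idx[:, 0] % out_shape[0], idx[:, 1] % out_shape[1], idx[:, 2] % out_shape[2]), vals)
    P = np.fft.fftn(C)
    imag_residue = float(np.abs(P.imag).max() / max(np.abs(P.real).max(), 1e-300))
    return PattersonMap(
        values=P.real,
        cell=grid.lattice,
        normalization="sum",
        meta={
            "zero_fill_fraction": float(fill_fraction),
            "imag_residue": imag_residue,
            "source": dmap.provenance,
        },
    )


def section(pmap: PattersonMap, axis: str, index: int = 0) -> np.ndarray:
    """Extract the plane axis = index (grid units) as a 2D array.

    Axes of the returned array run over the remaining two fractional
    coordinates in cyclic order.
    """
    axes = {"x": 0, "y": 1, "z": 2}
    if axis not in axes:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    ax = axes[axis]
    if not 0 <= index < pmap.shape[ax]:
        raise ValueError(f"index {index} outside grid of size {pmap.shape[ax]}")
    return np.take(pmap.values, index, axis=ax)


def radial_abs_profile(pmap: PattersonMap, r_width: float = 1.0, r_max: float | None = None):
    """Radially averaged |P(r)| in shells of ``r_width`` A (minimum-image).

    Returns (shell midpoints in A, mean |P| per shell).
    """
    n1, n2, n3 = pmap.shape
    fx = (np.arange(n1) + n1 // 2) % n1 - n1 // 2
    fy = (np.arange(n2) + n2 // 2) % n2 - n2 // 2
    fz = (np.arange(n3) + n3 // 2) % n3 - n3 // 2
    frac = np.stack(
        np.meshgrid(fx / n1, fy / n2, fz / n3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    r = np.linalg.norm(pmap.cell.frac_to_cart(frac), axis=-1)
    if r_max is None:
        r_max = r.max()
    vals = np.abs(pmap.values).ravel()
    keep = r <= r_max
    shell = np.floor(r[keep] / r_width).astype(int)
    n_shells = int(shell.max()) + 1
    counts = np.bincount(shell, minlength=n_shells)
    sums = np.bincount(shell, weights=vals[keep], minlength=n_shells)
    mean = np.full(n_shells, np.nan)
    pop = counts > 0
    mean[pop] = sums[pop] / counts[pop]
    return (np.arange(n_shells) + 0.5) * r_width, mean
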