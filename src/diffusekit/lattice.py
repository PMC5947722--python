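"""Unit-cell geometry and reciprocal-space index grids.

Conventions used throughout the package:

* The scattering vector is ``s`` with ``|s| = 1/d`` (no factor of 2*pi);
  all Debye-Waller style expressions are written in these units.
* Fractional -> Cartesian conversion follows the standard crystallographic
  orthogonalization: **a** along x, **b** in the x-y plane.
* A supercell grid stores *integer* Miller indices of the supercell; the
  physical (unit-cell) index is ``integer index / sampling`` and is
  half-integer for a 2x2x2 layout, matching the twofold-finer sampling of
  diffuse intensity between the Bragg positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = ["Lattice", "ReciprocalGrid"]

SUPPORTED_LAUE = ("P1", "P4/m")


@dataclass(frozen=True)
class Lattice:
    """Crystal unit cell (edges in Angstrom, angles in degrees).

    ``multiplicity`` records the supercell layout (na, nb, nc) that this
    cell participates in; a plain unit cell uses (1, 1, 1).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    laue_group: str = "P1"
    multiplicity: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        for edge in (self.a, self.b, self.c):
            if not edge > 0:
                raise ValueError(f"cell edges must be positive, got {edge}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError(f"cell angles must lie in (0, 180), got {ang}")
        if self.laue_group not in SUPPORTED_LAUE:
            raise ValueError(
                f"unsupported Laue group {self.laue_group!r}; supported: {SUPPORTED_LAUE}"
            )
        if any(int(m) < 1 for m in self.multiplicity):
            raise ValueError(f"multiplicity components must be >= 1: {self.multiplicity}")
        object.__setattr__(self, "multiplicity", tuple(int(m) for m in self.multiplicity))

    # -- geometry -----------------------------------------------------------

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix M with cartesian = M @ fractional (a along x, b in xy)."""
        return np.array(self.gemmi_cell.orth.mat.tolist(), dtype=float)

    @property
    def fractionalization(self) -> np.ndarray:
        return np.array(self.gemmi_cell.frac.mat.tolist(), dtype=float)

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """B with s_cartesian = B @ (h, k, l); columns are a*, b*, c* (1/d units)."""
        return np.linalg.inv(self.orthogonalization).T

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.fractionalization.T

    def s_vector(self, hkl: np.ndarray) -> np.ndarray:
        """Cartesian scattering vector(s) (A^-1) for Miller index array (..., 3)."""
        return np.asarray(hkl, dtype=float) @ self.reciprocal_matrix.T

    def s_modulus(self, hkl: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.s_vector(hkl), axis=-1)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.s_modulus(hkl)

    @property
    def volume(self) -> float:
        return float(self.gemmi_cell.volume)

    def unit_cell(self) -> "Lattice":
        """The underlying unit cell of a supercell lattice (edges / multiplicity)."""
        na, nb, nc = self.multiplicity
        return replace(
            self, a=self.a / na, b=self.b / nb, c=self.c / nc, multiplicity=(1, 1, 1)
        )

    def supercell(self, layout: tuple[int, int, int] | None = None) -> "Lattice":
        """The lattice of the na x nb x nc supercell (edges scaled, angles kept)."""
        na, nb, nc = layout if layout is not None else self.multiplicity
        if min(na, nb, nc) < 1:
            raise ValueError(f"layout components must be >= 1: {(na, nb, nc)}")
        return replace(
            self,
            a=self.a * na,
            b=self.b * nb,
            c=self.c * nc,
            multiplicity=(na, nb, nc),
        )


@dataclass(frozen=True)
class ReciprocalGrid:
    """Dense centrosymmetric integer-index grid out to a resolution cutoff.

    ``lattice`` is the cell the integer indices refer to (the supercell
    lattice when ``sampling != (1,1,1)``).  Physical unit-cell Miller indices
    are ``index / sampling``.  Points beyond ``d_min`` stay in the dense box
    but are excluded by :attr:`in_sphere`.
    """

    lattice: Lattice
    d_min: float = 1.6
    sampling: tuple[int, int, int] = (1, 1, 1)
    bounds: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.d_min > 0:
            raise ValueError("d_min must be positive")
        object.__setattr__(self, "sampling", tuple(int(m) for m in self.sampling))
        smax = 1.0 / self.d_min
        B = self.lattice.reciprocal_matrix
        bstar = np.linalg.norm(B, axis=0)  # |a*|, |b*|, |c*|
        bounds = tuple(int(np.floor(smax / bi + 1e-12)) for bi in bstar)
        object.__setattr__(self, "bounds", bounds)

    @classmethod
    def for_model(cls, model, d_min: float = 1.6) -> "ReciprocalGrid":
        """Grid matching a model's own cell; sampling from the cell's multiplicity.

        For a supercell model (multiplicity > 1) the integer indices are
        supercell Miller indices and the physical unit-cell hkl are the
        half-integer (etc.) fractions index/sampling.
        """
        return cls(model.lattice, d_min=d_min, sampling=model.lattice.multiplicity)

    @classmethod
    def for_cell(
        cls,
        unit_cell: Lattice,
        d_min: float = 1.6,
        supercell: bool = False,
    ) -> "ReciprocalGrid":
        """Grid on the unit cell (integer hkl) or on its supercell (finer sampling)."""
        if supercell:
            return cls(unit_cell.supercell(), d_min=d_min, sampling=unit_cell.multiplicity)
        return cls(unit_cell, d_min=d_min, sampling=(1, 1, 1))

    # -- dense layout -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(2 * b + 1 for b in self.bounds)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open-meshgrid integer index arrays H, K, L broadcastable to shape."""
        hmax, kmax, lmax = self.bounds
        return np.meshgrid(
            np.arange(-hmax, hmax + 1),
            np.arange(-kmax, kmax + 1),
            np.arange(-lmax, lmax + 1),
            indexing="ij",
            sparse=True,
        )

    def index_points(self) -> np.ndarray:
        """(N, 3) integer indices of the full dense box, C order."""
        H, K, L = np.broadcast_arrays(*self.index_arrays())
        return np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)

    @property
    def s_mod(self) -> np.ndarray:
        """|s| (A^-1) on the dense box."""
        H, K, L = self.index_arrays()
        B = self.lattice.reciprocal_matrix
        sx = B[0, 0] * H + B[0, 1] * K + B[0, 2] * L
        sy = B[1, 0] * H + B[1, 1] * K + B[1, 2] * L
        sz = B[2, 0] * H + B[2, 1] * K + B[2, 2] * L
        return np.sqrt(sx * sx + sy * sy + sz * sz)

    @property
    def in_sphere(self) -> np.ndarray:
        """Boolean mask of points with d >= d_min (includes the origin)."""
        return self.s_mod <= 1.0 / self.d_min + 1e-12

    @property
    def voxel_diagonal(self) -> float:
        """Reciprocal voxel diagonal |(1/A, 1/B, 1/C)| of the index cell (A^-1)."""
        return float(np.sqrt(sum(1.0 / e**2 for e in (self.lattice.a, self.lattice.b, self.lattice.c))))

    def physical_hkl(self, index: np.ndarray) -> np.ndarray:
        """Unit-cell (possibly half-integer) Miller indices for integer indices."""
        return np.asarray(index, dtype=float) / np.asarray(self.sampling, dtype=float)

    def to_dense_offset(self, index: np.ndarray) -> tuple[np.ndarray, ...]:
        """Array offsets into the dense box for integer index triples (..., 3)."""
        idx = np.asarray(index)
        off = idx + np.asarray(self.bounds)
        return off[..., 0], off[..., 1], off[..., 2]

    def congruent(self, other: "ReciprocalGrid") -> bool:
        return (
            self.shape == other.shape
            and self.sampling == other.sampling
            and np.allclose(
                self.lattice.orthogonalization, other.lattice.orthogonalization
            )
            and np.isclose(self.d_min, other.d_min)
        )
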