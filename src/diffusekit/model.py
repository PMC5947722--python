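"""Atomic models and coordinate ensembles.

An :class:`AtomicModel` stores fractional coordinates (wrapped to [0, 1)) of
a fixed atom list in one cell (asymmetric unit, unit cell or supercell).
An :class:`Ensemble` is an ordered stack of displaced snapshots of the same
atom list; snapshot coordinates are fractional in the same cell but are
deliberately *not* wrapped, so that displaced molecules stay intact (diffuse
intensity is invariant to lattice-translation phases either way).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import Lattice

__all__ = ["AtomicModel", "Ensemble"]


@dataclass
class AtomicModel:
    lattice: Lattice
    elements: np.ndarray          # (n,) str element symbols
    frac: np.ndarray              # (n, 3) fractional coordinates in [0, 1)
    occupancy: np.ndarray | None = None   # (n,), defaults to 1.0
    copy_id: np.ndarray | None = None     # (n,) symmetry/supercell copy label
    atom_names: np.ndarray | None = None  # (n,) PDB-style atom names ("CA", ...)

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=object).reshape(-1)
        n = len(self.frac)
        if len(self.elements) != n:
            raise ValueError("elements and coordinates disagree in length")
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        self.occupancy = np.asarray(self.occupancy, dtype=float).reshape(-1)
        if self.copy_id is None:
            self.copy_id = np.zeros(n, dtype=int)
        self.copy_id = np.asarray(self.copy_id, dtype=int).reshape(-1)
        if self.atom_names is None:
            self.atom_names = np.asarray(["CA"] * n, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object).reshape(-1)
        self.frac = self.frac % 1.0

    @property
    def n_atoms(self) -> int:
        return len(self.frac)

    @property
    def n_copies(self) -> int:
        return int(self.copy_id.max()) + 1 if self.n_atoms else 0

    @property
    def cart(self) -> np.ndarray:
        """Cartesian coordinates (A) under the standard orthogonalization."""
        return self.lattice.frac_to_cart(self.frac)

    def selection(self, names: str | list[str] | None = None) -> np.ndarray:
        """Boolean atom mask by atom name(s); ``None`` selects everything."""
        if names is None:
            return np.ones(self.n_atoms, dtype=bool)
        if isinstance(names, str):
            names = [names]
        return np.isin(self.atom_names.astype(str), names)

    def with_coords(self, frac: np.ndarray, wrap: bool = True) -> "AtomicModel":
        frac = np.asarray(frac, dtype=float).reshape(-1, 3)
        if len(frac) != self.n_atoms:
            raise ValueError("atom count is fixed across derived models")
        out = AtomicModel(
            lattice=self.lattice,
            elements=self.elements.copy(),
            frac=frac % 1.0 if wrap else frac.copy(),
            occupancy=self.occupancy.copy(),
            copy_id=self.copy_id.copy(),
            atom_names=self.atom_names.copy(),
        )
        if not wrap:
            out.frac = frac.copy()  # bypass the wrapping done in __post_init__
        return out


@dataclass
class Ensemble:
    """Ordered snapshots of one atom list (fractional, unwrapped)."""

    model: AtomicModel            # reference (mean) structure
    frac: np.ndarray              # (n_snapshots, n_atoms, 3)
    spacing_label: str = "snapshot"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)
        if self.frac.ndim != 3 or self.frac.shape[1:] != (self.model.n_atoms, 3):
            raise ValueError(
                f"snapshot array shape {self.frac.shape} does not match the "
                f"model's {self.model.n_atoms} atoms"
            )

    @property
    def n_snapshots(self) -> int:
        return self.frac.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.model.n_atoms

    def cart(self) -> np.ndarray:
        """(n_snapshots, n_atoms, 3) Cartesian coordinates in A."""
        M = self.model.lattice.orthogonalization
        return self.frac @ M.T

    def snapshot(self, n: int) -> np.ndarray:
        """Fractional coordinates of snapshot ``n``."""
        return self.frac[n]

    def __iter__(self):
        return iter(self.frac)
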