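"""Synthetic crystals, motion-model ensembles and rotation-series images.

This module generates the study conditions that the analysis stages assume:
a small tetragonal P4_1 crystal (four symmetry copies per cell), its
2x2x2 supercell, coordinate ensembles with four displacement statistics
(independent Gaussian, distance-correlated "liquid-like", per-copy rigid
body, and a two-state loop flip), and synthetic rotation-series detector
images carrying smooth diffuse signal, single-pixel Bragg spikes and
Poisson noise.

Every generator takes an explicit seed; identical seeds give bit-identical
output, and the seed is recorded in the produced object's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import Lattice
from .model import AtomicModel, Ensemble

__all__ = [
    "MotionModel",
    "make_toy_asymmetric_unit",
    "expand_p41",
    "build_supercell",
    "sample_ensemble",
    "render_images",
]

#: P4_1 symmetry operators acting on fractional (x, y, z)
P41_OPERATORS = (
    lambda x, y, z: (x, y, z),
    lambda x, y, z: (-x, -y, z + 0.5),
    lambda x, y, z: (-y, x, z + 0.25),
    lambda x, y, z: (y, -x, z + 0.75),
)


@dataclass(frozen=True)
class MotionModel:
    """Displacement statistics of an ensemble.

    kind:
      independent_gaussian -- i.i.d. N(0, sigma^2) per Cartesian coordinate.
      liquid_like          -- joint Gaussian, per-axis covariance
                              C_ij = sigma^2 exp(-r_ij / gamma) with r_ij the
                              mean-structure inter-atomic distance.
      rigid_body           -- each symmetry copy rotated about its centroid
                              (axis uniform on the sphere, angle N(0, rot_sd^2)
                              degrees) and translated N(0, trans_sd^2 I).
      loop_flip            -- ``flip_atoms`` hop between two conformations as a
                              symmetric two-state Markov chain (switch
                              probability per snapshot); everyone rides an
                              additive independent-Gaussian background.
    """

    kind: str
    sigma: float = 0.0            # A, per-coordinate displacement SD
    gamma: float = 5.0            # A, correlation length (liquid_like)
    rot_sd: float = 0.0           # degrees (rigid_body)
    trans_sd: float = 0.0         # A (rigid_body)
    flip_atoms: np.ndarray | None = None   # atom indices (loop_flip)
    conf_a: np.ndarray | None = None       # (m, 3) Cartesian A, conformation A
    conf_b: np.ndarray | None = None       # (m, 3) Cartesian A, conformation B
    switch_probability: float = 0.01

    def __post_init__(self) -> None:
        kinds = ("independent_gaussian", "liquid_like", "rigid_body", "loop_flip")
        if self.kind not in kinds:
            raise ValueError(f"unknown motion kind {self.kind!r}; one of {kinds}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "liquid_like" and not self.gamma > 0:
            raise ValueError("liquid_like needs gamma > 0")
        if not 0 <= self.switch_probability <= 1:
            raise ValueError("switch probability must lie in [0, 1]")
        if self.kind == "loop_flip":
            if self.flip_atoms is None or self.conf_a is None or self.conf_b is None:
                raise ValueError("loop_flip needs flip_atoms, conf_a and conf_b")


def make_toy_asymmetric_unit(
    n_atoms: int,
    extent: float,
    seed: int,
    cell: Lattice | None = None,
    element: str = "C",
) -> AtomicModel:
    """Compact random cluster of carbon-like scatterers in one asymmetric unit.

    Atoms are drawn uniformly in a cube of side ``extent`` (A) centred in the
    quarter-cell 0 <= x,y < 1/2, 0 <= z < 1/4 region so that the four P4_1
    copies stay separated.  Deterministic for a fixed seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if cell is None:
        cell = Lattice(18.0, 18.0, 24.0, laue_group="P4/m")
    shortest = min(cell.a, cell.b, cell.c)
    if not extent < shortest:
        raise ValueError(
            f"extent {extent} A does not fit inside the cell (shortest edge "
            f"{shortest} A); choose extent < {shortest}"
        )
    rng = np.random.default_rng(seed)
    cart = (rng.random((n_atoms, 3)) - 0.5) * extent
    # centre near the quarter-cell point, clamped so the cube fits unwrapped
    edges = np.array([cell.a, cell.b, cell.c])
    centre = np.clip(np.array([0.25, 0.25, 0.125]) * edges, extent / 2, edges - extent / 2)
    frac = cell.cart_to_frac(cart + centre)
    return AtomicModel(
        lattice=cell,
        elements=np.array([element] * n_atoms, dtype=object),
        frac=frac,
        atom_names=np.array(["CA"] * n_atoms, dtype=object),
    )


def expand_p41(au: AtomicModel, cell: Lattice | None = None) -> AtomicModel:
    """Apply the four P4_1 operators; output wrapped into [0, 1).

    Requires a tetragonal cell (a = b, all angles 90).
    """
    cell = cell or au.lattice
    if not (
        np.isclose(cell.a, cell.b)
        and np.allclose([cell.alpha, cell.beta, cell.gamma], 90.0)
    ):
        raise ValueError("P4_1 expansion needs a tetragonal cell (a = b, angles 90)")
    x, y, z = au.frac.T
    frac = np.concatenate([np.stack(op(x, y, z), axis=1) for op in P41_OPERATORS])
    n = au.n_atoms
    return AtomicModel(
        lattice=cell,
        elements=np.tile(au.elements, 4),
        frac=frac % 1.0,
        occupancy=np.tile(au.occupancy, 4),
        copy_id=np.repeat(np.arange(4), n),
        atom_names=np.tile(au.atom_names, 4),
    )


def build_supercell(model: AtomicModel, layout: tuple[int, int, int]) -> AtomicModel:
    """Tile the cell na x nb x nc; copy (i,j,k) maps x -> (x + i) / na etc."""
    na, nb, nc = (int(m) for m in layout)
    if min(na, nb, nc) < 1:
        raise ValueError(f"layout components must be >= 1: {layout}")
    shifts = np.array(
        [(i, j, k) for i in range(na) for j in range(nb) for k in range(nc)], dtype=float
    )
    scale = np.array([na, nb, nc], dtype=float)
    frac = ((model.frac[None, :, :] + shifts[:, None, :]) / scale).reshape(-1, 3)
    n_tiles = len(shifts)
    n_base_copies = max(model.n_copies, 1)
    tile_offset = np.repeat(np.arange(n_tiles), model.n_atoms) * n_base_copies
    return AtomicModel(
        lattice=model.lattice.supercell((na, nb, nc)),
        elements=np.tile(model.elements, n_tiles),
        frac=frac,
        occupancy=np.tile(model.occupancy, n_tiles),
        copy_id=np.tile(model.copy_id, n_tiles) + tile_offset,
        atom_names=np.tile(model.atom_names, n_tiles),
    )


# -- ensemble sampling -----------------------------------------------------


def _liquid_like_factor(cart: np.ndarray, sigma: float, gamma: float) -> np.ndarray:
    """Cholesky factor of C_ij = sigma^2 exp(-r_ij / gamma) with tiny jitter."""
    r = np.linalg.norm(cart[:, None, :] - cart[None, :, :], axis=-1)
    C = sigma**2 * np.exp(-r / gamma)
    jitter = 1e-10 * max(sigma**2, 1.0)
    try:
        return np.linalg.cholesky(C + jitter * np.eye(len(C)))
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "liquid-like covariance is not positive definite even after "
            f"jitter {jitter:g}; check sigma/gamma and atom geometry"
        ) from err


def sample_ensemble(
    model: AtomicModel, motion: MotionModel, n_snapshots: int, seed: int
) -> Ensemble:
    """Draw an ensemble of displaced snapshots of ``model``.

    Displacements are sampled in Cartesian A and converted back to fractional
    coordinates; wrapping is suppressed so molecules stay intact.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    rng = np.random.default_rng(seed)
    cart0 = model.cart  # (n_atoms, 3)
    n = model.n_atoms
    shape = (n_snapshots, n, 3)

    if motion.kind == "independent_gaussian":
        cart = cart0 + motion.sigma * rng.standard_normal(shape)

    elif motion.kind == "liquid_like":
        if motion.sigma == 0:
            cart = np.broadcast_to(cart0, shape).copy()
        else:
            L = _liquid_like_factor(cart0, motion.sigma, motion.gamma)
            # independent per Cartesian axis: disp[s,:,ax] = L @ z
            z = rng.standard_normal(shape)
            cart = cart0 + np.einsum("ij,sjx->six", L, z)

    elif motion.kind == "rigid_body":
        from scipy.spatial.transform import Rotation

        cart = np.broadcast_to(cart0, shape).copy()
        copies = np.unique(model.copy_id)
        for cp in copies:
            sel = model.copy_id == cp
            centroid = cart0[sel].mean(axis=0)
            axes = rng.standard_normal((n_snapshots, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            angles = np.deg2rad(motion.rot_sd) * rng.standard_normal(n_snapshots)
            R = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
            trans = motion.trans_sd * rng.standard_normal((n_snapshots, 3))
            local = cart0[sel] - centroid
            cart[:, sel, :] = (
                np.einsum("sab,jb->sja", R, local) + centroid + trans[:, None, :]
            )

    elif motion.kind == "loop_flip":
        flip = np.asarray(motion.flip_atoms, dtype=int)
        conf_a = np.asarray(motion.conf_a, dtype=float)
        conf_b = np.asarray(motion.conf_b, dtype=float)
        if conf_a.shape != (len(flip), 3) or conf_b.shape != (len(flip), 3):
            raise ValueError("conf_a/conf_b must be (len(flip_atoms), 3) Cartesian")
        # symmetric two-state Markov chain: switch with stated probability
        switches = rng.random(n_snapshots) < motion.switch_probability
        switches[0] = False
        state = np.cumsum(switches) % 2  # 0 = A, 1 = B
        cart = cart0 + motion.sigma * rng.standard_normal(shape)
        cart[:, flip, :] = np.where(state[:, None, None] == 0, conf_a, conf_b)
        cart[:, flip, :] += motion.sigma * rng.standard_normal((n_snapshots, len(flip), 3))

    frac = cart @ model.lattice.fractionalization.T
    return Ensemble(
        model=model,
        frac=frac,
        seed=seed,
        meta={"motion": motion.kind, "sigma": motion.sigma, "seed": seed},
    )


# -- synthetic rotation-series images --------------------------------------


def render_images(
    diffuse,
    geom,
    orientations,
    bragg=None,
    bragg_intensity: float = 5000.0,
    rocking_width: float = 0.01,
    noise_seed: int | None = None,
    apply_corrections: bool = True,
    scale: float = 1.0,
    offset: float = 0.0,
):
    """Synthesize a rotation series from a 3D diffuse map.

    Each pixel samples the diffuse map by 8-nearest-grid-point (trilinear)
    interpolation at its fractional Miller index; optionally multiplied by
    the polarization x solid-angle factor (so that ``correct_geometry``
    undoes it).  A single-pixel Bragg spike of ``bragg_intensity`` ADU is
    added at the pixel nearest each integer-hkl reflection whose Ewald-sphere
    offset is below ``rocking_width`` (dimensionless |lambda |k_out| - 1|).
    With ``noise_seed`` set, pixels are Poisson-sampled; output is clipped to
    the 16-bit range and the per-image saturation count is recorded in
    metadata.
    """
    from .images import DetectorImage, geometry_factors, hkl_to_pixel, simulate_image

    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    images = []
    for setting in orientations:
        base = simulate_image(diffuse, geom, setting)
        pix = base.pixels * scale + offset
        pix[base.mask] = 0.0
        if apply_corrections:
            pix = pix * geometry_factors(geom)
        if bragg is not None:
            _add_bragg_spikes(pix, bragg, geom, setting, bragg_intensity, rocking_width)
        if rng is not None:
            pix = rng.poisson(np.clip(pix, 0, None)).astype(float)
        saturated = int(np.count_nonzero(pix > 65535))
        pix = np.clip(pix, 0, 65535)
        meta = {
            "orientation_deg": setting.angle_deg,
            "saturated_pixels": saturated,
            "noise_seed": noise_seed,
        }
        images.append(
            DetectorImage(
                pixels=pix, mask=base.mask.copy(), geometry=geom,
                orientation=setting, meta=meta,
            )
        )
    return images


def _add_bragg_spikes(pix, bragg, geom, setting, intensity, rocking_width) -> None:
    from .images import hkl_to_pixel

    grid = bragg.grid
    sampling = np.asarray(grid.sampling)
    idx = grid.index_points()
    # integer physical hkl only (multiples of the sampling factor), not origin
    integer = np.all(idx % sampling == 0, axis=1)
    insph = grid.in_sphere.ravel()
    keep = integer & insph & ~(np.all(idx == 0, axis=1))
    hkl = idx[keep] / sampling
    ij, offs, visible = hkl_to_pixel(hkl, geom, setting)
    near = visible & (np.abs(offs) < rocking_width)
    ij = np.round(ij[near]).astype(int)
    ny, nx = geom.shape
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < ny) & (ij[:, 1] >= 0) & (ij[:, 1] < nx)
    np.add.at(pix, (ij[ok, 0], ij[ok, 1]), intensity)
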