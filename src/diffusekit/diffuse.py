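"""Diffuse intensity accumulation, decomposition, symmetry and statistics.

Diffuse scattering is the ensemble variance of the structure factor
(Guinier's equation):

    D(hkl) = < |f_n(hkl)|^2 >_n  -  | < f_n(hkl) >_n |^2

accumulated in one pass from the moments sum(f) and sum(|f|^2), which makes
chunked/parallel accumulation exact: pooling the moments of chunks
reproduces the single-pass result to floating-point identity.

The isotropic component is the shell-mean radial profile (shell thickness =
reciprocal voxel diagonal); the anisotropic component subtracts a natural
cubic interpolating spline through the shell means.  Laue symmetry (P4/m
for a P4_1 crystal) is enforced by orbit averaging.  Undefined statistics
propagate as NaN flags, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .lattice import ReciprocalGrid
from .structure_factors import StructureFactorSet

__all__ = [
    "DiffuseMap",
    "RadialProfile",
    "ComparisonStats",
    "GuinierAccumulator",
    "guinier_accumulate",
    "merge_partial",
    "radial_profile",
    "anisotropic_map",
    "laue_operations",
    "symmetrize",
    "pearson",
    "shell_cc",
    "cc_sym",
]


@dataclass
class DiffuseMap:
    """Intensities + measured flags on a dense reciprocal grid."""

    grid: ReciprocalGrid
    values: np.ndarray      # float, grid.shape
    measured: np.ndarray    # bool, grid.shape; always a subset of in_sphere
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.measured = np.asarray(self.measured, dtype=bool)
        if self.values.shape != self.grid.shape or self.measured.shape != self.grid.shape:
            raise ValueError("map arrays must match the grid shape")
        self.measured &= self.grid.in_sphere

    def copy(self, provenance: str | None = None) -> "DiffuseMap":
        return DiffuseMap(
            grid=self.grid,
            values=self.values.copy(),
            measured=self.measured.copy(),
            provenance=provenance or self.provenance,
            meta=dict(self.meta),
        )

    @classmethod
    def constant(cls, grid: ReciprocalGrid, value: float = 0.0, provenance: str = "synthetic") -> "DiffuseMap":
        return cls(
            grid=grid,
            values=np.full(grid.shape, float(value)),
            measured=grid.in_sphere.copy(),
            provenance=provenance,
        )

    def measured_values(self) -> np.ndarray:
        return self.values[self.measured]

    def value_at(self, index: Sequence[int]) -> float:
        i, j, k = self.grid.to_dense_offset(np.asarray(index))
        return float(self.values[i, j, k])


@dataclass
class RadialProfile:
    """Shell-mean intensity vs |s| (isotropic component).

    ``s_mid`` are the geometric shell midpoints; ``s_mean`` is the mean |s|
    of the measured points in each shell, which is the abscissa actually
    used when the isotropic curve is interpolated (on a discrete lattice the
    point density grows with |s|, so the population centre of a shell sits
    above its midpoint).
    """

    s_mid: np.ndarray       # shell midpoints, A^-1
    s_mean: np.ndarray      # per-shell mean |s| of measured points (NaN empty)
    mean: np.ndarray        # shell mean intensity (NaN where empty)
    counts: np.ndarray      # measured points per shell
    thickness: float        # shell width = reciprocal voxel diagonal

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class ComparisonStats:
    """Total and anisotropic correlations plus resolution-shell series."""

    r_oc: float
    r_prime_oc: float
    shell_s_mid: np.ndarray
    shell_cc: np.ndarray
    cc_sym: float


class GuinierAccumulator:
    """Single-pass accumulation of sum(f) and sum(|f|^2) over snapshots."""

    def __init__(self, grid: ReciprocalGrid):
        self.grid = grid
        self.n = 0
        self.sum_f = np.zeros(grid.shape, dtype=complex)
        self.sum_f2 = np.zeros(grid.shape, dtype=float)

    def add(self, sf: StructureFactorSet) -> "GuinierAccumulator":
        if sf.grid is not self.grid and not sf.grid.congruent(self.grid):
            raise ValueError("snapshot grid does not match the accumulator grid")
        self.sum_f += sf.values
        self.sum_f2 += np.abs(sf.values) ** 2
        self.n += 1
        return self

    def merge(self, other: "GuinierAccumulator") -> "GuinierAccumulator":
        if not other.grid.congruent(self.grid):
            raise ValueError("cannot merge accumulators on different grids")
        self.sum_f += other.sum_f
        self.sum_f2 += other.sum_f2
        self.n += other.n
        return self

    def finalize(self, provenance: str = "simulated") -> DiffuseMap:
        if self.n < 2:
            raise ValueError(
                f"variance needs at least 2 snapshots, accumulated {self.n}"
            )
        mean_f = self.sum_f / self.n
        D = self.sum_f2 / self.n - np.abs(mean_f) ** 2
        return DiffuseMap(
            grid=self.grid,
            values=D,
            measured=self.grid.in_sphere.copy(),
            provenance=provenance,
            meta={"n_snapshots": self.n},
        )


def guinier_accumulate(sf_stream: Iterable[StructureFactorSet]) -> DiffuseMap:
    """Diffuse map D = <|f|^2> - |<f>|^2 from a stream of snapshot SFs."""
    acc = None
    for sf in sf_stream:
        if acc is None:
            acc = GuinierAccumulator(sf.grid)
        acc.add(sf)
    if acc is None:
        raise ValueError("empty structure-factor stream")
    return acc.finalize()


def merge_partial(partials: Sequence[GuinierAccumulator]) -> DiffuseMap:
    """Pool chunk moments; exactly reproduces the single-pass accumulation."""
    if not partials:
        raise ValueError("no partial accumulations to merge")
    total = GuinierAccumulator(partials[0].grid)
    for p in partials:
        total.merge(p)
    return total.finalize()


# -- isotropic / anisotropic decomposition ---------------------------------


def radial_profile(dmap: DiffuseMap) -> RadialProfile:
    """Shell means over measured points; shells of one voxel diagonal from 0."""
    if not dmap.measured.any():
        raise ValueError("map has no measured points")
    width = dmap.grid.voxel_diagonal
    s = dmap.grid.s_mod[dmap.measured]
    v = dmap.values[dmap.measured]
    shell = np.floor(s / width).astype(int)
    n_shells = int(shell.max()) + 1
    counts = np.bincount(shell, minlength=n_shells)
    sums = np.bincount(shell, weights=v, minlength=n_shells)
    s_sums = np.bincount(shell, weights=s, minlength=n_shells)
    mean = np.full(n_shells, np.nan)
    s_mean = np.full(n_shells, np.nan)
    pop = counts > 0
    mean[pop] = sums[pop] / counts[pop]
    s_mean[pop] = s_sums[pop] / counts[pop]
    s_mid = (np.arange(n_shells) + 0.5) * width
    return RadialProfile(
        s_mid=s_mid, s_mean=s_mean, mean=mean, counts=counts, thickness=width
    )


def isotropic_spline(
    dmap: DiffuseMap, profile: RadialProfile, max_iter: int = 100, tol: float = 1e-9
) -> CubicSpline:
    """Mean-consistent natural cubic spline through the radial profile.

    The knots sit at each populated shell's mean |s|; knot values start at
    the shell means and are then iteratively adjusted so that the spline,
    averaged over the map's measured points of each shell (within the spline
    support), reproduces the shell-mean intensity.  This makes the
    subtracted anisotropic component carry zero shell means by construction
    -- the defining property of the isotropic/anisotropic split -- instead
    of leaving a quadrature bias wherever the radial curve bends within a
    shell or a boundary shell is only partially covered.
    """
    pop = profile.populated
    if pop.sum() < 4:
        raise ValueError(
            f"cubic spline needs >= 4 populated shells, found {int(pop.sum())}"
        )
    t = profile.s_mean[pop]
    s = dmap.grid.s_mod[dmap.measured]
    v = dmap.values[dmap.measured]
    shell = np.floor(s / profile.thickness).astype(int)
    support = (s >= t[0]) & (s <= t[-1])
    shells = np.flatnonzero(pop)
    target = np.array(
        [v[(shell == n) & support].mean() if ((shell == n) & support).any() else np.nan
         for n in shells]
    )
    usable = ~np.isnan(target)
    y = target.copy()
    y[~usable] = profile.mean[pop][~usable]
    scale = max(np.abs(target[usable]).max(), 1e-30)
    spline = CubicSpline(t, y, bc_type="natural")
    for _ in range(max_iter):
        sv = spline(s)
        got = np.array(
            [sv[(shell == n) & support].mean() if ((shell == n) & support).any() else np.nan
             for n in shells]
        )
        err = np.where(usable, target - got, 0.0)
        if np.nanmax(np.abs(err)) < tol * scale:
            break
        y = y + err
        spline = CubicSpline(t, y, bc_type="natural")
    return spline


def anisotropic_map(dmap: DiffuseMap, profile: RadialProfile | None = None) -> DiffuseMap:
    """D'(hkl) = D(hkl) - spline(|s_hkl|); no extrapolation beyond the knots."""
    if profile is None:
        profile = radial_profile(dmap)
    spline = isotropic_spline(dmap, profile)
    lo, hi = spline.x[0], spline.x[-1]
    s = dmap.grid.s_mod
    support = (s >= lo) & (s <= hi)
    out = dmap.copy(provenance="anisotropic")
    out.measured &= support
    out.values = np.where(out.measured, dmap.values - spline(np.clip(s, lo, hi)), 0.0)
    return out


# -- Laue symmetry ---------------------------------------------------------

_P4M_OPS = [
    np.array(m, dtype=int)
    for m in (
        [[1, 0, 0], [0, 1, 0], [0, 0, 1]],     # h, k, l
        [[0, -1, 0], [1, 0, 0], [0, 0, 1]],    # -k, h, l
        [[-1, 0, 0], [0, -1, 0], [0, 0, 1]],   # -h, -k, l
        [[0, 1, 0], [-1, 0, 0], [0, 0, 1]],    # k, -h, l
    )
]
_P4M_OPS = _P4M_OPS + [m @ np.diag([1, 1, -1]) for m in _P4M_OPS]  # x {l, -l}


def laue_operations(laue: str) -> list[np.ndarray]:
    if laue == "P1":
        return [np.eye(3, dtype=int)]
    if laue == "P4/m":
        return [m.copy() for m in _P4M_OPS]
    raise ValueError(f"unsupported Laue group {laue!r}; supported: 'P1', 'P4/m'")


def apply_index_op(values: np.ndarray, grid: ReciprocalGrid, M: np.ndarray) -> np.ndarray:
    """Return A' with A'[p] = A[M p] on the dense centered box."""
    H, K, L = grid.index_arrays()
    hmax, kmax, lmax = grid.bounds
    i = M[0, 0] * H + M[0, 1] * K + M[0, 2] * L + hmax
    j = M[1, 0] * H + M[1, 1] * K + M[1, 2] * L + kmax
    k = M[2, 0] * H + M[2, 1] * K + M[2, 2] * L + lmax
    i, j, k = np.broadcast_arrays(i, j, k)
    shape = values.shape
    if (
        i.min() < 0 or i.max() >= shape[0]
        or j.min() < 0 or j.max() >= shape[1]
        or k.min() < 0 or k.max() >= shape[2]
    ):
        raise ValueError(
            "index operation maps outside the grid (tetragonal ops need a = b)"
        )
    return values[i, j, k]


def symmetrize(dmap: DiffuseMap, laue: str | None = None) -> DiffuseMap:
    """Replace each point by the mean over measured members of its Laue orbit.

    Unmeasured points whose orbit contains measured mates become measured.
    """
    laue = laue or dmap.grid.lattice.laue_group
    ops = laue_operations(laue)
    acc = np.zeros(dmap.grid.shape)
    cnt = np.zeros(dmap.grid.shape)
    vals = np.where(dmap.measured, dmap.values, 0.0)
    meas = dmap.measured.astype(float)
    for M in ops:
        acc += apply_index_op(vals, dmap.grid, M)
        cnt += apply_index_op(meas, dmap.grid, M)
    out = dmap.copy(provenance="symmetrized")
    got = cnt > 0
    out.values = np.where(got, np.divide(acc, cnt, out=np.zeros_like(acc), where=got), 0.0)
    out.measured = got & dmap.grid.in_sphere
    return out


# -- comparison statistics -------------------------------------------------


def _pearson_arrays(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return float("nan")  # degenerate variance: undefined, not 0
    return float((xc @ yc) / den)


def pearson(a: DiffuseMap, b: DiffuseMap) -> float:
    """Pearson correlation over jointly measured points (NaN if undefined)."""
    if not a.grid.congruent(b.grid):
        raise ValueError("maps live on different grids")
    joint = a.measured & b.measured
    return _pearson_arrays(a.values[joint], b.values[joint])


def shell_cc(
    a: DiffuseMap, b: DiffuseMap, profile: RadialProfile | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-resolution-shell Pearson correlation (NaN where < 3 joint points).

    Returns (shell midpoints, per-shell CC).
    """
    if not a.grid.congruent(b.grid):
        raise ValueError("maps live on different grids")
    width = profile.thickness if profile is not None else a.grid.voxel_diagonal
    joint = a.measured & b.measured
    s = a.grid.s_mod[joint]
    x = a.values[joint]
    y = b.values[joint]
    shell = np.floor(s / width).astype(int)
    n_shells = int(shell.max()) + 1 if len(shell) else 0
    cc = np.full(n_shells, np.nan)
    for n in range(n_shells):
        sel = shell == n
        cc[n] = _pearson_arrays(x[sel], y[sel])
    s_mid = (np.arange(n_shells) + 0.5) * width
    return s_mid, cc


def cc_sym(dmap: DiffuseMap, laue: str | None = None, per_shell: bool = False):
    """Correlation of a map with its Laue-symmetrized image (self-consistency)."""
    sym = symmetrize(dmap, laue)
    if per_shell:
        return shell_cc(dmap, sym)
    return pearson(dmap, sym)


def compare_maps(simulated: DiffuseMap, observed: DiffuseMap, laue: str | None = None) -> ComparisonStats:
    """Full comparison: both inputs are symmetrized first, as in map merging."""
    a = symmetrize(simulated, laue)
    b = symmetrize(observed, laue)
    a_an = anisotropic_map(a)
    b_an = anisotropic_map(b)
    s_mid, shells = shell_cc(a_an, b_an)
    return ComparisonStats(
        r_oc=pearson(a, b),
        r_prime_oc=pearson(a_an, b_an),
        shell_s_mid=s_mid,
        shell_cc=shells,
        cc_sym=cc_sym(simulated, laue),
    )
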