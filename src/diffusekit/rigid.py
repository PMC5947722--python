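"""Rigid-body rotation decomposition of crystalline ensembles.

For each snapshot and each symmetry copy, the optimal proper rotation onto
a reference structure is found by least squares (covariance SVD with
determinant correction), and the motion is summarized by Euler-angle
standard deviations and by the RMSD before/after rotational alignment.
A small rotational-fit signal does *not* prove rigid-body motion: internal
conformational changes (e.g. a flipping loop) leak into the fitted
rotation, which is why the subset-exclusion test is provided.

Euler angles use the Cardan x-y-z convention, R = Rx(phi) Ry(theta) Rz(psi),
reported in degrees.  For the small rotations this analysis targets the
three angles approximate the rotation-vector components about x, y and z,
so their standard deviations are directly interpretable as per-axis
rotation amplitudes (a symmetric-axis convention such as z-y-z is
degenerate at the identity and would bury the signal in azimuth noise).
Angle series are continuity-unwrapped (multiples of 360 deg) before
standard deviations are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Ensemble

__all__ = [
    "RotationFit",
    "align_translation",
    "fit_rotation",
    "euler_decompose",
    "euler_recompose",
    "per_copy_fits",
    "rotation_statistics",
    "subset_excluded_fit",
]

_GIMBAL_EPS = 1e-8


@dataclass
class RotationFit:
    """Per-snapshot rotation fits of one symmetry copy."""

    copy_id: int
    matrices: np.ndarray        # (n_snap, 3, 3)
    euler_deg: np.ndarray       # (n_snap, 3) unwrapped (phi, theta, psi)
    rmsd_before: np.ndarray     # (n_snap,) A
    rmsd_after: np.ndarray      # (n_snap,) A
    gimbal: np.ndarray          # (n_snap,) bool

    @property
    def euler_sd(self) -> np.ndarray:
        return self.euler_deg.std(axis=0)

    @property
    def trajectory_rmsd_before(self) -> float:
        """Square root of the mean squared per-snapshot RMSD."""
        return float(np.sqrt(np.mean(self.rmsd_before**2)))

    @property
    def trajectory_rmsd_after(self) -> float:
        return float(np.sqrt(np.mean(self.rmsd_after**2)))


def align_translation(
    snapshot: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> np.ndarray:
    """Shift a snapshot so its selection centroid matches the reference's."""
    snap = np.asarray(snapshot, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.ones(len(ref), dtype=bool)
    selection = np.asarray(selection)
    if selection.dtype == bool and not selection.any() or len(snap[selection]) == 0:
        raise ValueError("empty atom selection")
    shift = ref[selection].mean(axis=0) - snap[selection].mean(axis=0)
    return snap + shift


def fit_rotation(
    snapshot: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """Least-squares proper rotation of a (centred) snapshot onto a reference.

    Returns (R, rmsd_before, rmsd_after) over the selection, where R is the
    Kabsch rotation (SVD of the covariance with determinant correction, so
    det R = +1 always) and x_aligned = R @ (x - centroid) + ref_centroid.
    Inputs are expected to be translationally aligned; centroids are removed
    internally so the fit is purely rotational.
    """
    snap = np.asarray(snapshot, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.ones(len(ref), dtype=bool)
    x = snap[selection]
    y = ref[selection]
    if len(x) < 3:
        raise ValueError("rotation fit needs at least 3 selected atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(xc, tol=1e-9) < 2:
        raise ValueError("selection is collinear/degenerate; rotation ill-defined")
    H = xc.T @ yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd_before = float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
    aligned = xc @ R.T + y.mean(axis=0)
    rmsd_after = float(np.sqrt(np.mean(np.sum((aligned - y) ** 2, axis=1))))
    return R, rmsd_before, rmsd_after


def euler_decompose(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Cardan x-y-z Euler angles (degrees) of a proper rotation.

    R = Rx(phi) Ry(theta) Rz(psi).  Returns ((phi, theta, psi),
    gimbal_flag).  At the gimbal degeneracy (theta = +/-90 deg) psi is set
    to 0 and phi carries the full remaining azimuth.  Near the identity the
    angles reduce to the rotation-vector components, so a 5 deg rotation
    about z comes back as psi + phi = 5 with theta = 0.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    sin_theta = np.clip(R[0, 2], -1.0, 1.0)
    theta = np.arcsin(sin_theta)
    cos_theta = np.sqrt(max(0.0, 1.0 - sin_theta**2))
    if cos_theta > _GIMBAL_EPS:
        phi = np.arctan2(-R[1, 2], R[2, 2])
        psi = np.arctan2(-R[0, 1], R[0, 0])
        gimbal = False
    else:
        # theta = +/-90: only phi -/+ psi determined; assign it all to phi
        phi = np.arctan2(R[2, 1], R[1, 1])
        psi = 0.0
        gimbal = True
    return np.degrees(np.array([phi, theta, psi])), gimbal


def euler_recompose(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrix from Cardan x-y-z Euler angles in degrees."""
    phi, theta, psi = np.radians(np.asarray(angles_deg, dtype=float))

    def rx(a):
        return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])

    def ry(a):
        return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])

    def rz(a):
        return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])

    return rx(phi) @ ry(theta) @ rz(psi)


def per_copy_fits(
    ensemble: Ensemble,
    reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
    stride: int = 1,
) -> list[RotationFit]:
    """Rotation fits of every symmetry copy across the ensemble.

    ``reference`` defaults to the ensemble's mean-structure model;
    ``selection`` is a boolean mask over all atoms (defaults to everything);
    ``stride`` subsamples snapshots, emulating sparser trajectory sampling.
    """
    model = ensemble.model
    if reference is None:
        reference = model.cart
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.ones(model.n_atoms, dtype=bool)
    selection = np.asarray(selection, dtype=bool)
    cart = ensemble.cart()[::stride]
    fits = []
    for cp in np.unique(model.copy_id):
        sel = selection & (model.copy_id == cp)
        if sel.sum() < 3:
            raise ValueError(f"copy {cp}: fewer than 3 selected atoms")
        mats, eulers, r_before, r_after, gimbals = [], [], [], [], []
        for snap in cart:
            shifted = align_translation(snap, reference, sel)
            R, rb, ra = fit_rotation(shifted, reference, sel)
            ang, gim = euler_decompose(R)
            mats.append(R)
            eulers.append(ang)
            r_before.append(rb)
            r_after.append(ra)
            gimbals.append(gim)
        euler = np.unwrap(np.asarray(eulers), axis=0, period=360.0)
        fits.append(
            RotationFit(
                copy_id=int(cp),
                matrices=np.asarray(mats),
                euler_deg=euler,
                rmsd_before=np.asarray(r_before),
                rmsd_after=np.asarray(r_after),
                gimbal=np.asarray(gimbals),
            )
        )
    return fits


def rotation_statistics(fits: list[RotationFit]) -> pd.DataFrame:
    """Per-copy Euler-angle SDs and trajectory-wide RMSD reduction.

    The fractional reduction is NaN-flagged (undefined) for a static copy.
    """
    rows = []
    for f in fits:
        if len(f.rmsd_before) < 2:
            raise ValueError("statistics need at least 2 snapshots per copy")
        sd = f.euler_sd
        rb = f.trajectory_rmsd_before
        ra = f.trajectory_rmsd_after
        reduction = (rb - ra) / rb if rb > 0 else float("nan")
        rows.append(
            {
                "copy": f.copy_id,
                "sd_phi_deg": sd[0],
                "sd_theta_deg": sd[1],
                "sd_psi_deg": sd[2],
                "rmsd_before_A": rb,
                "rmsd_after_A": ra,
                "fractional_reduction": reduction,
            }
        )
    return pd.DataFrame(rows).set_index("copy")


def subset_excluded_fit(
    ensemble: Ensemble,
    excluded: np.ndarray,
    reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
    stride: int = 1,
) -> dict:
    """Rotation statistics with and without an excluded atom subset.

    ``excluded`` is a boolean mask (or index array) over all atoms; it must
    leave >= 3 atoms per copy.  Returns the two summary tables and the
    per-copy change in each Euler-angle SD (full minus reduced) -- the
    loop-exclusion sensitivity test.
    """
    model = ensemble.model
    if selection is None:
        selection = np.ones(model.n_atoms, dtype=bool)
    selection = np.asarray(selection, dtype=bool)
    excl = np.zeros(model.n_atoms, dtype=bool)
    excl[np.asarray(excluded)] = True
    reduced = selection & ~excl
    if not (reduced & selection).any():
        raise ValueError("exclusion empties the selection")
    full_stats = rotation_statistics(per_copy_fits(ensemble, reference, selection, stride))
    red_stats = rotation_statistics(per_copy_fits(ensemble, reference, reduced, stride))
    delta = full_stats[["sd_phi_deg", "sd_theta_deg", "sd_psi_deg"]] - red_stats[
        ["sd_phi_deg", "sd_theta_deg", "sd_psi_deg"]
    ]
    return {"full": full_stats, "excluded": red_stats, "sd_change": delta}
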