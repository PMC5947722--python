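# Methods

## The model

Diffuse X-ray scattering from a molecular crystal is the variance of the
structure factor over the ensemble of instantaneous cell contents
(Guinier's equation):

    D(hkl) = <|f_n(hkl)|^2>_n - |<f_n(hkl)>_n|^2

while the Bragg intensities are determined by the mean:

    I(hkl) = |<f_n(hkl)>_n|^2 .

Each snapshot's structure factor is the exact direct sum over atoms,

    f(hkl) = sum_j occ_j f_j(|s|) exp(2 pi i (h x_j + k y_j + l z_j)) ,

with the International Tables 4-Gaussian atomic form factors and the
scattering-vector convention |s| = 1/d (no 2 pi); the Debye-Waller factor
for a Gaussian spread sigma is exp(-4 pi^2 sigma^2 |s|^2) in these units.
The sum is computed per element as a separable lattice sum over a dense
integer-index box (an exact reorganization, not a gridding approximation);
tests check it term-by-term against a brute-force oracle to 1e-10.

When a crystal is modelled as an n_a x n_b x n_c supercell, the reciprocal
lattice of the supercell samples n-fold finer than the unit cell: for a
2x2x2 layout the diffuse map carries values at half-integer Miller indices,
midway between the Bragg positions where Bragg contamination is smallest.
Internally all indices are integers of the supercell lattice plus a
per-axis sampling factor; half-integers only materialize in text output.

Accumulation is single-pass over the moments sum(f) and sum(|f|^2).
Pooling the moments of independent chunks reproduces the single-pass result
to floating-point identity, so chunked (parallelizable) accumulation is
exact by construction.

## Isotropic/anisotropic decomposition

Reciprocal space is divided into concentric shells of one reciprocal voxel
diagonal |(1/A, 1/B, 1/C)| (supercell edges A, B, C).  The isotropic
component is the per-shell mean intensity; the anisotropic component
subtracts an interpolated isotropic curve at each point's |s|.

The interpolant is a natural cubic interpolating spline whose knots sit at
each populated shell's mean |s| (on a discrete lattice the point density
grows as s^2, so a shell's population centre lies above its geometric
midpoint).  Knot values start at the shell means and are then adjusted by a
fixed-point iteration until the spline, averaged over the measured points
of each shell inside the spline support, reproduces the shell mean to 1e-9
relative.  This makes the anisotropic component carry exactly zero shell
means — the defining property of the split.  Anchoring the spline naively
at geometric midpoints leaves a quadrature bias wherever the radial curve
bends within a shell, and boundary half-shells (cut by the resolution
sphere or by the support edge) end up with all their points on one side of
the curve; the mean-consistent form removes both artifacts.  Points below
the first or above the last knot are flagged unmeasured rather than
extrapolated.  The same machinery produces the anisotropic component of
Bragg intensity sets.

## Laue symmetry and comparison statistics

For a P4_1 crystal the diffraction pattern has Laue symmetry P4/m: the
8-operation group {(h,k,l), (-k,h,l), (-h,-k,l), (k,-h,l)} x {l, -l}.
Symmetry averaging replaces every point by the mean over the *measured*
members of its orbit; unmeasured points with measured orbit mates become
measured.  The operation is idempotent and preserves the mean over measured
points.  Agreement statistics are Pearson correlations over jointly
measured points: the total correlation r_oc, the anisotropic correlation
r'_oc, per-resolution-shell correlations, and CC_sym (a map against its own
symmetrized image — the internal-consistency ceiling for any model-data
comparison).  Undefined statistics (fewer than 3 points, zero variance)
propagate as NaN flags, never as zeros.

## Detector images

Geometry is a flat detector at normal incidence, beam along +z, with
sample-to-detector distance, pixel size, wavelength, beam centre,
polarization fraction/azimuth and a saturation threshold in a plain-text
key=value config.  A pixel maps to reciprocal space through the Ewald
construction, s = (k_out - k_in)/lambda, followed by the inverse of the
crystal setting matrix (which maps physical unit-cell hkl to the lab frame;
the goniometer adds a per-image rotation about a stated lab axis).  The
setting matrix is an input — autoindexing is out of scope.

* **Mode filter** (Bragg rejection): every unmasked pixel becomes the
  representative of the most populated intensity bin (default 1 ADU) in its
  15x15 neighborhood.  The representative is the bin's lower edge, so
  integer-valued backgrounds pass through unchanged; ties resolve to the
  lowest bin, biasing toward background, which is the filter's purpose.
  Borders use the truncated neighborhood; fully-masked neighborhoods
  propagate the mask.
* **Geometric correction**: one floating-point pass divides each pixel by
  P * Omega, where P is the polarization factor
  xi (1 - sin^2 2theta cos^2 dphi) + (1 - xi)(1 - sin^2 2theta sin^2 dphi)
  (the unpolarized (1 + cos^2 2theta)/2 at xi = 1/2) and Omega = cos^3 of
  the pixel obliquity, both normalized to 1 at the beam centre.
* **Integration**: each filtered, corrected, unmasked pixel is assigned to
  the nearest supercell grid point (round half up in index space);
  per-voxel count-weighted means and contributing-pixel counts are kept.
* **Simulation**: the reverse path interpolates the 3D map at each pixel's
  fractional hkl from the 8 nearest grid points in proportion to the
  distances along each index axis; unmeasured corners drop out with weight
  renormalization.
* **Reindexing**: twofold rotations about h, k or l (e.g. the 180-degree
  rotation about h used to bring observed and simulated maps into one
  indexing convention) permute the dense index box; each is an involution.

## Patterson analysis

The Patterson map is the zero-phase Fourier transform of an intensity set;
for diffuse (variance) intensities it is the autocorrelation of the
charge-density *variations* and decays on the correlation length of the
motions, whereas the Bragg-derived Patterson reflects the mean density and
persists across the whole cell.  Only the anisotropic component is
transformed (the isotropic part would bury the signal in an origin peak).
Unmeasured points are zero-filled (fill fraction logged in metadata); the
output grid defaults to twice the index range per axis, even-sized; under
the stated convention the origin value equals the sum of input intensities.
Maps are written in CCP4 format and as plain-text sections; both raw and
sigma-scaled values are exposed since the absolute contour scale is a
display choice.

## Rigid-body decomposition

Per snapshot and per symmetry copy, the optimal proper rotation onto the
reference is the Kabsch solution (SVD of the coordinate covariance with
determinant correction; det R = +1 always), after centroid alignment.
Motion is summarized by the SDs of Euler angles and by the RMSD before and
after rotational alignment; trajectory-wide RMSD is the square root of the
mean squared per-snapshot RMSD, and the fractional reduction
(rmsd_before - rmsd_after)/rmsd_before measures how much of the motion is
rigid rotation.

Euler angles use the Cardan x-y-z convention R = Rx(phi) Ry(theta) Rz(psi).
The choice matters: symmetric-axis conventions (z-y-z) are degenerate at
the identity, and crystalline rigid-body rotations are small (degree
scale), so z-y-z phi/psi would be dominated by the azimuth of the
instantaneous rotation axis — SDs of hundreds of degrees carrying no
amplitude information.  Cardan angles reduce to the rotation-vector
components near the identity, making their SDs per-axis rotation
amplitudes; the convention is degenerate only at a 90-degree tilt, far from
the regime of interest.  Angle series are unwrapped by multiples of 360
degrees before SDs are taken.

A small rotational fit does *not* prove rigid-body motion: internal
conformational changes leak into the fitted rotation.  The subset-exclusion
test quantifies this by refitting without a suspect atom subset (e.g. a
flipping loop) and reporting the per-angle SD changes; for a genuinely
rigid ensemble the change is zero within sampling error, while for a
loop-flip ensemble excluding the flipping atoms strictly lowers the
apparent rotation SDs.

## Synthetic data: what it emulates, and what it does not

The generator produces a toy tetragonal P4_1 crystal (default cell
18 x 18 x 24 A, four copies per cell from the operators (x,y,z),
(-x,-y,z+1/2), (-y,x,z+1/4), (y,-x,z+3/4)), its 2x2x2 supercell, and
ensembles with four displacement statistics:

* `independent_gaussian` — i.i.d. N(0, sigma^2) per Cartesian coordinate
  (Einstein model; closed-form diffuse intensity used as an oracle);
* `liquid_like` — joint Gaussian with per-axis covariance
  sigma^2 exp(-r_ij/gamma) (the liquid-like-motions picture; Cholesky
  factorization with 1e-10 jitter, failure reported, never patched);
* `rigid_body` — each symmetry copy independently rotated about its
  centroid (axis uniform on the sphere, angle N(0, rot_sd^2)) and
  translated N(0, trans_sd^2 I);
* `loop_flip` — a designated atom subset hops between two conformations as
  a symmetric two-state Markov chain (default switch probability 0.01 per
  snapshot) over an independent-Gaussian background.

Defaults sigma = 0.3 A (B ~ 7 A^2, a typical well-ordered protein at
cryo-adjacent disorder levels), gamma = 5 A (short against the cell edge,
matching the observation that the dominant correlations are shorter than a
unit cell), rot_sd = 2 degrees and trans_sd = 0.1 A (the degree-scale
rigid-body amplitudes reported for crystalline proteins).  Displacements
are sampled in Cartesian A and converted back to fractional coordinates
without wrapping, so molecules stay intact; diffuse intensity is invariant
either way.  One seeded generator per produced object; seeds are recorded
in output metadata.

Synthetic rotation-series images carry trilinear-interpolated diffuse
signal, optional P*Omega shading (so the correction stage has something to
undo), single-pixel Bragg spikes at integer-hkl reflections within a
rocking tolerance of the Ewald sphere, Poisson noise, and 16-bit clipping
with a saturation count.  What this does *not* emulate: real point-spread
and mosaic peak profiles (spikes are impulses — enough to exercise the mode
filter, nothing more), solvent scattering, background gradients, detector
distortions, absorption, or a physical goniometer geometry.  Passing tests
therefore demonstrate the correctness of the analysis machinery under the
stated statistical models, not the fidelity of any particular experimental
data set.

## Numerical choices

* Grids are dense centrosymmetric integer boxes with a resolution-sphere
  mask; d_min defaults to 1.6 A (overridable; several desk-scale analyses
  here use 2.0-2.5 A to keep run times in seconds).
* Guinier maps may carry slightly negative values from floating-point
  cancellation; they are kept (not clipped) and bounded in tests by
  1e-9 of the mean squared amplitude.
* Mode-filter bins are floor(v/width); the in-memory representative stays
  floating point and is rounded to the raster's integer type on write.
* Integration rounds half-up in index space; merging across images is
  count-weighted.
* Patterson imaginary residue is checked against 1e-9 of the real maximum.
* Liquid-like covariance jitter is 1e-10 max(sigma^2, 1); a factorization
  failure raises with the offending parameters.
* Rotation fits require >= 3 non-collinear atoms; collinear selections are
  rejected (rank test at 1e-9).

## Problem sizes

Desk-scale defaults keep every stage in seconds to a few minutes on one
CPU: 6-20 atom asymmetric units (24-80 atoms per cell, up to 640 in the
2x2x2 supercell), 150-2000 snapshots depending on the statistic, 512^2
pixel images in series of 10, and reciprocal grids of order 10^5 points.
The same code paths scale to real systems; only the inputs change.

## Known limitations

* Flat, normally-incident detectors only; no tilts.
* Laue groups limited to P1 and P4/m (the crystal family of the target
  system); the orbit machinery generalizes but other groups are not wired.
* The anisotropic-displacement (per-atom B) smearing inside structure
  factors is deliberately absent: disorder enters only through the
  ensemble, which is the point of the method.
* No autoindexing, no MTZ, no proprietary detector or trajectory formats.
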