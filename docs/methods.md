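# Methods

This note records the models, conventions, parameter choices and known
limitations behind `axosta`, in the spirit of a package methods
appendix. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Conventions

* **Units.** All lengths are Angstroms internally; the phantom
  generator's geometric parameters carry `_nm` suffixes because
  nanometres are the unit in which axonemal periodicities are usually
  discussed (96-nm repeat, 24-nm picking, 72-nm spacing). The CLI
  accepts nanometres and converts. MRC headers are Angstroms.
* **Orientations.** Intrinsic ZYZ Euler angles in degrees, normalised
  to [−180°, 180°), defining the rotation that maps box-frame vectors
  into the tomogram frame (`v_tomo = R · v_box`). This is implemented
  once, in `axosta.io`, and used by every module. At β = 0 the
  decomposition is degenerate and the third angle is set to zero.
* **Positions.** A particle's position is the physical coordinate of
  its box *centre voxel* (`n//2` per axis). Recentering and residual
  composition are centre arithmetic under this convention.
* **Array layout.** `Volume.data` is indexed `[z, y, x]`; filaments
  run along x in all phantoms.

## The phantom generator

The generator emulates the statistical structure the analysis needs,
not the appearance of real tomograms:

* **Geometry.** Two central singlet rods 32 nm apart carrying
  32-nm-periodic protrusions in two registries staggered by 16 nm; nine
  doublet rods (a denser A-cylinder fused to a lighter B-cylinder — the
  density asymmetry is the A-vs-B marker) on a ring of radius
  72/(2·sin π/9) ≈ 105 nm so that neighbours are 72 nm apart; 96-nm
  repeating units on every doublet with RS1/RS2/RS3 at 0/32/56 nm,
  dynein blobs every 24 nm, and a 48-nm MIP marker inside the A rod.
* **Decorations.** Barrel (between RS1 and RS2), RS2–RS3 cross-linker
  and RS3 scaffold are Gaussian blobs switched per doublet by a
  decoration profile. The mouse default: barrel absent on 1 and 9, low
  on 3, present elsewhere; cross-linker absent on 3 and 8; scaffold on
  2 and 3 only. The human default keeps everything except the barrel,
  which sits on four doublets ({3, 6, 7, 8}); which four is not
  established by a text source, so the assignment flips doublets 2–5
  relative to the mouse (the doublets reported to differ) and is
  explicitly marked unverified and overridable in the docstring.
  "Low" occupancy renders at 50% amplitude; over many averaged repeats,
  amplitude occupancy and frequency occupancy are equivalent, and the
  qualitative present/low/absent scale maps onto a quantitative ratio.
* **Cross-linker and scaffold placement.** The cross-linker sits
  radially past the RS2/RS3 heads and the scaffold on the tangential
  side away from the B tubule. Both choices exist so that each
  feature's occupancy window reads clean background when the feature is
  absent; with blobs wedged between two spokes, the spoke tails alone
  would read as "low" occupancy everywhere.
* **Sliding and the 5–6 bridge.** Curvature is expressed as
  accumulated longitudinal phase shifts of each doublet's repeat train,
  taken from the analytic sliding model with each rod's bend-plane
  lever arm; the rods themselves stay straight. This renders exactly
  the quantity the analysis measures (inter-doublet phase offsets)
  without bending the lattice, which at these box sizes would cost far
  more than it tests. The 5–6 bridge adds a constant 20-nm phase offset
  to doublet 6 plus a connecting density between the rods.
* **Noise and wedge.** White Gaussian noise in real space; SNR is
  defined as var(clean volume)/var(noise), which is conservative
  because most of a phantom is empty. An optional missing-wedge mask
  zeroes the Fourier cone outside a ±`wedge_halfangle` tilt range
  (tilt axis y, beam z). CTF effects are upstream of the emulated
  stage and are not modelled.
* **Twist.** `radial_twist_sd` rotates the doublet ring *relative to
  the central pair* per phantom. This is deliberate: the context
  average is built in the CP-aligned frame, so only ring-vs-CP twist
  can smear it, and a generator that rotated both together would
  silently make the fixed-radial-position control untestable.

What passing tests on these phantoms do **not** show: robustness to
CTF, to non-white noise, to filament curvature within the box, to
picking errors on real membranes, or to the alignment ambiguities of
genuinely low-contrast data.

## Pipeline stages

* **Picking.** Tracks are piecewise-linear with chord-length arc
  parameterisation; at curvatures ≤ 0.5 µm⁻¹ the chord-vs-arc error
  over one 24-nm step is far below a voxel. Picks sit at arc positions
  0, s, 2s, …; the count is floor(length/s) + 1.
* **Duplicate removal** is greedy by descending score with a KD-tree:
  deterministic, maximal (every removed record violates the distance
  against a survivor), and equal to the exhaustive maximum-score subset
  on separable instances; tests verify both properties.
* **Alignment** maximises masked normalised cross-correlation over an
  exhaustive ZYZ grid (duplicates at β = 0 removed) crossed with an FFT
  translational search, with moving-window normalisation so the mask
  travels with the reference. Ties resolve to the earliest grid pose.
  Sub-voxel shifts come from three-point parabolic refinement. The
  correlation is circular; masks should therefore clear the box edges
  (the provided workflows use a dilated support mask of the reference).
  Coarse-then-fine refinement (8° grid, then 2° after re-extraction at
  the updated pose) recovers ≥95% of poses within one voxel and twice
  the final step at SNR 0.1 — the regime the per-particle stages
  assume. A wedge-aware averaging mode divides the Fourier sum by
  per-voxel wedge occupancy; plain averaging is the default, adequate
  without a wedge.
* **Half sets** split by tomogram parity, not per particle, so shared
  per-tomogram noise cannot correlate the halves.
* **FSC** is shell-wise normalised cross-correlation; resolution is
  the reciprocal of the first crossing below 0.143, linearly
  interpolated between shells. If the curve never drops below the
  threshold the Nyquist limit (two voxels) is reported — identical
  half-maps are a measurement floor, not infinite resolution.
* **Registry classification** assigns each pick the argmax masked
  correlation over k references staggered by the picking interval. The
  references are self-bootstrapped: along one filament, every k-th pick
  shares a registry by construction, so their average is a
  single-registry consensus and its 0/24/48/72-nm shifted copies are
  the reference set. Recentering then maps a per-class landmark (the
  base of RS2, in the real workflow) to the box centre, collapsing all
  classes onto one phase.
* **Focused two-class splitting** is iterative
  assign-to-nearest-class-average under a focus mask, seeded from a
  random split, capped at 25 iterations, converged when <1% of labels
  change. Class means are computed *leave-one-out* during assignment:
  with plain means each particle correlates with its own contribution,
  which freezes the initial random labels into a spurious fixed point.
  A split leaving one class under 5% is flagged degenerate — the
  expected outcome when the stack contains a single registry.
* **Contextual sorting.** Expanded boxes are averaged with no further
  alignment; the angular profile at the ring radius is sampled on a
  band of rings, peaks are detected with a prominence threshold, and
  the peak:trough contrast is measured against a background ring far
  outside the doublet ring (capped at 99). Axis detection requires
  exactly nine peaks at contrast ≥ 3. Axes are remapped into each
  tomogram by line-averaging: each CP record's pose carries the axis's
  transverse offset, and the per-tomogram mean of those carried points
  defines the axis line — stabler than per-subvolume remapping when
  poses are noisy. Doublet numbering proceeds by angle around the CP
  axis from a reference direction, with handedness set by polarity;
  doublet 1 is the axis nearest the reference angle. The convention is
  validated against generator truth; anyone comparing against real
  data should check it against the field's numbering conventions
  rather than assume they coincide.
* **Occupancy** is (feature-mask mean − background) / (RS1-mask mean −
  background); calls are present ≥ 0.75, low in [0.25, 0.75), absent
  below 0.25. The numeric statistic and thresholds are this package's
  quantitative stand-in for qualitative presence calls, and are
  configurable.
* **Multibody PCA.** Each body is locally refined under its mask; the
  12-vector per particle holds both bodies' residual shifts (Å) and
  Euler angles (deg) in the particle frame. PCA decomposes the **raw**
  covariance by default: Å and degrees are numerically commensurate
  here, and the direction of PC1 is then physically interpretable
  (under synthetic sliding it lies within a few degrees of the
  longitudinal axis, and its projections recover the sliding amplitude
  within a few percent). Z-scoring first — sometimes the default
  elsewhere — forces every axis to unit variance and destroys exactly
  that interpretability, so it is available (`standardize=True`) but
  not default. Eigenvector signs are gauged so the largest component is
  positive; explained fractions sum to one, with zero-variance axes
  contributing zero eigenvalue rather than failing. Morph bins are
  equal-count projection quantiles (sizes differ by at most one).

## Problem sizes

The canned experiments use: 2-µm single filaments at 20-Å voxels for
picking/classification (about 80 doublet picks or 122 CP picks per
run); 0.53-µm nine-doublet axonemes at 40-Å voxels, twenty per
experiment, for the context and occupancy stages; context boxes of
40³ voxels at 80 Å; 150 particles for the multibody experiments. These
sizes give every measured quantity a comfortable margin over its check
while keeping any single experiment in the seconds-to-a-minute range
on one core.

## Numerical notes and edge cases

* Rotations in `align` are precomputed per grid pose; the ZYZ grid is
  deduplicated by rounded rotation matrix.
* `extract` drops records whose rotated box corners leave the
  tomogram (logged via the returned table length); context boxes use
  `allow_partial=True` and read zeros outside.
* Even-sized boxes rotate about voxel `n//2`; utilities that rotate
  about the geometric centre agree with extraction only on odd boxes,
  which the tests use where the distinction matters.
* `periodicity` returns no dominant period for flat traces and for
  argmaxima on the window edge (not a true local peak).
* The sliding model reports Δ rounded half-up to 0.1 nm and
  accumulates the rounded value when asked for the reporting
  convention (20 × 1.4 = 28 nm); full precision is the default
  elsewhere. With signed curvature the offset negates exactly when the
  bend reverses, because the roles of inner and outer filament swap.
* `remove_duplicates` with distance 0 is the identity; coincident
  records keep the single best scorer.

## Known limitations

* The supervised-registry bootstrap assumes contiguous picks along
  each filament; gaps would desynchronise the every-k-th heuristic
  (real workflows would build references from curated class averages
  instead).
* The angular-profile contrast statistic saturates (cap 99) and its
  absolute value depends on the background ring placement; only the
  fixed-vs-twisted comparison is meaningful.
* Phantom rods are straight; the generator encodes curvature only as
  longitudinal sliding, so bent-filament extraction artefacts are out
  of scope.
* The occupancy statistic assumes feature masks that read clean
  background in the absent state; masks for features crowded by other
  densities would need background-matched controls.
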