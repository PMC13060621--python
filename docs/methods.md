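# Methods

## The problem

Serial crystallography (SX) records diffraction snapshots from many randomly
oriented crystals on a segmented pixel detector. Sub-pixel errors in the
modeled positions and orientations of the detector panels degrade indexing
rates and intensity measurements. The obvious fix — average the
calculated-minus-observed spot offsets per panel and shift the panels by that
amount (a "spot-deviation" method) — is biased: the per-crystal refinement of
cell and orientation absorbs part of any panel offset, so the averaged
residual under-reports the true misalignment and can even paint offsets onto
panels that were never moved. `sxalign` implements the unbiased alternative:
a joint linear least-squares refinement of all per-crystal ("local")
parameters and the shared detector ("global") parameters, reduced with Schur
complements so the solved system has only as many unknowns as there are
detector parameters.

## Model

For crystal *k*, each observed peak paired with a predicted reflection
contributes three weighted measurements:

* `r_fs`, `r_ss` — calculated minus observed spot coordinates, in pixels, on
  the panel containing the observation (σ = 0.3 px);
* `r_e` — the modeled excitation error, the signed distance of the reciprocal
  point from the Ewald sphere under a thin-sphere assumption, in m⁻¹ scaled by
  10⁻⁷ so all three components are comparable (σ = 0.2 after scaling).

The calculated position is the intersection of the diffracted ray
(k + q)/|k + q|, with k = (0, 0, 1/λ) and q = R B h, with the plane of the
observation's panel. Intersecting the *assigned* panel's plane (out-of-bounds
coordinates permitted) keeps the residuals smooth under small geometry
changes, which matters for finite-difference derivatives.

Local parameters are the free cell parameters of the lattice type
(monoclinic: a, b, c, β; triclinic: all six) plus three small orientation
adjustments about the lab axes. Global parameters are translations (mm) and
rotations (degrees) of panel groups in a rigid hierarchy; each group rotates
about its own center (recursive mean of child centers; a panel's center is
the mean of its four corners), and corrections are applied root-to-leaf with
exact rotation matrices composed Rz·Ry·Rx.

With A and B the Jacobians of the measurement vector with respect to local
and global parameters, W = diag(1/σ²), the per-crystal blocks are
Γₖ = AᵀWA, Gₖ = BᵀWA, Cₖ = BᵀWB, and the Schur-reduced global system is

    ( Σₖ Cₖ − Gₖ Γₖ⁻¹ Gₖᵀ ) δg = −Σₖ (BᵀW r − Gₖ Γₖ⁻¹ AᵀW r).

The right-hand correction term vanishes for converged local fits but is
always computed. The reduced matrix never grows with crystal count, so the
solve cost is independent of the dataset size and accumulation is one bounded
update per crystal.

### Constraints

A hierarchy with a parent parameter and per-child parameters of the same kind
is degenerate; sibling parameters of every kind are therefore constrained to
sum to zero at every level, leaving the level above to carry the common
motion. The overall rotation about the beam is unobservable in SX (it only
re-labels crystal orientations) and is gauged to zero. Constraints enter as
Lagrange multipliers on the KKT system

    [ C′ Aᵀ ] [ δg ]   [ b′ ]
    [ A  0  ] [ λ  ] = [ 0  ],

which keeps the parameter registry readable (no elimination). The solved δg
are corrections: applying them to the model geometry cancels the geometry
error, so they carry the opposite sign to an injected perturbation.

### Weak modes

The eigen-spectrum of C′ projected onto the constraint null space is reported
after every solve; eigenvalues below 1e-10 of the largest are flagged with
their dominant parameter combinations. The canonical SX example reproduces
here: with triclinic cells (all six cell parameters free) and whole-detector
out-of-plane tilts active, tilting the detector about x is indistinguishable
from squeezing every crystal along y *if* the excitation-error rows are
removed — the system is then numerically rank deficient (and the
camera-length/cell-scale pairing degenerates the same way). The excitation
errors depend only on crystal and beam, never on the detector, which is
precisely why including them breaks the degeneracy; this geometry-independence
is asserted exactly (those Jacobian rows are hard zeros).

## The local fit

Per crystal, an iterated weighted Gauss–Newton update (Γ δa = −b) with the
pairing held fixed, stopping when the largest shift falls below 1e-8 in
native units or after 10 iterations. Derivatives are central finite
differences (1e-4 Å for lengths, 1e-6 rad for angles and rotations, 1e-3 mm
for detector translations), with steps halved if they leave the cell-validity
domain. Convergence implies ‖b‖∞ ≈ 0, which is what justifies dropping the
Schur right-hand correction term. Crystals whose local normal matrix is
singular, or with fewer measurements than parameters, are flagged and
excluded from accumulation.

Peak–reflection pairing is greedy nearest-neighbour on the same panel in
ascending pixel distance, one-to-one, with a 10 px cutoff and deterministic
tie-breaks. For simulated data the generator's ground-truth pairing can be
used instead; both modes are available and give matching recoveries within
statistical tolerance (cross-validated in the tests). The greedy stand-in is
not claimed to be equivalent to any production indexing pipeline's pairing
rules.

## The sketch simulator

`simulate_dataset` emulates the stated experiment: four 1024×1024-pixel
panels (100 µm pixels) tiling the quadrants around the beam at 100 mm camera
length, a 9 keV beam (1.3776 Å), and a primitive monoclinic cell a = 123,
b = 45, c = 80 Å, β = 97°. Per pattern: a uniformly random orientation
(quaternion method, counter-based substream per pattern id so datasets are
reproducible and order-independent), thin-Ewald prediction, independent
Bernoulli(0.5) retention of each reflection (an imperfect peak search), and
rounding of positions to the nearest pixel (peak-search localisation error,
uniform ±0.5 px, σ ≈ 0.289 px). "Select half" is per-reflection Bernoulli
rather than an exact split — a fluctuating count is what an average peak
count implies.

The prediction cutoff on |excitation error| is not printed by any reference;
`DEFAULT_E_MAX = 3.259e6 m⁻¹` was calibrated once by bisection
(`scripts/calibrate_emax.py`) so the stock configuration averages ≈162
retained peaks per pattern (≈324 excited reflections before half-selection),
and is never adjusted afterwards.

What the simulator does *not* model: photon noise, background, spot profiles,
mosaicity/bandwidth partiality, multi-lattice patterns, bad pixels, or a real
indexing algorithm. Indexing is emulated by starting each local fit from the
generating crystal state. A green recovery test therefore establishes that
the *solver* recovers injected geometry errors from realistic peak
statistics; it says nothing about indexing robustness, and quantities that
depend on indexing internals (the exact absorbed fraction in the bias demo)
are reproduced only approximately.

## Numerical choices

* **Outlier rejection.** Records with chi2/ndf above `cutoff` × the median
  chi2/ndf (median floored at 1) are dropped before accumulation, one round,
  default cutoff 4. A relative cut is required because a misaligned starting
  geometry inflates every crystal's chi2 alike; on clean data the floor makes
  the cut act at the nominal absolute value. This is a deliberate
  single-round stand-in for pede's rounds of re-weighted rejection.
* **Units.** mm and degrees end-to-end for global parameters (the Jacobian
  columns are per-degree); Å/degrees/radians for cell lengths/cell
  angles/orientation adjustments. No hidden unit conversions between the
  registry, the solver and the reports.
* **Sign conventions.** Residuals are calculated minus observed; moving a
  panel's model by +x makes the residuals on it negative. Excitation error is
  positive outside the Ewald sphere (only |e| and squares matter, but
  gradient tests need the convention fixed).
* **Rotation-center bookkeeping.** Group centers are recomputed from the
  current geometry before each alignment round; a rotation about the group
  center plus the solved translation is equivalent to the same rotation about
  any other point with a compensating translation (tested), so the choice of
  center is a parametrisation, not a physical assumption.
* **Corner-motion reporting.** Recovered and injected motions are compared as
  displacements of each panel's (0,0) corner plus cumulative rotation angles,
  which makes results comparable regardless of the hierarchy level at which a
  motion was applied; reports from successive rounds add (to first order).
* **Degenerate inputs.** Empty patterns are returned empty and skipped;
  predictions rounding onto a panel edge are dropped; pairs whose modeled ray
  misses the assigned panel plane are dropped for that iteration with a
  warning; a singular constrained system raises an error carrying the
  near-null parameter combinations.

## Known limitations

* The Mille-style binary format is self-consistent (bit-exact float32
  round-trip) but not byte-compatible with the Fortran/C++ ecosystem files.
* The geometry dialect is a documented subset inspired by production geometry
  files; real-world files with masks, distortion maps or non-orthogonal scan
  axes are out of scope (non-orthogonality only warns on load).
* Dense linear algebra throughout: appropriate for tens to hundreds of global
  parameters, not for the thousands seen in high-energy-physics alignment.
* Statistical floors in the stock world (100 patterns × ~162 peaks): solved
  corrections scatter by ~1 µm in-plane, a few µm in z, and ~0.003–0.005° in
  the out-of-plane tilts; two-iteration recovery residuals of that size are
  expected, not defects. Without the excitation terms the z direction softens
  further (camera length vs cell scale), to roughly ±15 µm.
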