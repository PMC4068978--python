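# Methods

This note documents the models, conventions and numerical choices behind
`casttrack`, and what its synthetic validation does and does not demonstrate.

## Measurement model

The pipeline assumes each tooth crown moves as a rigid body between
timepoints, that the casts are metrically true (no scale estimation), and
that the non-treated teeth are stationary and can anchor the timepoints to a
common frame. Under those assumptions a tooth's displacement is a single
rigid motion, recovered by point-to-point registration and decomposed into
six clinically named degrees of freedom.

**Rigid fit (Kabsch).** For row-paired point sets the least-squares rotation
comes from the SVD of the centered cross-covariance; a reflection in the SVD
solution is corrected by flipping the smallest singular direction, so the
result is always a proper rotation. Inputs with a rank-deficient
cross-covariance (fewer than 3 points, collinear configurations) raise a
degeneracy error rather than returning an arbitrary rotation.

**Trimmed ICP.** Correspondences are nearest neighbours in a k-d tree
(exact-distance ties resolved to the lowest reference index, for
reproducibility); at each iteration the `trim_fraction` worst-distance pairs
are discarded and the rigid fit is re-solved on the survivors. The trimmed
RMS is non-increasing and iteration stops when its relative change falls
below `rel_rms_tol` (default 1e-8), when it falls below an absolute floor of
1e-12 mm (far below any physical residual), or after `max_iterations`
(default 100). The default `trim_fraction` of 0.1 absorbs modest
non-correspondence between casts (gingival points, cast-base differences);
it is a configuration parameter, not a constant. Point-to-point (rather
than point-to-plane) residuals were chosen because the clouds are dense and
the point-to-point objective is directly checkable against brute-force
oracles.

**Per-tooth initialization.** A crown is a compact, nearly convex shape, and
centroid-aligned ICP reliably converges only for rotations up to roughly
20°; clinically planned rotations reach 30–35°. The per-tooth measurement
therefore seeds ICP from a small candidate grid — identity plus rotations of
±10°, ±20°, ±30°, ±40° about each patient-frame axis, each with
centroid-matching translation — runs a short trimmed-ICP burst per candidate
and polishes the lowest-RMS one to convergence. The final trimmed RMS
separates the true optimum from the stall cleanly (observed ≈0.04 mm vs
≈0.36 mm at 20 µm noise). This is a structured *local* initialization over
the clinically bounded movement range, not a global search; movements beyond
about 45° are outside the measurement envelope. Whole-cast superimposition
keeps plain centroid initialization, since scanner poses differ only
modestly and the full arch is strongly asymmetric.

**Patient frame.** z is the unit normal of the least-squares plane through
the reference-tooth centroids; its sign (occlusal side) is not derivable
from centroids alone, so `build_frame` takes an `occlusal_hint` vector
(default +z, the crowns-up convention in which scans are stored; callers
superimposing arbitrarily posed casts pass a hint, and the hint only needs
the correct hemisphere). x is the tangent of a quadratic arch curve fitted
to the reference centroids in the occlusal plane's principal coordinates,
evaluated at the moved tooth and signed away from the arch midline (distal);
y = z × x. The frame origin is the moved tooth's T1 crown centroid — the
rotation center is not observable from crowns alone, and translation
components depend on it, so it is fixed and documented here. Note that a
sign flip of z flips the measured signs of R_y and R_z for both the achieved
and the planned movement, so the efficacy ratio is invariant to it.

**Decomposition.** The recovered rotation is re-expressed in the frame basis
(R' = BᵀRB) and factored with the fixed-axes x→y→z convention,
R' = R_z(γ)R_y(β)R_x(α); translations are the frame components of the frame
origin's displacement. The studied movements are dominated by a single axis,
so cross-convention differences are second order, but one convention must be
pinned for reproducibility. At gimbal lock (|R_y| = 90°) α is set to 0 by
convention and a warning is raised.

**Efficacy.** Signed percentage of the planned movement achieved on the
group's primary component (distalization → T_x, torque → R_y, derotation →
R_z). The planned value is *measured* from the ClinT2 scan by the identical
pipeline rather than read from the manifest, so any systematic measurement
bias cancels in the ratio. Off-axis components are reported but not scored.
A zero planned movement makes the ratio undefined and raises an error (the
study design guarantees substantial planned movements).

## Synthetic cohort

The generator emulates the study conditions: an upper arch of 14 labelled
crowns on a parabolic curve, one moved tooth per hemiarch (split-mouth, the
movement performed in isolation), planned magnitudes drawn uniformly from
intervals whose midpoints equal the protocol's mean planned movements
(derotation 17.8°/20.1°, distalization 2.7/2.6 mm, torque 16.1°/15.9°) with
the interval tops at the protocol maxima, staging fixed per subgroup and
capped at the protocol limits (2°/aligner derotation, 1°/aligner torque,
0.25 mm/aligner distalization), isotropic Gaussian scanner noise of
σ = 20 µm, and per-movement true efficacy drawn from a normal distribution
truncated to [−0.25, 1.25] — wide enough to admit the negative and >100 %
outcomes observed clinically — with subgroup means and SDs matching the
reference cohort's accuracies (0.375/0.30, 0.424/0.30, 0.884/0.20,
0.869/0.20, 0.491/0.20, 0.515/0.20). The protocol table also quotes a mean
torque staging of 1.2°/aligner, which exceeds the protocol's own 1°/aligner
cap; the cap wins here and torque defaults to 1.0°/aligner. T2 and ClinT2
additionally receive a modest random global pose (≤5°, ≤5 mm) emulating
independent scanner placement.

Crowns are superellipsoid point samples (400 points/tooth by default):
incisors faceted and blade-like, premolars round in cross-section (the shape
that makes clinical derotation hard), molars large and boxy. Crown half-widths
follow standard odontometric proportions. Only one magnitude is drawn per
config per patient; compliance is recorded as the protocol's 22 h/day.

What the simulator does **not** model: gingiva and palate, impression/cast
distortion, per-tooth segmentation errors, drift of the reference teeth
(reciprocal anchorage loss), occlusion/shadowing in scanning, and anatomical
crown detail. Passing the recovery tests therefore demonstrates the
*measurement machinery* — registration, frame construction, decomposition,
statistics — is correct and noise-stable at scanner-grade noise; it does not
certify accuracy on real casts, where segmentation quality and reference-
tooth stability dominate the error budget.

## Statistics

Per-subgroup summaries report mean/highest/lowest efficacy in percent and
the sample SD (n−1) of the efficacy *ratio* — i.e. sd = 0.2 means 20
percentage points; this mixed unit convention is stated wherever the tables
are emitted. Normality is assessed with Shapiro–Wilk and planned-vs-achieved
differences with the two-sided paired t-test (both delegated to
`scipy.stats`; the paired t is negative under systematic under-achievement).
Overall efficacy is the *unweighted* mean of subgroup means, so each
condition contributes equally regardless of dropout; the derotation splits
assign boundary values (exactly 15°, exactly 1.5°/aligner) to the lower bin
— the printed convention is strict inequality with no boundary rule, so a
closed-lower rule is fixed for determinism. No multiple-testing correction
and no mixed-effects modelling of the split-mouth correlation are applied,
matching the analysis the tables summarize.

## Problem sizes and tolerances

The test suite and the acceptance script simulate cohorts of 10 movements
per subgroup (the study size) for cohort statistics and 25 per subgroup
(50 per movement group) for parameter-recovery checks, at 400 points per
tooth. At these sizes the pipeline recovers achieved movements with a mean
absolute error of about 0.02° (rotations) and 0.002 mm (translations)
against exact ground truth, and per-movement efficacy to about 0.1
percentage points. On-disk scans are double-precision PLY so that the
write→read round trip is exact to well below 1e-6 mm; STL input is
deduplicated at 1e-9 mm. Rigid transforms are validated to orthonormality
1e-9 in memory and 1e-6 on JSON read (with re-orthonormalization of the
float round-trip), and reflections are rejected everywhere.

## Known limitations

- Rotation centers are fixed at crown centroids; clinical torque about the
  root apex maps to a crown-centroid rotation plus a translation, so
  translation components are convention-dependent.
- The occlusal sign of the frame requires a hint for arbitrarily posed
  scans (default: crowns-up storage).
- The measurement envelope for a single tooth is about ±45° of rotation;
  beyond that the initialization grid would need to grow.
- Reference-teeth drift is assumed zero by construction in the simulator
  and by assumption in the measurement.
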