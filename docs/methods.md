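# Methods

This note documents the models implemented in `aortaflow`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate, and
the numerical conventions that matter when interpreting results.

## Signal model and turbulence estimation

4D flow MRI with four-point asymmetric motion encoding yields one
motion-compensated magnitude volume |S| and three encoded volumes |Sᵢ| per
timeframe. Intravoxel velocity fluctuations attenuate the encoded
magnitudes; for a Gaussian intravoxel velocity distribution with standard
deviation σᵢ along encoding direction i,

    |Sᵢ| = |S| · exp(−k_v² σᵢ² / 2),     k_v = π / VENC.

The estimator inverts this: σᵢ² = (2/k_v²)·ln(|S|/|Sᵢ|), and
TKE = ½ ρ Σᵢ σᵢ² with ρ = 1060 kg/m³. Two conventions matter:

* **Signed σ².** Rician noise can push |Sᵢ| above |S|; clamping σ² at zero
  would bias regional TKE upward. σ² is therefore kept signed, and a
  regional TKE can average slightly negative — read as "zero within noise".
* **Validity regime.** The model requires σ < VENC; the phantom generator
  rejects specifications outside it.

The generator encodes magnitudes with exactly this attenuation law, so the
noise-free encode → decode round trip is an identity to machine precision —
that identity is the primary correctness oracle for the turbulence stage.

## Helicity and vorticity

Vorticity is computed by finite differences restricted to the lumen mask:
central differences where both axis neighbours are inside, one-sided where
only one is, undefined otherwise (undefined voxels are flagged, never
zero-filled). The absolute local normalized helicity
LNH = |V·ω|/(|V||ω|) ∈ [0,1] by Cauchy–Schwarz. Voxels with
|V||ω| below a configurable floor (default 10⁻⁶ m·s⁻²) are excluded from
regional averages rather than set to 0, since 0/0 carries no directional
information; exclusion counts are reported.

The phantom's swirl is a forced vortex (solid-body rotation,
v_φ = swirl·W₀·r/R) because its LNH has closed forms: with a plug axial
profile, LNH = W/√(W² + Ω²r²) exactly, giving 1 on the axis and 1/√2 where
Ωr = W. With the default parabolic (Poiseuille) axial profile and no swirl,
velocity is everywhere orthogonal to the (azimuthal) vorticity and LNH ≡ 0.

A property worth knowing: the cross-section mean LNH of the forced-vortex +
Poiseuille tube is **not monotone** in the swirl ratio over [0, 1]. It rises
steeply (≈0 → 0.94 between swirl 0 and 0.5), peaks near swirl ≈ 0.65, and
declines slightly toward swirl 1 (≈0.91 in the continuum limit) because the
velocity vector tilts away from the axial vorticity faster than the helical
alignment grows. The package's monotonicity tests therefore cover the rising
branch {0, 0.25, 0.5}, which brackets the cohort's swirl range (~0.2–0.6).

## Geometry pipeline

* **PC-MRA**: √(mean_t(|S|²·|v|²)) — bright where flow is fast and signal
  strong, zero in static tissue.
* **Segmentation**: Otsu threshold → largest 6-connected component →
  1-voxel morphological closing. With swirl present the wall speed stays
  well above zero, so the Otsu threshold falls in the gap between background
  and lumen intensities and the mask matches the true lumen almost exactly.
* **Centerline**: 3D skeletonization; skeleton voxels form a 26-connected
  graph with Euclidean edge weights; the centerline is the shortest path
  between the skeleton voxels nearest the two anatomical endpoints (aortic
  valve, iliac bifurcation). Two details are load-bearing:
  - *Endpoint anchoring.* A 3D skeleton retreats roughly one lumen radius
    from tube end caps, which would bias both L and D and hence tortuosity;
    the supplied endpoints are prepended/appended to the path before
    smoothing (moving average, window 5, endpoints pinned).
  - *Geodesic attachment.* "Nearest skeleton voxel" is measured by geodesic
    distance inside the mask, not Euclidean distance: when the aorta folds
    back on itself the Euclidean-nearest skeleton voxel can lie in the
    adjacent descending limb, which would short-circuit the path.
* **Landmarks and regions**: the arch top is the most superior centerline
  point (first index on ties); the other landmarks map to the arc length of
  their nearest centerline point. Regions: AAo = [valve, arch top),
  DAo = [arch top, midway(subclavian, renal) in **arc length**),
  SAA = [midway, renal), IAA = [renal, iliac]; lumen voxels are labeled by
  nearest centerline point. Whole-aorta metrics are computed as a fifth
  region spanning valve → iliac.
* **Diameter**: the acquisition protocol for a "diameter" is genuinely
  underdetermined, so the package defines it as the equivalent-circle
  diameter of the mean cross-section, D = 2√(A/π) with A = region volume /
  region centerline length.

## Preprocessing

Phase wraps are corrected by comparing each velocity component against the
median of its 6-neighbourhood: voxels off by more than VENC are shifted by
2·VENC toward the median, iterated to convergence (max 5 passes). Background
phase offsets are removed by a weighted least-squares polynomial fit (total
degree ≤ 4 by default) to static tissue, with the time-mean reference
magnitude |S| as weights (down-weighting noise voxels) and monomials
evaluated on coordinates scaled to [−1, 1] for conditioning. Static tissue is
selected by temporal standard deviation of speed below 0.05·VENC and mean
magnitude above an Otsu noise floor. The fit uses the time-averaged velocity
by default (offsets are quasi-static); per-timeframe fitting is available.
Degree-≤4 offsets over static tissue are removed exactly on noise-free data,
and the correction is idempotent. Slowly moving near-wall lumen voxels can
enter the static mask when flow is present; their influence on the fit is at
the 10⁻³ m/s level and the exact-removal guarantee is stated for flow-free
static tissue.

## Synthetic phantoms and cohorts

Geometries: straight tube, circular arc and helix (closed-form L, D,
tortuosity — the analytic oracles), and an `aorta_like` candy cane: a
circular arc from valve to arch end (the valve sits `arch_angle` radians
before the apex) joined to a descending limb with a sinusoidal in-plane
perturbation whose amplitude ramps from a thoracic to an abdominal value.
Ground truth for the candy cane (lengths, landmark positions, regional
tortuosity) is computed by dense quadrature at 0.05 mm steps. Sampled
geometries whose ascending limb would come within two voxels of the
descending limb are rejected as invalid and resampled, since a self-touching
voxelized lumen has no well-defined centerline.

Flow: parabolic or plug axial profile × a smooth single-peak systolic
waveform (peak at 25% of the cycle, diastolic baseline 0.15), plus the
forced-vortex swirl. Noise: Rician on magnitudes (SNR = baseline
magnitude / complex noise scale); optional additive Gaussian velocity noise
with sd VENC/(SNR·π). All randomness flows from explicit integer seeds.

The default two-group cohort emulates a young/old study design at roughly
half anatomical scale (arch radius 18 mm, descending limb 90 mm, lumen
radius 7 mm young / 8.5 mm old) with the acquisition's 2.5 mm isotropic
voxels and, for cohort work, 20 timeframes — sizes chosen so a full 10+10
cohort analysis runs in seconds per cohort on one CPU. Older subjects get a
larger arch angle, larger limb perturbations, wider lumens and slower flow;
two coupling rules tie swirl positively to the arch angle (tortuous aortas
carry more helical flow) and σ positively to peak velocity (faster flow is
more disturbed). Consequences: old cohorts have higher tortuosity and
helicity, lower TKE, velocity and Reynolds number — the qualitative
structure the statistics layer is asked to recover.

Two calibration caveats, both deliberate:

* At 2.5 mm voxels on a half-scale aorta, sub-voxel centerline undulations
  are destroyed by voxelization and skeleton smoothing. The old group's limb
  perturbation amplitudes (4–4.5 mm, wavelength 36 mm) are therefore larger,
  relative to scale, than elderly human abdominal tortuosity; with
  physiological amplitudes the SAA/IAA ordering would be unmeasurable at
  this resolution, not absent.
* Absolute cohort values (velocity ≈ 0.28–0.49 m/s region means, Re ≈
  1500–1900, TKE ≈ 6–20 J/m³) are in the physiological ballpark but are not
  calibrated to any particular human cohort; only orderings, signs and
  correlation structure are claims the tests make.

What passing tests on phantoms do **not** show: performance under real
acquisition physics (k-space sampling, SENSE, eddy currents, concomitant
gradients beyond polynomial offsets), wall motion and compliance, branch
vessels, valve-jet inflow (the reason ascending-aorta correlations behave
differently in humans is absent here), or secondary-flow physics
(Dean vortices) — the swirl is prescribed, not emergent.

## Statistics

Group comparisons are gated by Shapiro–Wilk at α = 0.05 per group: both
normal → Welch (unequal-variance) t-test, otherwise Mann–Whitney U (exact
for group sizes ≤ 20 without ties, normal approximation with tie correction
above). Summaries follow the test family: mean ± sd when normal, median
[q1, q3] otherwise. Spearman ρ is the Pearson correlation of mid-ranks; its
p-value uses exact permutation enumeration for n ≤ 10 (the null distribution
is cached per rank multiset) and the t-approximation above. Interpretation
bins on |ρ| are left-closed: [0, 0.2) very weak, [0.2, 0.4) weak, [0.4, 0.6)
moderate, [0.6, 0.8) strong, [0.8, 1] very strong. TKE regressions are OLS
with intercept: TKE ~ Helicity, TKE ~ Velocity, and the two-predictor model,
fit per region and per subset (Young, Old, pooled). No multiple-testing
correction is applied by default (α = 0.05 throughout). Velocity and
Reynolds numbers are averaged over the systolic window by default.

## Numerical conventions and degenerate inputs

Coordinates are millimetres with voxel-center convention (mm = 0-based index
× spacing); gradients convert to metres so vorticity is in s⁻¹. Peak-systole
ties resolve to the earliest frame; the ±5% window is cyclic and closed
(a frame exactly at the boundary is included), so a T-frame acquisition
yields ⌊0.1T⌋ to ⌈0.1T⌉+1 window frames. Tortuosity is undefined (error) for
chords below 1 nm; empty regions, empty static masks, rank-deficient
polynomial designs, disconnected skeletons and zero-variance correlation
inputs all raise informative errors rather than returning numbers.

## Known limitations

* The centerline from a 2.5 mm skeleton carries a tortuosity noise floor of
  roughly 1–2% on straight segments and underestimates tortuosity in tightly
  curved segments (measured ascending-aorta tortuosity runs ~5–8 points
  below the analytic value); group orderings survive, absolute regional
  tortuosity should be read with that bias in mind.
* The diameter definition differs from clinical caliper measurements on
  reformatted planes; values are consistent within the package but not
  directly comparable to radiological reports.
* The exact-permutation Spearman p enumerates n! permutations; n = 10 costs
  a few seconds (cached thereafter), larger n falls back to the
  t-approximation by design.
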