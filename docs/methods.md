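# Methods

## Signal model and unmixing

The forward model treats each voxel's photoacoustic amplitude at wavelength
λ as

    PA(λ, r) = Γ · F(λ, r) · (C_HbO₂(r) ε_HbO₂(λ) + C_Hb(r) ε_Hb(λ)) · E/E₀ + ε

with Γ the (dimensionless) Grüneisen parameter, F the local optical fluence,
C the molar concentrations of oxy-/deoxy-haemoglobin (mol/L), ε(λ) the molar
extinction coefficients (cm⁻¹ M⁻¹), E the recorded per-frame laser pulse
energy relative to nominal E₀, and ε additive noise. Fluence is modelled as
a separable depth decay, `F = F₀(λ)·exp(−μ_eff(λ)·d)` with d the depth below
the probe face (the image row coordinate). The default configuration sets
equal F₀ and equal μ_eff at both wavelengths: in breast tissue the
absorption and reduced-scattering coefficients at 750 and 830 nm are close
enough that, after laser-energy normalization, the fluence ratio between
wavelengths is approximately one. Under that assumption the two-wavelength
ratio estimator (see README) is algebraically exact — a property the test
suite checks to machine precision — and unequal attenuation settings let
tests probe how the estimator degrades when the assumption is violated.

Oxygen saturation is defined as `SO₂ = C_HbO₂ / (C_HbO₂ + C_Hb)`; it is
undefined where total haemoglobin is zero.

### Invalid-pixel policies

The estimator is a ratio and noise can push it outside [0, 1]:

* **Negative estimates** are removed (marked NaN).
* **Over-unity estimates** in (1, 1 + δ] with δ = 0.05 (configurable) are
  clipped to 1; above 1 + δ they are removed. This mirrors the negative
  removal symmetrically and keeps regional means inside [0, 1].
* **Background floor**: voxels whose amplitude at *both* wavelengths falls
  below a configurable per-stack quantile (default 1st percentile) are
  removed — the ratio of two near-zero amplitudes carries no oxygenation
  information. How zero-signal voxels should be distinguished from genuine
  low-SO₂ voxels is underdetermined by the physics; this floor is this
  package's choice and is recorded in the SO₂ volume's JSON sidecar.

Invalid voxels are always NaN, never zero, so they can never leak into a
mean.

### Extinction coefficients

No single canonical ε table exists; values shipped in
`paquant/data/hb_extinction.csv` follow the standard compiled near-infrared
haemoglobin spectra used in photoacoustic oximetry and carry a version tag
that is copied into every output sidecar. The test suite pins its own
fixture table so that test expectations are independent of future updates
to the shipped file. At 750 nm deoxy-Hb must absorb more strongly than
oxy-Hb and at 830 nm the reverse; the table loader enforces this as a
sanity check.

## Region geometry

Tumour boundaries enter as per-slice closed polygons (physician contours in
a real acquisition; analytic ellipsoid cross-sections, 64 vertices per
slice, in the synthetic one). Coordinates are physical millimetres with the
origin at the first voxel centre; a voxel belongs to a region iff its
centre lies inside (or on) the polygon/surface. Rasterized masks therefore
converge to the analytic region volume as voxel size shrinks (verified at
three resolutions).

The **least-volume enclosing ellipsoid** is fitted to the union of contour
vertices across slices — the boundary alone determines the enclosing
ellipsoid, and the vertex set is orders of magnitude smaller than the voxel
mask. The fit solves the dual D-optimal design problem by Khachiyan-type
iterative reweighting. The implementation uses the Wolfe–Atwood refinement
(away steps on the active support): plain first-order reweighting converges
only sublinearly and cannot reliably reach tight tolerances within a
bounded iteration count, whereas the away-step variant converges linearly
and reaches the default duality-gap tolerance of 1e−6 in a few hundred
sweeps. The iteration cap (10⁴) raises an explicit error rather than
returning a silently unconverged ellipsoid. The returned ellipsoid is
inflated minimally (≤ 1 + tolerance) so that containment of every input
point is exact. The optimum is unique, so two runs from different initial
weightings agree — the property that makes the ROI construction repeatable
— and the fit is affinely equivariant; both are property-tested.

The **extension ellipsoid** scales each semi-axis by 1.2 (volume × 1.728)
about the same centre and orientation; the **surrounding region** is the
set difference (inside extension, outside tumour mask), clipped at the
volume bounds with the clipped fraction reported. The **contralateral ROI**
reflects ellipsoid and mask across a sagittal plane (default: the lateral
midline of the volume); how two separately acquired breasts should be
registered is not defined by the acquisition, so the mirror plane is a
per-case user choice.

## Biomarkers

The regional biomarker is the volumetric mean SO₂ over voxels that are
finite and **≥ 0.40** (inclusive). The 40% lower threshold suppresses
noise artefacts: breast-tumour SO₂ does not normally fall below 40% in
small, non-necrotic lesions, so lower estimates are treated as artefactual.
The vessel mask for 3D rendering uses the *strict* window 0.40 < SO₂ < 1.00;
the two rules are stated differently and are deliberately kept distinct. A
region with no qualifying voxel is flagged unevaluable (NaN) and the case is
excluded from that comparison downstream, with a log entry — never silently
scored as zero. Raising the threshold can only raise the mean
(property-tested monotonicity).

## Statistics

* **Mann-Whitney U**, two-tailed, with U = #{aᵢ > bⱼ} + ½·ties. For
  tie-free samples with n₁n₂ ≤ 10⁴ the exact null distribution is computed
  by the standard counting recurrence; otherwise a normal approximation
  with tie correction and continuity correction is used. The exact branch
  is cross-checked in tests against both full permutation enumeration and
  an independent reference implementation.
* **Hodges-Lehmann**: point estimate = median of all pairwise differences;
  the CI inverts the U test, taking order statistics of the pairwise
  differences at the exact critical ranks. The interval is distribution-free
  with coverage ≥ the nominal level; simulation at n = 8 vs 16 puts
  empirical 95% coverage near 94–95%.
* **ROC**: positivity direction is fixed to "lower SO₂ ⇒ malignant". The
  threshold sweep visits −∞ and every distinct score; sensitivity counts
  positives at or ≤ the cut-off (a case exactly at the cut-off is called
  positive). The trapezoid AUC equals the Mann-Whitney concordance
  U/(n₁n₂) identically — ties contribute the diagonal segments — and tests
  require agreement to 1e−12. Reported cut-offs are user-supplied (defaults
  78.2% for tumour, 77.9% for surrounding) plus the Youden-optimal one.
* **Size-matched subgroups**: bins are (group, size interval, quota); the
  enumeration emits the Cartesian product of per-bin combinations in
  lexicographic order. One bin choosing 2 of 10 cases yields C(10,2) = 45
  subgroups. No multiple-testing correction is applied; the number of
  comparisons is recorded in the outputs.

## Synthetic phantoms

Real swept-probe breast PA volumes are not publicly available, so the test
surface is synthetic. A phantom is a voxel grid (default 200 slices at
0.2 mm — a 4 cm sweep — by 120 × 128 voxels at 0.3 mm, i.e. 36 mm depth and
38.4 mm width, matching a 192-element linear probe) carrying:

* a **background** at 20 µM total haemoglobin, SO₂ 0.75 — diffuse tissue
  signal;
* an **ellipsoidal tumour** (100 µM) with per-case SO₂;
* an optional **peri-tumoral shell** between the tumour surface and its
  1.2×-scaled copy (40 µM) with its own SO₂ — the altered peri-tumoral
  microvascular environment that makes the surrounding region informative;
* **vessel capsules** (cylinders with hemispherical caps, 150 µM ≈ whole
  blood, radius 0.8 mm) threaded through the peri-tumoral shell; overlaps
  resolve "last segment wins".

Cohort simulation draws, per case, tumour diameter uniform over the size
range, a random orientation, tumour SO₂ from the group's truncated normal
(defaults: benign 0.785, malignant 0.708 — a 7.7-point deficit — sd 0.03)
and shell/vessel SO₂ from the surrounding distributions (benign 0.785,
malignant 0.736 — a 4.9-point deficit). Per-frame laser energy jitter is
2% (relative sd) and additive Gaussian noise 5% of the mean noise-free
signal; neither is stated by any acquisition standard, so both are exposed
in the configuration. All randomness derives from one seed through spawned
per-case substreams, so cohorts are reproducible case by case and any seed
below 2³¹ is valid.

**What the phantoms do not emulate**: acoustic propagation, transducer
bandwidth, reconstruction (delay-and-sum) artefacts, limited-view vessel
bias, speckle, heterogeneous fluence beyond a separable exponential, or
physician inter-observer contour variability. Passing tests therefore
establish the correctness of the quantification chain given co-registered
amplitude images — not the fidelity of any reconstruction, nor clinical
performance on patient data.

## Problem sizes and numerical choices

Cohort-level tests and the acceptance script run the pipeline on reduced
grids (40 × 48 × 56 voxels at 0.5 mm, tumours 6–10 mm) — the package's
choice of a resolution at which every stage is still exercised while a
hundred cohort replicates remain cheap; the phantom defaults above remain
full scale. Group-level SO₂ distributions, noise and jitter levels, and
group sizes (8 benign vs 16 malignant) are identical at both scales.

Degenerate inputs fail loudly and specifically: coplanar contour vertices
raise a rank-deficiency error from the MVEE; empty samples, single-class
ROC inputs and geometry mismatches raise data errors; a tumour whose distal
margin exceeds the configured imaging depth (default 3.5 cm — beyond which
light attenuation makes the measurement unreliable) is rejected per case
and logged, and a run fails only if every case fails. Ties at the ROC
cut-off count as positive; the 40% mean threshold is inclusive; the vessel
window is strict on both ends.

## Known limitations

* Haemoglobin *concentration* is not quantified — only the saturation
  ratio; absolute quantification would require a fluence map.
* Two wavelengths resolve exactly two chromophores; no multi-wavelength
  unmixing.
* The equal-fluence assumption biases SO₂ when spectra of overlying tissue
  differ between wavelengths; the forward model can simulate this, but the
  estimator does not correct it.
* Contralateral "symmetric location" mirroring assumes the two breasts were
  acquired in mirrored frames; no nonrigid registration is attempted.
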