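# Methods

## Optical model

The illumination arm is modelled as a scalar monochromatic field obeying the
Helmholtz equation, decomposed into plane waves and advanced between optical
elements in the angular-spectrum domain:
`E(x, z+d) = IFFT{ FFT{E(x, z)} · exp(i·k_z·d) }` with
`k_z = √(k² − k_x²)`, `k = 2πn/λ`. Components with `k_x² > k²` are
evanescent over the centimetre-scale distances involved and are set to zero
rather than decayed exponentially. The model is 2D (one transverse axis plus
propagation); with power-of-two grids every step is a pair of FFTs, and
total power over propagating components is conserved to better than one part
in 10⁹ through an arbitrary train (verified as a property test).

The source is a Gaussian that has picked up the cubic phase of a spatial
light modulator, `E₀(x) = A·exp(−x²/w₀²)·exp(i·(α/3)·x³)`. Lenses are thin,
`T(x) = exp(−i·(2π/λ)·x²/2f)` — a pure phase element, so power is conserved
exactly. The default train mirrors a bench layout: seven lenses
(f = 75.6, 40, 3.5, 1.2, 7.5, 30, 2 cm), the source one focal length before
the first lens and consecutive lenses separated by the sum of their focal
lengths. Default sampling is a 2²⁰-point grid at 0.2 µm transverse pitch.
At these settings the Gaussian envelope (w₀ = 4.3 mm) decays to ~10⁻⁹ in
amplitude well before the region where the cubic and lens phases would
alias, so the FFT sampling is safe despite the grid spanning ±10 cm.

The thin-lens phase is parabolic, i.e. paraxial. It is accurate for every
lens in the train (per-lens NA ≤ 0.03), but a *reference* Gaussian focused
to a 1.2 µm waist implies NA ≈ 0.13, where the parabolic phase carries tens
of radians of spherical aberration. The Gaussian reference is therefore
injected as the analytic converging Gaussian-beam field
(`make_gaussian_beam_field`) and then handled by the same propagation and
metrology code.

## Beam metrology

* **Main-lobe diameter.** The "1/e beam diameter" of a lobe is measured by
  walking outward from the lobe peak to the first crossings of a threshold
  and interpolating linearly. Two conventions are offered: `field` (the
  default; threshold `peak·e⁻²` in intensity, i.e. 1/e in field amplitude —
  the convention under which a Gaussian's diameter is `2·w(z)` with
  `w(z) = w₀√(1+(z/z_r)²)`, `z_r = πw₀²n/λ`) and `intensity` (threshold
  `peak/e`). A profile with a single supra-threshold sample reports one
  pitch (degenerate floor).
* **Lobe tracking.** Across axial planes the tracked lobe is the local
  maximum nearest the previous plane's centre (the first plane uses the
  global maximum), which prevents jumps between Airy side lobes. The tracked
  centre follows the expected parabolic trajectory of a self-accelerating
  beam (R² > 0.99 over the focal corridor in the tests).
* **Diffraction-free path.** Longest contiguous axial interval over which
  the tracked diameter stays within √2 of its minimum over the map — the
  Gaussian-confocal analogue, under which an ideal Gaussian focus scores
  exactly 2·z_r (the scaled reference returns 18.25 µm against
  2·z_r = 18.54 µm). A 3-plane median filter on the diameter track is
  applied first: near-merged side lobes can flip in and out of the
  first-crossing walk at single planes, and without smoothing those flips
  split the corridor at grid-dependent positions.
* **Waist location.** The plane of minimum (smoothed) tracked diameter,
  taken directly — no sub-pitch fitting, because the diameter of a
  cubic-phase beam is strongly asymmetric about its collapse point and a
  local parabola fit biases the estimate by tens of micrometres.

The production pipeline (`simulate_airy_sheet`) propagates the source
through the train once, locates the waist on a coarse scan (4 µm pitch) of
the 4 mm output range around the last focal plane, then maps a 400 µm
window at 1 µm axial pitch around the waist and measures the corridor
there. All scans re-use one stored spectrum (per-plane spectral phase
advance), and the stored map is cropped transversely around the beam. With
the default parameters the corridor is 205 µm with a ~6 µm minimum main
lobe; the matched Gaussian reference manages 2·z_r ≈ 18.5 µm — an
order-of-magnitude difference.

## Image formation and deconvolution

The detection PSF is the scalar Born–Wolf pupil integral
`h(r, z) = ∫₀¹ J₀(k·NA·r·ρ)·exp(−i·k·z·NA²ρ²/2n)·ρ dρ`, evaluated on a
radial table per defocus plane and normalised to unit sum; defaults are
NA 0.7 and λ = 0.525 µm (centre of a 525/50 emission band). Vectorial
effects are ignored — at NA 0.7 the scalar lateral FWHM (0.514·λ/NA) is
within a few percent of the vectorial value, sufficient for synthetic
resolution studies. The light-sheet system PSF multiplies the detection PSF
along the detection axis by the illumination-sheet profile (a transverse cut
through the beam map at the working propagation distance; uniform scanning
averages the beam along the in-plane direction) and renormalises.

Bead stacks are rendered as `expected = Σ brightness·(raster ∗ PSF) +
background`, with spheres volume-rasterised at 4× sub-voxel resolution
(normalised to unit sum, so a bead's brightness is its total expected
photon count), optional Poisson noise under a fixed seed, and no read
noise by default. FWHM measurement refines the peak within 1 µm of a seed
point, subtracts the median of the border voxels as background, and
interpolates the half-maximum crossings; an object whose profile never
falls below half maximum inside the stack is reported as truncated.

Richardson–Lucy deconvolution runs the multiplicative update with cyclic
(FFT) convolutions on a reflect-padded copy of the stack (one PSF extent per
face). Cyclic updates make a unit-sum PSF conserve total counts exactly on
the padded domain and keep a uniform image an exact fixed point; reflective
padding suppresses wrap-around. Stopping is a fixed iteration count
(default 50) with a 10⁻¹² division guard — the simplest reproducible
contract. On rendered Airy-sheet bead stacks 20 iterations already shrink
every bead's axial FWHM below its pre-deconvolution value and into the
sub-micron regime.

## QPI analysis

Cells are segmented by direct phase thresholding (default 0.4 rad — far
above the phase-noise floor yet low on the soft ellipsoid edge), 8-connected
components with holes filled, minimum area 3 µm², border-touching cells
excluded; LDs by a second, higher threshold (default 1.8 rad) nested inside
each cell mask. Dry-mass surface density follows
`ρ = λ·⟨Φ⟩/(2π·dn/dc)`; with λ in metres and dn/dc in m³ kg⁻¹ the result is
in kg m⁻², and 1 kg m⁻² = 10³ pg µm⁻² (⟨Φ⟩ = 1 rad, λ = 500 nm,
dn/dc = 1.85 × 10⁻⁴ m³ kg⁻¹ → 0.430148 pg µm⁻²). Expression is the cell-mean
fluorescence minus the extracellular background mean (the complement of the
dilated cell union); negative values are reported, not clipped.

The LD's 3D position is a sphere at the 2D mask centroid with
equivalent-area diameter; its z-centre starts at the plane of maximal
in-mask fluorescence and is then refined by minimising the flux-weighted
squared radial residual `(|r−c| − r_LD)²` over a ±0.8 µm grid — the argmax
plane alone is pulled toward a fluorescent cap, which biased coverage
estimates by ~10 percentage points before refinement.

**Localization** is called `localized` when the fraction of above-background
flux inside the spherical shell `r_LD ± margin` exceeds 0.5. The library
default margin is 0.3 µm; the analysis pipeline uses 0.6 µm to absorb the
axial PSF smear of shell-bound signal. Cells without a segmented LD are
diffusive by definition.

**Surface coverage** supports two estimators. `contact` (the library
default) counts surface patches — voxels within half a voxel diagonal of
the sphere — having at least one supra-threshold voxel within a contact
distance (default one voxel diagonal). `radial` (the pipeline default for
blurred stacks) projects above-background flux in the band
`r_LD ± 0.7 µm` radially onto the nearest-angle patch and marks a patch
covered when its accumulated flux exceeds 0.33 × the 95th-percentile patch
flux. Radial projection undoes the radial component of PSF blur; the
relative threshold localises the cap edge under the remaining symmetric
tangential smear. The 0.33 factor was calibrated once on noiseless
single-cap spheres spanning the generator's LD radii and coverage fractions
(bias zero-crossing of the calibration sweep); on full scenes the estimator
recovers coverage with ≈0 mean bias and ~8 points mean absolute error.

**Mann–Whitney U** uses midranks for ties. The exact two-sided p-value
enumerates all labelings of the pooled sample whenever `n₁·n₂ ≤ 400` *and*
the number of labelings is moderate (≤ 2×10⁵ — covering all n₁, n₂ ≤ 8);
otherwise a tie-corrected normal approximation with continuity correction
is used. No multiple-testing correction is applied.

## Synthetic phantoms

Cells are prolate ellipsoids, major axis ~N(5.3, 0.4²) µm, in-plane aspect
ratio U(0.6, 0.85), random orientation, placed by rejection sampling with
non-overlap and a border margin (placement failure after 10⁴ attempts raises
with a suggestion to enlarge the field). Phase is the vertical chord length
times 0.4 rad µm⁻¹ — a typical cell peaks near 1.5 rad — plus each LD's
chord-weighted excess (1.2 rad at centre), so the projected phase integral
has a closed form (ellipsoid volume + π·d²/6 per droplet) used as the
dry-mass oracle. LDs number 0–2 per cell with diameters U(1.2, 2.2) µm,
constrained well inside the cell. Expression is ~N(500, 150²) counts per
voxel (floored at 5% of the mean); cells with an LD are localized with
probability 0.5, in which case all reporter flux sits on a spherical cap of
the LD shell whose area fraction U(0.15, 0.9) is the coverage ground truth;
diffusive cells emit uniformly over their volume. Rendering blurs with a
supplied PSF, adds a 10-count background and Poisson noise under fixed
seeds; every scene is bit-for-bit reproducible from its seed.

The four-bucket QPI round trip models the un-scattered wavefront stepped by
δ ∈ {π/2, π, 3π/2, 2π} against the scattered component of a unit-amplitude
transparent object: `I_k = |e^{iδ_k} + (e^{iΦ}−1)|²`. The standard
arctangent estimator recovers `Φ` from
`Re U_s = (I₀−I_π)/4`, `Im U_s = −(I_{3π/2}−I_{π/2})/4`,
`Φ = arg(1 + U_s)` — exact for |Φ| ≲ 1 rad and accurate until the scattered
amplitude approaches the background.

What the phantoms do **not** emulate: organelle ultrastructure (ER,
vacuoles), partial cap/diffuse mixtures of the reporter, cell motion,
refractive-index heterogeneity inside the cytosol, camera read noise, and
QPI halo/shade-off artefacts. Passing tests therefore demonstrate that the
estimators are unbiased and well-calibrated under the stated geometric and
noise model, not that they are robust to every artefact of real data.

## Problem sizes and numerical choices

The production beam run uses the full 2²⁰-point grid at 0.2 µm pitch with a
4 µm-pitch coarse scan and a 1 µm-pitch 400 µm fine window (~2 minutes,
deterministic). Unit tests exercise the same physics on a scaled single-lens
cubic beam (2¹⁷ points, f = 0.5 cm) whose Airy focal scale is sub-micron.
The end-to-end recovery suite runs 200 four-cell scenes at
(0.12, 0.12, 0.24) µm voxel pitch in a 26 × 26 × 8 µm³ volume — small
enough for a few hundred milliseconds per scene while keeping ≥ 4 voxels
across every LD radius. Convolution is FFT-based throughout; coordinates
refer to voxel centres with 0-based indices; all lengths are micrometres
internally (sources in mm, mask scaling in mm⁻³, focal lengths in cm at the
interface).

## Known limitations

* The corridor length is metrologically fragile for beams whose side lobes
  hover near the 1/e threshold: single-plane lobe merges can re-segment the
  corridor run. The median smoothing bounds, but does not eliminate, this.
* The 2D beam model ignores the second transverse axis; the real mask is
  separable (`x³+y³`), so the 1D profile is representative but absolute
  intensities are not.
* The scalar PSF under-represents vectorial broadening above NA ~0.8 and
  index-mismatch aberrations entirely.
* Exact Mann–Whitney enumeration is capped by the number of labelings;
  large balanced samples fall back to the normal approximation even below
  the `n₁·n₂` bound.
* The coverage estimator assumes one dominant LD per cell (the largest
  segmented LD is analysed) and a sphere fully inside the imaged volume.
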