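# Methods

`neuromre` simulates and analyses multifrequency magnetic resonance
elastography (MRE) of neuroinflammation in mouse-brain-like digital phantoms.
This note documents the models, the numerical choices, and what the synthetic
experiments do and do not establish about real data.

## Physical model

Time-harmonic shear displacement fields `u(x) e^{-iωt}` obey the scalar
heterogeneous Helmholtz equation per coronal slice,

    ∇·(G(x) ∇u) + ρ ω² u = 0,

with density ρ = 1000 kg/m³ (soft-tissue convention, configurable). A medium
is parameterised by its shear wave (phase) speed `c` (m/s; stiffness
surrogate — softer tissue → lower `c`) and the loss angle `φ` of the complex
shear modulus (rad; fluidity surrogate, 0 = elastic solid, π/2 = fluid). The
complex wavenumber is defined so that the wavenumber inversion's target is
exactly the ground truth:

    k = (ω/c)(1 + i tan(φ/2)),   Re k = ω/c,   Im k > 0 (attenuation),

which corresponds to `G = ρ c² cos²(φ/2) e^{-iφ}`, i.e. |arg G| = φ.

This 2D scalar model is the minimal physics that exercises the inversions;
it omits the 3D vector (compressional/shear mode-converted) field, slice
cross-talk, and transducer dynamics of a real acquisition.

## Forward solver

Flux-form second-order finite differences in the frequency domain (FDFD),
one sparse LU solve per slice, frequency and source. Absorbing boundaries
use complex coordinate stretching (a 10-pixel graded PML, quadratic profile,
target reflectivity 1e-4). The outer boundary is left natural (zero-flux):
a hard Dirichlet wall behind the PML produces grazing-incidence diffraction
that no absorbing layer removes (this alone was a 10% interior error in
early validation). Excitation is a unit Dirichlet line one PML-width inside
a chosen edge; four edges are superposed by default, mimicking a skull that
transmits vibrations all around the brain. An optional grid-refinement
factor (default 2) solves the PDE on a finer grid and samples back, keeping
numerical dispersion ((kh)²/24 per wavelength) well below the inversion
error budget. Homogeneous-medium solutions match analytic attenuated plane
waves to ≲1% (refine 2) and ≲0.1% amplitude / 0.15% of a cycle phase
(refine 4) in the interior.

## Stiffness inversion (multifrequency wavenumber analysis)

Per frequency and wave image:

1. **Amplitude-envelope normalisation** — the image is divided by its
   Gaussian-smoothed magnitude envelope (σ = 4 px). Brain tissue at
   1000–1400 Hz with φ ≈ 0.7 attenuates by ~e⁻³ per traversal, and an FFT
   filter applied to a field with 10²–10⁵ dynamic range buries the
   low-amplitude regions under filter leakage; normalising the envelope
   (not the pointwise modulus, which would rectify interference fringes)
   removes the decay while preserving local superpositions.
2. **Directional decomposition** — FFT-domain angular windows
   `cos²(nδ/4)` centred at `2πj/n` (n = 8), a partition of unity with FWHM
   `2π/n`, plus a per-frequency radial pass band `[0.8 ω/c_hi, 1.2 ω/c_lo]`
   with expected speeds `(c_lo, c_hi) = (1.5, 5.0)` m/s. The image is
   mirror-padded to twice its size before the FFT to suppress wraparound
   ringing. The sharp per-frequency band matters: a strongly damped wave has
   a Lorentzian wavenumber spectrum of half-width `Im k ≈ 0.5 Re k`, and an
   over-wide band lets its heavy tail drag the local phase gradient (we
   measured ~10% speed bias inside high-φ regions with a fixed broadband).
3. **Local wavenumber** — the unwrap-free phase gradient
   `arg(u_{i+1} ū_{i-1}) / 2h` per axis (exact for attenuated plane waves;
   the linearised `Im(∇u/u)` with central differences carries a `(kh)²/6 ≈
   3%` bias at 0.18 mm), Gaussian-smoothed (σ = 1 px), vector norm `k`.
4. **Aggregation** — speeds `ω/k` are averaged over frequencies, directions
   and components with weights `(directional amplitude share × local
   amplitude)²`, zeroing contributions whose wavenumber falls outside the
   plausibility gate `[0.8 ω/c_hi, 1.2 ω/c_lo]` (these are leakage or phase
   singularities, not waves).

## Fluidity inversion (Laplacian-based multifrequency estimate)

For any field obeying the homogeneous Helmholtz equation, `Δu = -k²u` and
`arg k² = φ`, so

    φ = arccos( -Σ_j Re(Δu_j ū_j) / Σ_j |Δu_j||u_j| ),

summing over all frequencies and components; Δ is the spacing-scaled 5-point
Laplacian per slice. Fields are Gaussian-smoothed (σ = 1.5 px) first: the
Laplacian amplifies white noise as k⁴ and needs its own regularisation
(exact for locally homogeneous fields, since Gaussian convolution commutes
with Δ). The width was selected by a three-way calibration: at σ = 1 px the
20 dB-SNR loss-angle error is ~0.05 rad (at the tolerance), at σ = 2.5 px a
wavelength-dependent partial-volume artefact appears (+0.03 rad paired drift
in lesion-class regions whose speed changes between sessions); σ = 1.5 px
gives 0.002 rad noise error and +0.01 rad artefact. The estimate is
invariant to rescaling the field and needs no directional filtering
(standing waves also satisfy `Δu = -k²u`).

Validity is explicit: pixels with negligible weight, vanishing denominator,
or within `edge_margin_px` (default 2) of the tissue-mask boundary are
flagged invalid; regional statistics ignore them. Ventricles are never
analysed (no shear propagation in fluid).

## Synthetic data generator

Phantoms are per-slice brain ellipses (7 coronal slices of 0.8 mm, 90 × 60
matrix at 0.18 × 0.18 mm by default) in a coupling medium (c = 3.0 m/s,
φ = 0.25), with dorsal ventricle pairs (c = 1.0 m/s, φ = 1.35) and two
lesion classes: large blobs near the ventricles whose contrast analogue is
T1 gadolinium enhancement (blood-brain-barrier leakage), and small focal
discs (radius 2–4 px; optionally elongated tract-like streaks or
commissural bands) whose analogue is T2* hypointensity from iron-oxide
nanoparticle (VSOP) accumulation. A toy four-region atlas (cortex ring,
nuclei, brain stem, fiber tracts) supports regional incidence tables.

Cohorts draw per animal: baseline tissue speed ~ N(3.15, 0.11) m/s (lesion
speeds co-scaled, preserving the class means 3.28 m/s for Gd territories and
3.03 m/s for VSOP territories), loss angle ~ N(0.69, 0.03) rad (lesion
classes offset to 0.85 / 0.91 rad). The EAE timepoint multiplies speeds by
1 + pct/100 with class-specific defaults: −5.85% in unremarkable parenchyma,
−9.76% in Gd territories, −16.81% in VSOP territories — so the whole-brain
change emerges at ≈ −7…−8%. Loss angles change only by a session-level
drift ~ N(+0.01, 0.052) rad, the null fluidity effect implied by reported
group statistics (0.69 ± 0.03 → 0.70 ± 0.06, not significant). Optional
`*_pct_sd` fields add between-animal effect spread for power studies.

**Inflammation halo.** The mechanically altered territory extends
`soften_halo_px` (default 12 px ≈ one wavelength at the centre frequency)
beyond the contrast-visible core, at both timepoints. Biologically,
particle accumulation marks the core of a broader inflamed territory;
numerically, the halo lets the inversion's point-spread function (≈ λ/2
transition at property boundaries) reach plateau values inside the measured
masks. Contrast images see only the core.

Noise: complex Gaussian on wave images (default σ = 0.01 of the median
brain amplitude, i.e. 40 dB; chosen as typical for preclinical MRE phase
data) and Rician on magnitude contrast images (σ = 1 at tissue SI 100).

Contrast defaults: 30% T1 enhancement in Gd lesions, 40% T2* signal drop in
VSOP foci; masks by thresholding (percent change ≥ 15%, post/pre ratio
≤ 0.8, minimum component 5 px) replacing the manual delineation of a real
study; VSOP masks dilated 2 px in-plane (4-connected cross) before mutual
exclusion and ventricle removal. Slice-axis resampling onto a reference
atlas grid (215 slices spanning 20.8 mm) maps the 7 × 0.8 mm acquisition
onto ≈ 58 populated atlas slices.

## Statistics

Regional values are arithmetic means of a parameter map over mask ∩ valid
pixels; percent change is `100 (EAE − baseline)/baseline` per animal. Paired
comparisons follow the GraphPad-style convention: D'Agostino-Pearson K²
normality on each compared group (α = 0.05); both pass → two-sided paired
t-test; otherwise the Wilcoxon matched-pairs signed-rank test (zero
differences dropped, exact null for n ≤ 25). Below n = 8 the omnibus test is
undefined: the gate is skipped with a warning and the rank test used.
P-values are unadjusted, one per comparison. Monte-Carlo calibration (10⁴
replicates, n = 19) puts the size of the gated procedure at ≈ 0.05 for both
Normal and log-normal data.

## Recovery validation and known limitations

Effect-size recovery is assessed on the ground-truth softened territories
eroded by 4 px (the PSF half-width), at zero imaging noise, on a reduced
3-slice grid with sparse, separated lesions so territories do not overlap.
Distributed changes recover essentially unbiased (rest of brain ≈ 0.6 pp,
whole brain ≈ 1.5 pp, at injected −5.85% / ≈ −8%). Compartment-scale regions
recover to < 1% (two-compartment slab at 3.03 / 2.55 m/s: ≈ +0.8% medians).

**Focal lesions are different.** At 1000–1400 Hz the shear wavelength in
brain-like tissue is 2.3–3 mm, and a compact softened territory of ≲ 1.2 λ
scatters and refracts the field (Mie regime): the interior local wavenumber
genuinely differs from ω/c, and regional percent changes in VSOP-class
territories come out ≈ 4–5 points shallower than injected (e.g. measured
≈ −12% for −16.81% injected), with Gd-class blobs ≈ 2–3 points shallow.
This is a resolution property of local wavenumber estimation, not an
implementation defect — the same pipeline recovers band-shaped regions
spanning the brain and half-plane compartments to better than 1%. The
corresponding acceptance check is intentionally left failing rather than
loosened; by implication, focal-lesion percent changes reported by this
class of method on real data should be read as lower bounds on the true
local change.

Passing tests show that the analysis chain is internally consistent and
correctly calibrated on fields obeying the stated scalar physics; they do
not validate the 3D vector acquisition, registration across sessions (all
synthetic grids are co-registered by construction), manual mask variability,
or biological variance structure beyond the Normal between-animal model
stated above.

## Problem sizes used in the shipped analyses

Analysis scripts and end-to-end validations use 8 animals on a 3-slice
90 × 60 grid with all five frequencies and four sources (the package's
standard reduced configuration); replicate studies use a single slice at
40 × 60 with two sources. The phantom default remains the full 7-slice
acquisition geometry.
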