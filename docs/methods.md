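# Methods

`dectbench` is a self-contained 2D simulation environment for studying how a
projection-domain dual-energy material decomposition with object-specific
scatter correction compares against image-domain decomposition and against
conventional calibration-based decomposition. Everything — phantoms, spectra,
scatter, and all three decomposition pipelines — is synthetic and analytic,
so every claim about attenuation-value accuracy can be checked against an
exact ground truth. This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic results do and
do not say about real scanner data.

## Attenuation model and materials

Linear attenuation follows the two-basis parameterization

    mu(E) = pe * E^-3 + kn * f_KN(E),

with `f_KN` the total Klein–Nishina cross-section shape normalized to 1 at
100 keV. Per-material coefficients `(pe, kn)` are solved exactly from two
reference points (40 and 80 keV) in the packaged CSV table of linear
attenuation values (standard mass-attenuation tables times nominal
densities: water, a bone-equivalent at 1.5 g/cm³, polyethylene, PMMA, air,
aluminum, iron, adipose). A third tabulated point at 70 keV is used only by
tests to confirm that the two-point fit interpolates the table within 2%.

Two consequences matter for interpreting results. First, the ground truth is
self-consistent: the same coefficients drive the forward simulation and the
evaluation, so accuracy numbers measure pipeline fidelity, not table
fidelity. Second, in a strict two-basis world every material is *exactly* a
linear combination of water and calcium, so two-material decomposition has
no model error; residual errors isolate the data-processing chain (scatter,
fitting, reconstruction). Real inserts deviate slightly from any two-basis
representation; the testbench deliberately removes that confound.

The decomposition's "calcium" basis is the bone-equivalent fixture material.

## Spectra and energy response

The per-channel energy response W(E) is the normalized product of a
simplified bremsstrahlung fluence (kV − E)·E, aluminum filtration
(inherent plus bowtie), and an energy-integrating detector weighting
d(E) = E. Defaults: 80 kV (LE) and 120 kV (HE) tubes, 6.0 mm Al inherent
filtration, a quadratic bowtie t(γ) = t₀ + t₂γ² with t₀ = 2 mm and the edge
channels receiving 3× the central filtration. Rows are normalized to sum to
one; normalization holds to 1e−12 by construction.

The spectral integration grid runs from **30 keV** to the tube voltage in
1 keV steps. The lower bound is a deliberate numerical choice: the simple
bremsstrahlung shape does not decay at low energy the way a real tube-window
spectrum does, and the polynomial training set includes negative calcium
lengths down to −4 cm, for which the photoelectric E⁻³ term turns the lowest
energy bins into exp(+mu·4) amplifiers. Truncating at 30 keV (where heavily
filtered clinical spectra carry only a fraction of a percent of their
weight) keeps the training measurements in a numerically sane range; with a
10 keV grid the quintic fit is rank-deficient and useless (training RMS
~3 cm), with the 30 keV grid it reaches 0.017 cm (water) / 0.004 cm
(calcium).

## Geometry and phantoms

Fan-beam, 360°, fixed bed. Full-scale parameters (2304 projections, 736
channels, 0.067864° channel width, source radius 595 mm, source–detector
1085.6 mm) are available, but the default is a half-scale geometry
(720 × 368) that preserves the total fan angle by widening the channels.
Rays are source-to-channel-center lines; path lengths through disks and
axis-aligned ellipses are analytic chords, with nested shapes following a
replacement rule (a container's length is its chord minus its children's).

Phantoms: the ACR-style module A (200 mm water cylinder; bone, polyethylene,
acrylic and air inserts of 25 mm, water insert of 50 mm), the
two-configuration multi-energy calibration phantom (20 cm water cylinder
with a 28.6 mm calcium insert at the center or at 9 o'clock), plain water
cylinders for the vendor-style calibration, and an elliptical abdomen
surrogate (400 × 300 mm, fat ring, two bone disks). The ACR insert layout
(60 mm radial offset, diagonal quadrants) is a configurable default — only
relative placement matters for the physics.

## Scatter: simulation truth and estimation model

Scatter is additive in the intensity domain:

    s_i = alpha * Ibar * [G_sigma ⊛ I_primary^beta]_i  (+ constant),

with `Ibar` the projection-mean primary intensity and `G_sigma` a unit-sum
Gaussian over detector channels. The estimation model fixes sigma = 5
channels. Two simulation-truth modes exist:

* **matched** — truth uses the same model (sigma = 5, no constant); used by
  oracle tests, where subtraction with the true parameters must invert the
  simulation exactly.
* **mismatch** (default for headline experiments) — truth uses sigma = 8
  plus a constant floor of 2e−4, while estimation still uses the sigma = 5
  two-parameter model, so the estimator always faces model error, as it
  would on real data.

Truth amplitudes default to alpha = 0.25, beta = 0.95, giving a
scatter-to-primary ratio of roughly 20% behind a 20 cm water phantom —
the upper end of what collimated fan-beam CT exhibits. The constant floor
2e−4 is a few percent of the most attenuated primary in the LE scan.

Subtracting model scatter requires the primary intensity, which the model
itself depends on; `subtract_scatter` solves the fixed point
I_p = I_meas − s(I_p) with a plain iteration fast path and a matrix-free
Newton–Krylov fallback (the plain iteration diverges once the scatter
operator's Jacobian exceeds unit spectral radius, around alpha ≈ 0.8 for
these phantoms). Trial parameters for which no physical primary exists are
reported as non-converged and penalized during estimation.

Parameter estimation mirrors the clinical scheme: Nelder–Mead from
(alpha, beta) = (1, 1), tolerance 1e−4 on cost and parameters, at most 500
iterations, minimizing the mean squared mismatch between (i) the raw scan
corrected by the vendor-style empirical water calibration and (ii) the raw
scan after model-based scatter subtraction followed by the analytical water
beam-hardening correction. Recovery of matched-model parameters is exact to
better than 0.1% across alpha ∈ [0.5, 3], beta ∈ [0.8, 1.1].

## Vendor-emulation water correction

The "data the vendor uses for reconstruction" is emulated by an empirical
per-channel monotone map built from scans (scatter on) of centered water
cylinders of 100–300 mm diameter plus an exact air anchor. The map is
interpolated (PCHIP) in the water-linearized coordinate
u = mu_w(70 keV)·L_BHC(g) rather than in raw g: in that coordinate the map
is close to identity plus a smooth scatter offset, which the five sparse
nodes capture well, whereas direct interpolation in g fails where chord
length changes quickly with channel. Outside the calibrated node range the
map continues linearly. Channels outside every calibration cylinder pass
through unchanged. Bulk (median) line-integral error on a held-out diameter
is below 1%; near-tangent rays remain worse because object-dependent scatter
cannot be represented by any per-channel 1-D map — precisely the limitation
that motivates the object-specific projection-domain method.

## Projection-domain decomposition (proposed path)

Scatter-subtracted (g_HE, g_LE) pairs are mapped to water/calcium lengths by
two bivariate polynomials of total degree 5, least-squares fitted (LAPACK
lstsq, i.e. SVD-based, no normal equations) on noise-free measurements
simulated from the energy response over the training grid: water lengths
−2.0 to 28.0 cm and calcium lengths −4.0 to 5.0 cm, both in 0.1 cm steps
(301 × 91 pairs). Negative lengths are included so that mixtures less
attenuating than water need no extrapolation. Measurements are normalized to
the unit square of their fitted range before building the Vandermonde basis
(degree-5 conditioning). Because the bowtie makes the response
channel-dependent, channels are binned by bowtie thickness into at most 16
groups, each with its own polynomial pair fitted to the group-mean response;
a central-only binding reproduces the simplified single-spectrum variant.
Training residuals and fitted domain boxes are stored; rays evaluated
outside the box are counted and logged.

The conventional comparator is fitted from simulated calibration scans of
the two calcium-insert configurations (scatter included, no subtraction),
pooled over all channels, in two standard forms: cubic (all terms
1 ≤ k+l ≤ 3, nine coefficients per material) and a constrained quartic in
(g_HE + g_LE) and powers of (g_HE − g_LE) (four coefficients per material).
The known lengths come from analytic projection of the same phantom shapes.

## Image-domain decomposition (comparator path)

Vendor-corrected LE and HE sinograms are reconstructed; ROI means of the
two calibration-phantom configurations give relative densities whose ratio,
matched against the ground-truth mu_c/mu_w curve, identifies effective
energies ε_LE and ε_HE (monotone interpolation at 0.1 keV). Each pixel's
(mu_LE, mu_HE) pair is then inverted through the 2 × 2 basis matrix
D = [[mu_w(ε_LE), mu_c(ε_LE)], [mu_w(ε_HE), mu_c(ε_HE)]] (conditioning
floor |det D| ≥ 1e−6·‖D‖²). Relative densities are referenced to the
energy-independent water value mu_w(70 keV).

Virtual mono-energetic images (shared by both paths) recombine the density
pair with the basis attenuations at the requested energy and convert to HU
against mu_w(E).

## Reconstruction

Fan-beam sinograms are rebinned to parallel geometry (θ = β + γ + const,
r = R sin γ, bilinear interpolation; default 360 angles over 180° and
2 × channels + 1 radial samples — the radial oversampling matters: one
sample per channel over the full span noticeably blurs 25 mm inserts) and
reconstructed by FBP with the band-limited discrete ramp kernel and a
cosine apodization window (exponent 1 by default, emulating a moderately
smooth quantitative kernel). Pixel-driven backprojection with linear
interpolation; default grid 256² at 1 mm over a 250 mm field of view
(512²/0.49 mm available by config). Grid offsets compensate off-centered
phantoms exactly (insert ROI means match the centered case within 2 HU at
default scale).

FBP of attenuation sinograms yields mu in 1/cm (uniform-disk oracle within
0.02% at the center); FBP of length sinograms yields dimensionless relative
densities (water region 1 ± 0.01 on matched simulations).

## Evaluation

Insert ROIs are 20 mm circles centered on the inserts (margin against edge
resolution effects); the beam-hardening ring around the bone insert has
inner radius 17.64 mm and thickness 4.9 mm and is scored by mean absolute
deviation from ground truth (no error cancellation). Accuracy and noise
curves run over 30–140 keV in 5 keV steps. The water insert's relative
error is computed on mu values, since its ground-truth HU is zero. Pixel
membership is by pixel-center containment. Noise experiments emulate the
repeat-and-average protocol (10 repeats by default) with intensity-domain
Poisson sampling (zero counts clipped to 0.5).

## What the synthetic conditions show — and what they do not

Under matched-model scatter the full projection-domain pipeline is accurate
to a few HU everywhere (air insert −998 HU at 70 keV against a true value
of −999 HU), confirming that the chain itself — subtraction, quintic
tabulation, rebinned FBP, VMI synthesis — is essentially unbiased at the
default scale.

Under the mismatch conditions the water insert stays below 1% relative
error over the whole energy range, and the noise-versus-energy curve shows
the expected parabola with the projection-domain minimum about 10 keV below
the image-domain one. The solid inserts, however, can exceed the ±4% band
that real-scanner studies report: with a ~20% scatter-to-primary ratio, the
sigma = 8 → 5 kernel mismatch leaves a residual scatter error behind the
25 mm inserts that *no* (alpha, beta) of the sigma = 5 model can remove (a
least-squares fit of the model directly to the true scatter profile leaves
the same residual). This is a property of the chosen synthetic mismatch
conditions, not of the decomposition chain; the matched-model results bound
the chain's own error.

The abdomen-surrogate position-consistency check behaves the same way: with
a 40 mm vertical shift and a compensating reconstruction grid, the
soft-tissue profile agrees within a few HU in the central body, but the
differential residual-scatter shading grows to ~10–20 HU within about 2 cm
of the fat/water interface, exceeding the 6 HU target the experiment
reports against. The experiment emits both the metric and the pass/fail
flag rather than hiding the boundary region.

More generally: the synthetic scatter is a two-parameter convolution model,
not Monte-Carlo transport; the spectra are simplified bremsstrahlung, not
measured tube spectra; the geometry is a single detector row without a
flying focal spot; and all materials are exactly two-basis. Passing tests
therefore validate the algorithmic chain and its relative orderings
(projection-domain vs image-domain vs conventional), not absolute
performance on any particular scanner.

## Problem sizes

Defaults are half-scale (720 × 368 rays, 256² pixels at 1 mm), at which the
full accuracy study (two positions, two methods, noise pass) runs in
minutes on one CPU. The unit-test suite uses quarter- and eighth-scale
geometries. Full Table-style scale (2304 × 736, 512² at 0.49 mm) is a
config change.
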