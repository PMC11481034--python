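# Methods

This note documents the models, numerical choices and known limitations of
each analysis stage, and what the synthetic-data generators do and do not
emulate.

## AFM force-curve mechanics

**Hertz fit.** The spherical-indenter (paraboloidal) Hertz law
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} is used rather than the full Sneddon sphere
solution. At the operating regime this package targets — indentation depth
≈ 0.1·R (1 µm on a 10 µm-radius tip) — the two agree within a few percent,
and the paraboloidal form admits a closed-form linear solve for E at fixed
contact point. Poisson ratio defaults to 0.5 (incompressible, rubber-like
gels) and must lie in [0, 0.5].

The contact point is a free parameter by default: for each candidate the
modulus is solved in closed form (linear least squares on δ^{3/2}) and the
RMS residual minimised by bounded scalar search over the position range; if
the search does not improve on the nominal origin, the origin is kept.
A threshold detector (baseline mean + 5 SD over the first 20% of samples,
with an absolute floor so noiseless data still triggers) is available as an
initialiser and for diagnostics. Fits with fewer than 5 post-contact samples
are refused; a negative fitted modulus is clamped to zero and flagged.

**Loss tangent.** Amplitude and phase of indentation and force at the drive
frequency are estimated by least-squares sinusoid fits with simultaneous
constant + linear-drift terms (a lock-in with detrending). For small
oscillations about a working indentation the linearised contact stiffness
carries the loss angle of the complex modulus, so tan of the
force–indentation phase lag equals G″/G′. The segment must contain at
least two full periods; a lag at or beyond π/2 (force lagging into the
non-physical quadrant) raises an error, and small negative lags within
1e-6 rad are clamped to zero as numerical noise.

**Stress relaxation.** Per curve, in order: shift to zero force when the
pre-peak baseline (mean of the first tenth of pre-peak samples) is
negative; locate the force maximum (t0, F0); shift time by t0; crop to the
constant-indentation hold (retract data is excluded upstream by segment
label); normalise by F0. Curves are then linearly interpolated onto the
time grid of the first curve, cropped to the shortest common hold, and
averaged pointwise; the first averaged sample is pinned to exactly 1.0 to
guard interpolation round-off. Energy dissipation is
(1 − F_norm(t_max))·100 on that averaged, normalised signal — so a signal
relaxing as (1−a) + a·e^{−t/τ} over a hold T dissipates
a·(1−e^{−T/τ})·100 percent, the closed form the tests check.

## Polymer network

All three mesh-size routes report nm and keep lab-convention units at the
interface (g/cm³, cm³/g, cm³/mol); conversions to SI are internal.
Constants: R = 8.314 J mol⁻¹ K⁻¹, N_A = 6.02214076×10²³ mol⁻¹. PEG
defaults: Mr = 44 g/mol, l = 0.146 nm, Cn = 4.0, ν̄ = 0.89 cm³/g,
V₁ = 18 cm³/mol, χ = 0.426.

Temperature is an explicit parameter with default 310.15 K (measurements on
temperature-controlled AFMs are commonly at 37 °C); room-temperature
instruments should pass ≈296 K. The combined route's chain-end term is
implemented with a positive sign, 1/M̄c = G·Q^{1/3}/(R·T·C₂ᵣ) **+** 2/M̄n;
some literature variants subtract it — check which convention a comparison
value uses. Parameter sets yielding 1/M̄c ≤ 0 have no physical network and
raise rather than return a negative weight. Volume fractions ν₂ᵣ, ν₂ₛ are
taken directly as inputs (deriving them from gravimetric swelling requires
density assumptions that belong to the experiment, not this package).

## Traction force microscopy

The gel is a semi-infinite, isotropic elastic half-space loaded
tangentially at its surface; out-of-plane force and displacement are
neglected (valid when displacements are small compared with gel
thickness). The per-wavevector Green's tensor is

G̃(k) = 2(1+ν)/(E·k³) · [[(1−ν)k²+ν·ky², −ν·kx·ky], [−ν·kx·ky, (1−ν)k²+ν·kx²]].

The k = 0 mode of both the forward and inverse maps is set to zero, which
enforces zero net force and zero-mean displacement — the physically
correct constraint for a force-balanced cell, and the only consistent
choice since the half-space operator has no DC response. Reconstruction
solves the 2×2 Tikhonov normal equations (G̃ᵀG̃ + λ²I)⁻¹G̃ᵀũ in closed form
per mode. λ carries the units of G̃ (m/Pa) and is user-supplied; no L-curve
or GCV selection is built in, but `lambda_grid_search` picks the best λ
against a known truth for synthetic studies. Zero padding (default factor
2) softens the periodic-boundary artefact of FFT convolution; an optional
Hann window is available. With no padding and λ = 0 the forward→inverse
round trip is exact to machine precision on zero-mean fields; with padding,
truncation of the slowly decaying displacement tails costs ≈1% L2 error on
a compact patch.

PIV is single-pass: each 16-px (default) interrogation window of the
relaxed image is matched against a search region of the stressed image by
normalized cross-correlation; the peak is refined by a 3-point parabolic
fit per axis. When the correlation peak is numerically exact (≥ 1 − 1e-7)
the displacement is exactly integer and refinement is skipped — parabolic
interpolation of a zero-residual match is meaningless. Vectors whose
primary/secondary peak ratio falls below 1.1 are flagged spurious and
replaced by the 3×3 neighbourhood median. An iterative multi-grid scheme
would track larger or strongly sheared displacements; fields may instead
be supplied directly as CSV, which is the primary path.

"Total" traction is reported both as integrated force Σ|f|·Δx² (newtons)
and as the raw sum of stress magnitudes (Pa), explicitly labelled, since
both conventions appear in the literature.

## Image quantification

Segmentation is Otsu (default) or fixed-level thresholding plus connected
components, with objects under 9 px removed. The YAP partition follows the
identity definitions exactly — YAP_cyt and A_cyt are differences, so the
partition identities hold to the bit on every output — and nuclei are
paired to cells by maximal overlap, rejecting pairings that cover less
than 50% of the nucleus. The ratio is undefined (raises, with diagnostics)
when the cytoplasmic area or signal is zero.

Perimeter uses a Freeman chain-code with Kulpa's diagonal correction
(straight steps 1.0 px, diagonal 1.340 px). The uncorrected √2 chain code
overestimates smooth boundaries by ≈4–5% (staircase bias), pushing a large
disk's circularity down to ≈0.92; the corrected estimator keeps
axis-aligned edges exact (a digitised square reports 4πA/P² = 0.826
against the continuum π/4 = 0.785) while landing a large disk at ≈0.97.
Circularity is clamped at 1.0.

Focal-adhesion lengths come from the best-fit ellipse, rescaled by √3/2 to
the support length of the uniform rod with the same second moment — the
raw major axis overestimates a bar's length by 2/√3 ≈ 15%, the corrected
value is within one pixel. The pipeline (white top-hat background
subtraction with a 20 px disk, threshold, components) exposes
`background_radius_px`, `threshold` and `min_length_um` because the exact
filter sizes of published FA workflows vary; objects under 1 µm are
treated as noise and excluded from the length list and the [1, 2] µm /
> 2 µm frequency bins.

Fiber anisotropy is the eigenvalue anisotropy (λ₁−λ₂)/(λ₁+λ₂) of the
intensity-gradient structure tensor (σ = 2 px, nearest-edge padding)
averaged over the ROI — the nematic-order formulation used by fibril
plug-ins. It is invariant under intensity gain and offset and under
rotation (to within gradient-stencil anisotropy, ≲0.02); a constant ROI
has no gradient energy and returns 0 flagged undefined.

## Synthetic data

Generators draw all randomness from one `numpy.random.default_rng(seed)`
per scene; identical parameters + seed are bit-identical, and zero noise
reproduces the analytic forward model exactly. Noise is additive Gaussian:
for force curves its SD is the stated fraction of the local noiseless
force, for displacement fields a fraction of max |u|, for images a fixed
intensity SD.

Defaults mirror the acquisition geometry the analyses target: 0.3 N/m
cantilever with a 10 µm-radius sphere, ≈1 µm indentation, 10 Hz / 10 nm /
0.4 s oscillation at 5 kHz sampling, 60 s relaxation holds; 12 kPa
substrates for traction scenes; 0.02 beads/px² Gaussian beads (SD 1 px)
advected by the bilinearly interpolated displacement field.

What the generators deliberately do **not** emulate: instrument drift and
hydrodynamic drag on force curves beyond a linear trend, non-exponential
(power-law) relaxation — the hold uses a single-exponential
standard-linear-solid form, enough to exercise the processing pipeline but
not a model of real gel rheology — optical blur and photobleaching,
out-of-plane bead motion, and segmentation ambiguity (masks are exact
ellipses). Passing the recovery tests therefore demonstrates correctness
of the estimators on in-model data, not robustness to every instrument
artefact.

## Problem sizes

Validation runs use 200 noiseless + 100 noisy Hertz curves (500 samples
each), 2 000-sample oscillation segments, 64×64 traction grids with
pad-factor 2, 256×256 bead images (~1 300 beads), and ~400×650 px cell
images — sizes at which every stage's error is measured well below its
tolerance while the whole suite runs in seconds.
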