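# Methods

## The measurement and its model

Hyperpolarized [1-13C]pyruvate MRI images the enzymatic conversion of an
injected, transiently hyperpolarized pyruvate bolus into lactate.  The
observable is a pair of dynamic complex image series (one per metabolite)
acquired with a multi-channel 13C receive array.  The quantity of interest
is the apparent exchange rate constant kPL (1/s) of the label transfer
pyruvate -> lactate, which in renal tumors tracks WHO/ISUP grade and the
expression of the pyruvate transporter MCT1.

The kinetic model is the standard input-driven unidirectional two-site
exchange:

    dP/dt = b(t) − P/T1_P − kPL·P
    dL/dt = kPL·P − L/T1eff

with b(t) a gamma-variate arterial input, T1_P the pyruvate relaxation
time, and T1eff an *effective* lactate decay constant that absorbs
spin-lattice relaxation, back-conversion (kLP) and any signal loss shared
between the metabolites.  No separate kLP or intrinsic T1 appears anywhere:
they are not identifiable from this data and are folded into T1eff by
definition.

RF excitation consumes hyperpolarized magnetization.  The simulator applies
a per-frame factor cos(α)^E (α = 15°, E = excitations applied to a slice
per frame) compounding across frames, identically for both metabolites.
Because the loss is shared and multiplicative, it shifts the fitted 1/T1eff
by −ln(cos^E α)/Δt and leaves kPL untouched; the estimator therefore makes
no flip-angle correction, and recovery tests compare fitted 1/T1eff to the
depletion-adjusted truth.

**Why E = 1 per frame.** Excitation pulses are slice-selective: a slice's
magnetization is depleted only by its own excitation, roughly once per
4-second frame.  This choice is corroborated by the data the method is
known to produce: with E = 1, T1_P = T1eff = 30 s, the simulated
time-summed Lac/Pyr ratio is 0.355 at kPL = 0.0152 1/s and 0.148 at
kPL = 0.0065 1/s — matching the reported ratios (0.35 for the most
metabolically active tumor, ~0.13 for the median clear-cell carcinoma).
With one excitation per slice *count* per frame (E = 5) the simulated
lactate would be roughly half the observed level.  E remains configurable.

## Synthetic data

The clinical scans and histology behind this analysis are not
redistributable, so every stage is
validated on synthetic data whose ground truth is known by construction:

- **Dynamic phantoms.**  A labelled scene (background / body / normal
  kidney / tumor / biopsy subregions) on the reconstruction grid; each
  region carries its own (kPL, T1eff) and pyruvate delivery amplitude.
  Courses are integrated by RK4 at 0.1 s and sampled at the frame times
  (20 frames, 4 s apart, first frame 12 s after injection).  Each voxel is
  multiplied by smooth complex ring-coil sensitivities and independent
  complex Gaussian noise (per real/imaginary component) is added per
  metabolite, coil, frame and voxel.  All randomness is
  `numpy.random.default_rng(seed)`.
- **Bolus.**  Peak-normalized gamma-variate
  A·(τ/(sβ))^s·exp(s − τ/β), τ = t − t0; defaults t0 = 2 s, s = 3,
  β = 2 s put the peak at 8 s, before the first frame.  The true in-vivo
  bolus shape and T1 values are not observable here; these defaults are
  conventional configuration, not facts about any dataset.
- **IHC micrographs.**  H-DAB images composed through Beer–Lambert mixing
  with the standard Ruifrok–Johnston stain vectors (shared with the
  quantifier).  Class pixels are painted at DAB optical densities in the
  middle of each class interval (0.27 / 0.40 / 0.55) so that 8-bit
  quantization cannot cross a boundary; nuclei are non-overlapping
  hematoxylin disks placed by dart throwing in DAB-negative tissue, with a
  one-pixel halo so 8-connected components never merge.
- **Cohorts.**  Patients receive grades by cycling through a shuffled
  grade pool {2,3,4} (the reported ccRCC case mix), patient kPL from a
  monotone grade link spanning the reported ccRCC range
  (0.0024–0.0151 1/s) with lognormal scatter (CV 8%), biopsy grades with
  ±1 within-tumor heterogeneity, biopsy kPL with 15% lognormal scatter,
  and MCT1 from a linear kPL link.  MCT4 is drawn at the reported
  tumor level (37 ± 10.5%), uncorrelated with kPL.  Viable-tumor
  fractions follow Beta(5,1) (≈24% of biopsies fall below the 75%
  inclusion cut).  Each biopsy is embedded in the phantom as a disk
  subregion with the same radius as the sampling cylinder, so the image
  at the biopsy site carries the biopsy's true kPL.  Per-patient noise is
  calibrated so the time-summed pyruvate SNR in the tumor equals the
  reported median of 26.7; because SVD weights computed in noise-only
  voxels align with the noise, the background statistics of the combined
  map are not plain Rayleigh, and the calibration constants come from a
  seeded Monte-Carlo of that noise-only combination.

What the generator does **not** emulate: spiral/chemical-shift artifacts
and k-space-correlated noise (noise is white per recon voxel), partial
volume at region boundaries, B0/B1 inhomogeneity, respiratory motion, real
stain variability and nucleus morphology.  Passing tests therefore
demonstrate correctness of the analysis chain under its stated model, not
performance on scanner data.

## Coil combination

Per voxel, the complex data are summed over all time points first (to
minimize noise propagation into the weights), the summed values of both
metabolites are stacked into a (2 × neighborhood) × coils matrix, and the
dominant right-singular vector — unit norm, reference-coil phase made real
and non-negative — is the combination weight.  This is the maximum-SNR
matched filter for white noise; no noise-covariance pre-whitening is
applied because the simulator draws white noise (a documented divergence
from pipelines that whiten first).  The time-summed weights are reused for
every frame so the dynamic courses needed by the kinetic fit stay
single-channel.  Metabolite maps take the magnitude after the complex
time sum; total carbon is the voxel-wise sum of the pyruvate and lactate
magnitude maps.

## SNR and masking

SNR = (mean(SI_ROI) − mean(SI_noise)) / (√2 · SD(SI_noise)), with noise
statistics from an extracorporeal background region of the same map; the
√2 reflects the narrowed Rayleigh distribution of magnitude noise.  The
kinetic fit runs only where the summed total-carbon SNR is ≥ 5 — the
boundary is inclusive.

## kPL estimation

The lactate balance is linear in (kPL, r = 1/T1eff), so the fit is linear
least squares in the frequency domain: the N−1 trapezoid interval
differences ΔL/Δt and interval averages of P and L are Fourier transformed
(4× zero-padding) and the overdetermined complex system

    DFT(ΔL/Δt) = kPL·DFT(P̄) − r·DFT(L̄)

is solved over stacked real and imaginary parts.  Two numerical choices
matter:

- **Window boundaries.**  The acquisition starts 12 s after injection,
  when both signals are already large.  Applying the continuous derivative
  theorem (iω multipliers) to the raw windowed courses leaves O(signal)
  boundary terms and biased kPL by 12–19% in noiseless tests; forming the
  system from interval differences uses only equations that hold within
  the window and reduces the noiseless error to ≈1.3% (inside the 2%
  discretization budget), dominated by the trapezoid treatment of the
  bolus curvature between 4 s samples.
- **Errors in variables.**  With noisy data the lactate regressor carries
  the same noise as the response, attenuating both rates.  When the
  per-sample noise SD σ is known, the consistent moment correction
  subtracts n·σ²/2 from both diagonal Gram entries (the lhs/regressor
  noise cross-terms cancel exactly for the difference/average pair).  The
  correction is capped at 80% of the raw Gram's smallest eigenvalue —
  subtracting c·I shifts both eigenvalues by exactly c, and an uncapped
  correction drives the system toward singularity at low lactate signal,
  producing heavy-tailed estimates whose median is itself biased.

Voxel courses are the *phase-corrected real channel*: both metabolites of
a voxel share one constant phase (from the coil sensitivities), estimated
from the complex sum over both metabolites and all frames (pyruvate-
dominated) and projected out.  The noise is then zero-mean Gaussian.
Fitting plain magnitudes is available as an option but is severely biased
at realistic lactate SNR (Rician floor; Monte-Carlo median bias near −80%
at clinical noise levels), which is why it is not the default.

Negative fitted values are returned as-is with flags, never clipped;
medians downstream use them unchanged.

**Two-stage maps.**  Voxel-wise joint (kPL, r) fits are ill-conditioned at
clinical SNR — the two rates trade off along a ridge.  The pipeline first
fits the mean phase-corrected course over the whole tumor ROI (high SNR)
jointly, pools the per-patient r estimates across the cohort by median
(the effective relaxation is shared: sequence depletion plus lactate T1),
and then solves the one-parameter kPL problem per voxel with r fixed.
Whether the original analysis fitted or fixed T1eff per voxel is not
documented; fixing it at the map stage is this package's choice and is
what makes low-kPL voxels usable.

**Verification oracle.**  An independent time-domain nonlinear fit of the
explicit solution L(t_{k+1}) = L(t_k)e^{−rΔt} + kPL·∫P̃e^{−r(Δt−u)}du
(piecewise-linear P, exact interval integrals, first-frame lactate as the
initial condition, bounds kPL ∈ [0, 0.1], r ∈ [1/120, 1], four-point
multi-start).  The two estimators agree within 2% in kPL over 200 random
noiseless draws spanning kPL ∈ [0.001, 0.02], T1eff ∈ [15, 45] s.

## ROIs and patient tables

Voxel-center rasterization (a voxel belongs to an ROI iff its center, at
(index + 0.5)·voxel size in mm, is inside), with boundary points included,
for per-slice polygons (validated simple; shapely) and for the 3 cm
diameter × 3 cm height biopsy cylinders (in-plane distance ≤ radius,
slice-center within half-height; with 3 cm slices and a 5 mm gap a
cylinder spans exactly one slice).  Biopsy coordinates are consumed as
given — the tumor-mold co-registration that produces them is upstream of
this package.  Patient-level values are medians over a patient's biopsies
after excluding samples with viable-tumor fraction strictly below 0.75
(a sample at exactly 75% is retained).

## IHC quantification

OD = −log10(I/255) per channel (zero intensities clamped at OD 3.0);
least-squares two-stain color deconvolution onto the H-DAB unit vectors
(negative concentrations clipped, counts logged); tissue = total OD ≥ 0.05;
DAB classes with inclusive lower bounds at 0.2164 / 0.3274 / 0.4938;
percent positive = (weak+moderate+strong)/tissue × 100.  Cells are
8-connected components of hematoxylin OD ≥ 0.5 with ≥ 4 pixels.  The
tissue rule and the component counter are deliberately simple, open
substitutes for proprietary commercial operators: exact on the synthetic
micrographs, but real scanner slides would need stain-vector and threshold
calibration.

## Cohort statistics

Spearman correlation (mid-ranks; exact permutation p for n ≤ 8, t
approximation above), Pearson correlation (t-based p), Wilcoxon rank-sum
and signed-rank tests (exact enumeration for combined n ≤ 10, tie-corrected
normal approximation with continuity correction above).  All p-values are
two-sided; exact two-sided p = min(1, 2·min(P(T ≤ t), P(T ≥ t))).

Biopsy-level measurements cluster within patients.  Instead of a linear
mixed model or ordinal two-way ANOVA — whose exact specifications are a
matter of software defaults — the grade effect is tested by a
patient-blocked permutation F-test: kPL ~ patient indicators + numeric
grade, statistic = partial F for grade, null distribution from permuting
grade labels within each patient block, p = (1 + #{F* ≥ F}) / (1 + n_perm)
with n_perm = 9999 by default and a mandatory seed.  This tests the same
null (no grade effect after accounting for patient) without parametric
assumptions; its type-I error is calibrated by simulation in the test
suite.  The test is invariant to patient relabeling and to per-patient
kPL offsets, which the block term absorbs.

## Problem sizes used in tests

Phantom and cohort tests run on reduced spatial grids — 32×32 or 40×40
in-plane (the latter equal to the protocol's true 40×40 acquisition matrix),
1–3 slices, 2–4 coils — with the temporal axis, kinetics, SNR target and
link structure at their study values.  The end-to-end acceptance check
uses 100 cohorts of 6 patients at 40×40 × 3 slices; the number of
statistically independent tumor voxels there (~500–900) is comparable to
the imaged tumors at acquisition resolution.  The full
128×128 / 5-slice / 8-coil geometry remains the default configuration.

## Known limitations

- The ~1.3% noiseless kPL bias is inherent to 4 s sampling with trapezoid
  quadrature; finer temporal sampling would shrink it.
- Voxel-wise joint (kPL, T1eff) estimates at clinical SNR are unstable for
  kPL below ≈0.004 1/s; only the fixed-r map or ROI-level fits are
  meaningful there, and reported medians inherit a few-percent bias.
- The EIV correction needs a noise SD; in the pipeline it is measured from
  the per-coil background, which exists only because the simulator's
  geometry is known.  On real data a noise-only acquisition or artifact-free
  background region serves the same purpose.
- Stain quantification assumes the generator's stain vectors; no
  per-slide calibration is implemented.
- The synthetic cohort's grade–kPL link is a modeling device for recovery
  tests; nothing here re-estimates the clinical effect sizes.
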