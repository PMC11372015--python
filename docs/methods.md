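# Methods

`autoaif` implements a fully automated image-derived input function (IDIF)
pipeline for dynamic ¹⁸F-FDG brain PET, together with the kinetic models used
to consume the IDIF and a synthetic head phantom used to validate the whole
chain. This note describes the model and procedure choices, the phantom's
design and its limits, and the numerical decisions.

## The extraction pipeline

Dynamic data are a 4D volume `F(X, Y, Z, n)` on a frame schedule (62 frames
over 65 min in the reference protocol: 2×10 s, 30×2 s, 4×10 s, 8×30 s,
4×60 s, 5×120 s, 9×300 s). The stages are:

1. **Data preparation** (`autoaif.frames`). Brain voxels are selected by a
   strict threshold of 1 (kBq/mL) on the duration-weighted time-averaged
   image, restricted to the top 20 cm of the supra-threshold axial extent,
   and rearranged into a voxel-by-frame matrix `F̂(M, n)`. Thresholding is
   applied before the axial crop: once noise makes every voxel numerically
   nonzero, "nonzero head region" is only well defined through the
   threshold; for strictly positive head support the two orders agree.
2. **Shape identification** (`autoaif.peaks`). Each curve is resampled to a
   uniform 2 s grid (linear interpolation; the wavelet transform assumes
   uniform sampling) and scanned with a continuous wavelet transform (real
   Morlet, integer scales 1–100). Candidate peaks are strict local maxima of
   the coefficients along time at any scale whose magnitude exceeds 0.5 of
   the curve's largest coefficient magnitude; the candidate with the largest
   curve value is reported, earliest first on ties (arterial peaks precede
   venous ones). The relative 0.5 threshold operationalises "significant
   coefficients" per curve and makes detection scale-equivariant. The tail
   of a curve is the duration-weighted mean of the final two frames
   (55–65 min). Cohort statistics average the ten largest peaks
   (`Mean_peak`) and ten smallest tails (`Mean_tail`).
3. **Filtering and clustering** (`autoaif.vessels`). A curve survives iff
   its peak exceeds `(1 − a1)·Mean_peak` and its tail stays below
   `((1 − a2)·Mean_tail) + Mean_tail`, both strict. Note the tail criterion
   *tightens* as a2 grows (the cutoff is `(2 − a2)·Mean_tail`). Survivors
   are split into two clusters by agglomerative hierarchical clustering
   (Ward linkage, Euclidean distance); the earlier-peaking cluster is
   arterial. `cluster_two` defaults to raw curves; the end-to-end extractor
   clusters unit-norm (shape) curves instead, because partial-volume
   attenuation spreads each vascular family along the amplitude axis and
   raw-amplitude Ward then groups attenuated vein voxels with arteries.
   Shape normalisation removes that failure mode while leaving the
   timing/washout information that actually separates arteries from veins;
   both modes are exposed as a parameter.
4. **IDIF formation** (`autoaif.idif`). Cluster averages are formed at
   a1 ∈ {0.4, 0.5, 0.6} with a2 = 0.9 and averaged across levels. The
   automatic input function combines the arterial peak with the venous
   remainder: both curves are interpolated to a 2 s grid, the venous curve
   is shifted so the peaks align, values are concatenated at the arterial
   peak, the two grid points (4 s) on each side of the junction are
   replaced by the mean of the two curves, and the result is resampled to
   the frame midtimes. A descending-aorta reference VOI (10 mm diameter ×
   10 mm cylinder over the lumen) provides the reference curve where the
   field of view includes the chest.

`IDIFExtractor` packages stages 2–4 as a scikit-learn estimator
(`fit(tacs, schedule=...)`, fitted attributes `idif_auto_`, `idif_artery_`,
`idif_vein_`, per-level cluster row sets and voxel counts).

## Kinetic modelling

The irreversible two-tissue compartment model (k4 = 0) is

    C_T(t) = (1 − vb)·[(K1·k2/(k2+k3))·e^{−(k2+k3)t} + K1·k3/(k2+k3)] ⊗ C_p(t)
             + vb·C_b(t)

with plasma and whole blood not distinguished (C_p = C_b = the input
function). Rates are per minute; K1 in mL/cm³/min; vb a fraction; the net
influx rate is Ki = K1·k3/(k2+k3). The convolution is evaluated on a
uniform 2 s grid with exact per-step integration of the exponential kernel
against a piecewise-linear input, realised as a first-order IIR recursion
(O(n) per model evaluation, no frame-width quadrature error); frame values
are model time-averages over each frame. The k2+k3 = 0 limit reduces
analytically to K1·∫C_p. Fitting uses bounded least squares
(trust-region-reflective — an LM-class local method honouring the box)
from the initial point (0.01, 0.01, 0.01, 0.01) inside [0, 1]⁴ with
unweighted residuals and no smoothing or outlier handling. Patlak analysis
regresses C_T/C_p on ∫C_p/C_p over frames with midpoints at or after
t* = 40 min (five frames on the reference schedule) by ordinary least
squares; the slope estimates Ki and the intercept absorbs the blood volume.

## The synthetic head phantom

No patient data accompany the method, so validation runs on a simulated
dynamic acquisition with known ground truth (`autoaif.phantom`). What it
emulates, and why each piece exists:

- **Arterial input**: a Feng-type tri-exponential bolus,
  C(t) = (A1(t−t0) − A2 − A3)e^{λ1(t−t0)} + A2 e^{λ2(t−t0)} + A3 e^{λ3(t−t0)}
  for t ≥ t0. Defaults peak at ~26 kBq/mL around 42 s with a
  peak-to-60-min-tail ratio of ~20:1. The absolute scale is *not*
  arbitrary: the pipeline masks the brain at a fixed threshold of one
  image unit, so amplitudes are calibrated to the clinical kBq/mL scale on
  which a whole-blood tail of ~1.3 kBq/mL sits just above that threshold.
- **Venous curves**: the bolus delayed by 2 s and dispersed with a
  unit-area exponential kernel (τ = 4 s). The measured arterial-to-venous
  time-to-peak difference is the bulk delay plus the dispersion-induced
  peak shift, ≈6–7 s, matching published total-body measurements (reported
  per-subject range 4–8 s). With τ = 0 the difference equals the delay
  exactly, which is how the pure-shift property is tested.
- **Tissue**: grey and white matter follow the irreversible 2TCM with the
  published mean rate constants (GM 0.173/0.137/0.053, vb 0.05;
  WM 0.061/0.094/0.025, vb 0.03).
- **Anatomy**: a head ellipsoid holds a superior cortical cap (GM shell
  with an inner WM ellipsoid) above a skull-base zone of low-uptake tissue
  whose 55–65 min tail is calibrated to match whole blood. Two vertical
  carotid-like arteries (radius 3.2 mm, the published common-carotid
  calibre) and a venous-sinus tube (radius 4.4 mm) run through the basal
  zone; the sinus sits in a well-perfused dural ring whose mid-study
  activity tracks blood and whose tail exceeds blood by ~20%, with
  bloodless dural caps closing the tube ends. A 7 mm scalp/soft-tissue
  shell wraps the head. A descending-aorta cylinder (radius 13 mm) sits in
  an inferior body slab that the 20 cm axial crop excludes, so the brain
  cohort never sees it while the reference VOI can.

  This arrangement is load-bearing, not decorative. The cohort tail
  criterion keeps curves below 1.1× the mean of the *ten smallest* tails;
  those smallest tails come from partial-volume boundary voxels, whose
  tail-to-time-mean ratio is scale-free. Any blood-dominated structure
  near an exposed surface therefore drags `Mean_tail` below every vessel
  tail and empties the candidate set, while hot cortex directly abutting a
  vessel inflates the vessel's tail past the cutoff. Real heads avoid both
  failure modes — large vessels run through low-uptake skull-base tissue
  and the head is wrapped in moderately perfused extracerebral tissue —
  and the phantom reproduces exactly that structure. The dural ring's
  blood-like mid-curve likewise mirrors why venous IDIFs are nearly
  unbiased in practice: spill-in from perfused surroundings compensates
  mid-study spill-out, while the late tail, being blood-matched
  everywhere, is insensitive to partial volume.
- **Resolution and noise**: each frame is blurred with an isotropic 3D
  Gaussian (default 3.83 mm FWHM = 3.27 mm scanner resolution ⊕ 2 mm
  reconstruction filter, combined in quadrature) and corrupted with
  zero-mean Gaussian noise of variance proportional to activity divided by
  frame duration (noise_scale 0.5, giving ~5-7% relative noise at the peak
  in the 2 s frames and ~1% in the late 300 s frames — a level consistent
  with a high-sensitivity long-axial-FOV system). Frame values are
  time-averages of the continuous curves over each frame, as scanners
  report them.
- **Problem size**: a 44×44×150 grid at 1.65 mm isotropic voxels with a
  brain of ~6,000 supra-threshold voxels. This is a deliberately compact
  head — about a quarter of the voxel count of a full clinical brain — so
  that whole-pipeline studies over many realizations remain cheap; vessel
  radii, the PSF and the noise level are at clinical scale, so the
  partial-volume physics the framework confronts is preserved.

What passing phantom tests does *not* show about real data: the phantom has
no motion, no scatter/attenuation artefacts, piecewise-homogeneous tissue
classes, geometrically ideal vessels, Gaussian noise rather than
reconstructed-Poisson texture, and a single anatomy rather than anatomical
variability. Results on it validate the mechanics and the partial-volume
behaviour of the pipeline, not clinical accuracy.

## Numerical choices

- The batched Morlet CWT mirrors PyWavelets' kernel convention
  (integrated wavelet, `−√s·diff(conv)`) but evaluates all voxels of a
  block with one FFT per scale, and extends each curve with its edge values
  over the largest kernel's half-width so boundary discontinuities cannot
  masquerade as wavelet maxima; a constant curve then has exactly constant
  coefficients over the original span and no detected peak. Agreement with
  `pywt.cwt` on the identically extended signal is tested.
- Curves are flat-extrapolated (clamped) outside their support during
  interpolation; inputs starting after t = 0 are anchored with a zero
  sample at t = 0 inside the kinetics grid (pre-arrival activity is zero).
- AUC uses the trapezoidal rule on a 2 s grid with period boundaries
  inserted as grid points, so period AUCs sum exactly to the total.
- NRMSE divides by the reference at every time point and is therefore
  undefined on pre-arrival (zero-activity) frames; the resolution study
  evaluates it on the reference's nonzero support.
- Ties: equal candidate peaks resolve to the earliest time; equal cluster
  mean times-to-peak resolve to the smaller mean tail (with a warning);
  identical-curve cohorts return a warned singleton split rather than an
  error so that degenerate inputs fail loudly downstream.
- All randomness flows through a single integer seed per phantom
  realization (`numpy.random.default_rng`); images are bit-reproducible.

## Known limitations

- The adjudication windows T1–T7 are implemented and used in "adjustment
  mode" against a reference curve; in brain-only fields of view no
  reference exists, and deployment applies the fixed arterial-peak +
  venous-tail combination rule directly.
- No plasma-vs-whole-blood or metabolite correction, no dispersion
  deconvolution of the measured IDIF, no partial-volume correction — all
  deliberately outside the framework's premise.
- The wavelet peak detector assumes a single dominant bolus event; cohorts
  whose curves all lack structure (flat or monotone without a ridge
  maximum) yield no candidates and the pipeline reports that loudly.
- At effective resolutions beyond ~4 mm FWHM the extraction degrades in the
  manner the resolution study quantifies (sharply growing AUC error);
  this is a property of the method, reproduced rather than repaired here.
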