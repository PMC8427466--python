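# Methods

This note documents the models implemented in `hepaflow`, the choices made
where the design was genuinely open, what the synthetic phantom does and
does not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and its inversion

The Look-Locker FAIR readout is modelled by the three-parameter
inversion-recovery curve Mz(TI) = M0·(1 − α·e^(−TI/T1\*)) with the
small-angle correction T1 = T1\*·(α − 1). The simulator generates data
**self-consistently**: it sets T1\* = T1/(α − 1) so that the standard
fitting-and-correction chain is its exact inverse. This makes noiseless
parameter recovery a strict oracle without committing to a full Bloch
simulation of the spoiled gradient-echo readout (which the package
deliberately does not attempt; neither are B0/B1 field maps, multi-slice
phantoms, or HA/PV perfusion separation in scope).

For the slice-selective inversion, perfusion shortens the effective T1.
The forward model inverts the perfusion equation:

T1_ss = T1_global / (1 + P/s), s = (λ/T1_blood)·60000·100,

so `perfusion_map` applied to (T1_global, T1_ss) returns P exactly — the
test suite checks this identity over P ∈ [0, 2000] ml/min/100 g. The
conversion factor s is computed from λ and T1_blood at call time (3000 at
the defaults λ = 0.95 ml/g, T1_blood = 1900 ms), so overrides propagate;
both constants plausibly differ in liver disease and can be configured per
run.

**Inversion-time grid.** TIs are k·110 ms for k = 1…50 (the first readout
one spacing after the inversion). The spacing and count are protocol
constants; placing the first sample at 110 ms rather than 0 is a recorded
convention of this implementation.

**Noise.** Zero-mean Gaussian noise on the signed signal is the default;
it keeps least-squares fitting unbiased so oracle tests isolate the
estimator. A Rician option (`noise_model="rician"`) returns magnitude data
for studying polarity-restoration behaviour.

## T1 fitting

Per-pixel bounded least squares (`scipy.optimize.least_squares`, trf,
analytic Jacobian; convergence tolerances 1e−12). Initialisation: M0 from
the mean of the last five samples; T1\* from the null-point heuristic
TI_min/ln 2 (assuming α ≈ 2); α starts at 1.9. Bounds: M0 ∈ (0,
10·max|signal|], α ∈ (1, 2.2], T1\* ∈ [50, 5000] ms — a physiological
rodent-tissue range at 9.4 T. Fits that hit a bound, return α ≤ 1, or
start from degenerate input (< 4 finite samples, all-zero curve) are
marked invalid rather than raising; invalid pixels are excluded from every
downstream mean.

Magnitude-like input (no negative samples) is polarity-restored before
fitting: samples before the curve minimum are sign-flipped, and because
the sample nearest the null can lie on either side of the zero crossing,
both splits are fitted and the lower-RSS solution kept. A direct
magnitude-model fit (|Mz|) is available behind `model="magnitude"`.

Each TI image is smoothed with a unit-sum Gaussian kernel (σ = 1.6 px,
truncated at 4σ, reflect padding) before fitting, identically for both
inversion modes. Smoothing blurs tissue-contrast boundaries, which is why
the default parenchymal ROIs are centred at the deepest interior point of
each lobe (the maximum of the lobe's distance transform): ROI pixels stay
clear of boundary contamination. ROI radius defaults to 8 px (≈ 3.75 mm)
at the 128 matrix, scaled with matrix size.

`fit_t1_map` fits each *unique* pixel curve once and broadcasts the result
— an exact optimisation that makes piecewise-constant (noiseless) phantoms
cheap without affecting noisy data.

## Phantom anatomy and cohorts

A single axial slice: a body ellipse, a liver ellipse split into
right/middle/left lobes (piecewise-constant T1, M0 and per-lobe
perfusion), zero-signal background. The two caval stations live on their
own phase-contrast slices (192 matrix, 40 mm FOV, 0.208 mm pixels) as
circular vessels of 3.5 mm diameter with parabolic through-plane flow; the
supra-hepatic peak velocity is chosen so the supra-minus-infra flow
difference equals the configured TLBF, making caval subtraction an exact
oracle up to discretisation.

Cohort draws (all Gaussian, clamped to physical ranges): per-group means
are the literature baseline values and the SDs are the reported standard
errors scaled by √n (n = 10 sham, 9 BDL; 7 BDL for post-LPS changes,
reflecting attrition) — sham perfusion 316 (SD 75.9), BDL 199 (SD 96.0)
ml/min/100 g; liver T1 1256 (SD 56.9) vs 1533 (SD 150) ms; liver weights
14 (SD 3.16) vs 30 (SD 6.0) g; LPS perfusion shifts +78 (SD 104.4) vs −49
(SD 105.8) ml/min/100 g; LPS T1 shifts +0.2 (SD 28.5) vs +14 (SD 29.1) ms.
Each animal's true TLBF is its perfusion plus an offset with mean 51 and
SD 131.6 ml/min/100 g, emulating the observed between-method disagreement
so the agreement layer has realistic structure. BDL animals are lost
post-LPS with probability 2/9 (the observed attrition, not the 30%
planning assumption). Heart rate is uniform on 300–400 bpm; the LPS
response is a single additive per-animal shift with no within-acquisition
dynamics.

What the phantom does **not** emulate: coil sensitivity and B1
inhomogeneity, partial-volume mixtures at tissue boundaries, physiological
T1/perfusion texture within a lobe, vessel pulsatility waveform shape
beyond a single zero-mean harmonic, through-plane motion, and any
systematic FAIR-vs-PCMRI bias mechanism beyond the drawn offset. Passing
round-trip tests therefore demonstrates correctness of the analysis chain
and calibration of the statistics — not robustness to every real-data
artifact.

## Respiration, segmented acquisition and gating

Respiratory cycles have configurable period (default 1 s, 3% jitter) with
a quiescent end-expiration window covering a configurable fraction
(default 0.6) of each cycle. Segments of 4 k-space lines are triggered at
the first quiescent-window start after the previous inversion has relaxed
(TR_inversion = 13 s); each segment reads all 50 TIs, so the ~5.5 s train
inevitably overruns quiescence and retrospective gating has work to do.

A line is **kept** iff the closed interval [t − margin, t + margin] around
its acquisition instant intersects a (closed) quiescent window; at
margin = 0 a line exactly on a boundary is kept. The motion model for
corrupted lines is a rigid 2 mm in-plane translation along the row
(cranio-caudal) axis, applied exactly via the Fourier shift theorem — the
dominant respiratory mode, and exactly invertible. Rebuild policies:
`reacquire` (default) replaces each discarded line with the same line
acquired in the next quiescent window, i.e. the motion-free line, giving
complete k-space as retrospective optimisation effectively achieved;
`zero_fill` zeroes them. Cardiac gating of the FAIR series and non-rigid
motion correction are out of scope.

## Flow integration

Phase decodes to velocity as v = venc·φ/π with φ ∈ (−π, π]; no
unwrapping is attempted — aliasing is flagged when any vessel-ROI phase
lies within 5% of ±π. The cycle average divides the wrapped-trapezoid
area under the flow curve by the cardiac period (exact for any single
harmonic under uniform sampling, and equivalent to per-beat summation
scaled by heart rate). Negative TLBF from error propagation through the
caval subtraction is reported as-is with a warning, never clamped. The
partial-volume rule (voxel width ≤ vessel diameter/3) is boundary-
inclusive. Maxwell/eddy-current phase offsets and background-phase
fitting are not modelled.

## Statistics

All tests are two-sided at the 5% level; printed "±" summaries are treated
as standard errors throughout. Specific conventions:

- **Bland–Altman**: LoA multiplier fixed at 1.96 (large-sample), not a
  small-sample t quantile.
- **Forkman's CoV test**: F = [c1²/(1 + c1²(n1−1)/n1)] / [c2²/(1 +
  c2²(n2−1)/n2)] on F(n1−1, n2−1); two-sided p = 2·min(cdf, sf). The
  statistic for CoVs 29.3%/50.1% at n = 19/19 is 0.39.
- **KS normality**: parameters are estimated from the sample, so the null
  is Lilliefors-corrected via seeded Monte Carlo (10⁴ replicates by
  default) rather than the classical KS table.
- **Mixed ANOVA**: for the 2 (between) × 2 (within) design the interaction
  F with df (1, n − 2) equals the squared pooled-variance t on per-subject
  change scores; this change-score equivalence is exact, handles
  unbalanced groups without choosing a sums-of-squares type, and matches
  `pingouin.mixed_anova` (verified in the test suite). Subjects missing a
  time point are dropped with a warning. Post hoc per-group paired tests
  use Bonferroni m = 2.
- **Mann–Whitney U**: exact enumeration for pooled n ≤ 20 without ties,
  normal approximation with tie correction otherwise. The pipeline uses it
  in place of Welch's t when a KS normality check (possible only with ≥ 4
  per group) rejects at 5%.

## Pipeline problem sizes and persistence

The study pipeline persists every intermediate (NIfTI series and maps with
a JSON sidecar for protocol metadata, CSV measurement tables, a JSON
report) under one directory per animal per time point, and each stage
reads only what earlier stages wrote — re-running the stats stage alone
reproduces the report byte-for-byte. All randomness derives from the
configured master seed via `numpy` seed sequences.

Default problem sizes are chosen for interactive turnaround: the pipeline
simulates at a 64 matrix (the protocol's 128 matrix remains the
single-phantom default and is used for the exact round-trip checks), and
study-level power evaluation runs at measurement level — cohort parameter
draws fed directly to the ANOVA — rather than re-imaging 50 full cohorts.
The imaging chain itself is validated separately by the noiseless
end-to-end study test. The gated-vs-ungated comparison uses a 64-matrix
phantom over 20 seeds.

## Known limitations

- The self-consistent forward model cannot detect errors that cancel
  between simulator and fitter by construction; the closed-form and
  brute-force oracles in the test suite (grid-search fitting, parabolic
  flow, quadrature identities, permutation/direct-formula statistics)
  exist precisely to break that circularity.
- Perfusion quantification inherits the constant-inflow assumption of the
  two-compartment T1 model; transit-time and bolus-arrival effects are not
  modelled.
- The pixel threshold rule excludes (rather than caps) supra-threshold
  pixels from ROI means; with unequal valid-pixel counts the mean-of-ROI-
  means convention (implemented) differs from a pooled-pixel mean.
- Attrition is a per-animal Bernoulli flag; no mechanism links it to the
  drawn physiology.
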