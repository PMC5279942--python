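# Methods

This note documents the models implemented in `pilarray`, the defaults
and why they were chosen, the design of the synthetic-data generators,
and what the synthetic benchmarks do and do not demonstrate about real
recordings.

## Pillar mechanics

A pilus is modeled as a laterally loaded elastic cylinder clamped at its
base: spring constant k = (3/4)·π·E·r⁴/L³, restoring force F = k·d.
Units are handled through the exact identity 1 MPa ≡ 1 pN/nm², with
lengths converted via a single pixel-size / µm→nm table. Forces are
reported as unsigned magnitudes: the sign of the restoring force carries
no information once deflection magnitude is the stimulus measure. The
default calibration (E = 2.1 MPa, r = 1.79 µm, L = 5.87 µm, k ≈ 251
pN/nm) describes the standard PDMS arrays and is echoed into every
output table. No finite-element, substrate-warping or cell-stiffness
correction is applied; the linear-beam model is the whole mechanical
story here.

## Spot localization and deflection

Pillar spots are fitted with an isotropic 2D Gaussian plus constant
background by trust-region least squares. Conventions and choices:

- Coordinates are 0-based, pixel-center. All nm values go through one
  `pixel_size_nm` constant (default 161 nm/px, a 40× objective with a
  6.45 µm camera pixel).
- Initialization: background-subtracted intensity centroid for the
  center, max−min for the amplitude, a quarter of the ROI for σ. On a
  clean symmetric spot the centroid and the converged Gaussian center
  agree to < 10⁻³ px, which the tests use as an independent oracle.
- A fit that fails to converge or whose center leaves the ROI raises an
  error; no silent values.
- An anisotropic (σ_row, σ_col) variant is available behind a flag; the
  isotropic fit is the default because the spot model is isotropic.
- Candidate detection is local-maximum search above median + k·MAD
  (default k = 5), one ROI (half-width 8 px) per spot; plateau ties
  resolve to the lowest row, then column.

Deflection is (during − before)·pixel size; the after frame provides a
recovery residual (default flag limit 50 nm) confirming the pilus
returned to rest. Optional reference pillars (non-stimulated) allow
median-drift subtraction; this is off by default because the three-frame
protocol does not require it, and on in the synthetic drift tests.

On noiseless synthetic scenes the recovered deflection is exact to
< 0.01 nm; at the default imaging conditions (peak 2000 counts over
background 200, read noise 15 counts) the deflection RMSE over 200
random 0–500 nm deflections is ≈ 1.3 nm, comfortably inside the method's
7 nm error budget.

## Current kinetics

The event detector declares a response when the current deviates from
the pre-stimulus baseline (window 10 ms) by more than k·SD (default
k = 5) sustained for 0.3 ms. These defaults are this module's own
definition — acquisition software conventions vary — and are fully
configurable.

- **Peak location.** The extremum of a 5-sample boxcar-smoothed
  deviation between onset and stimulus end; the amplitude itself is read
  from the raw extremum (exact on clean traces), smoothing only
  stabilizes the fit windows under noise.
- **Activation.** I(t) = A·(1−exp(−(t−t₀)/τ₁)) fitted from onset to
  peak. By default the onset time t₀ is itself a free parameter bounded
  between 2 ms before the detected crossing (never before the stimulus)
  and the peak: a threshold detector necessarily fires late — the
  current must clear the noise band first — and pinning t₀ at the
  detected crossing biases τ₁ downward by up to tens of percent. With a
  free t₀ the reported latency is the fitted onset, exact on clean
  unfiltered traces and within one sample period on filtered ones.
- **Decay.** I(t) = A·exp(−(t−t_peak)/τ₂) + C from the peak to the point
  where the smoothed deviation stays below 5% of the peak (or trace
  end). The polarity is taken from the signed deviation at the peak, so
  decays that cross baseline (negative offsets) fit correctly.
- **Classification.** `rapid_gating` requires latency < 5 ms (strict
  inequality at the boundary); `direct_gating` additionally requires
  τ₁ < 1 ms. Both thresholds are configurable.
- Windows with fewer than 5 samples are flagged unfittable; responding
  events keep latency and amplitude with null τ, matching how sparse
  currents are reported in practice.

Recovery performance (synthetic): noiseless events reproduce latency,
τ₁, τ₂ and amplitude within 1% (latency within one sample period on
3 kHz-filtered traces); at baseline SD = amplitude/20 the median
relative error of τ₁ and τ₂ over 500 events is ≈ 4%.

## Stimulus–response binning and thresholds

Deflection bins are the contiguous edges {0, 10, 50, 100, 250, 500,
1000} nm with half-open (lower, upper] intervals; 0 nm is excluded. (The
50–100 nm bin is included so the edges are contiguous across the full
range.) Averaging is two-stage: per-cell bin means first, then across
cells, so the per-bin denominator is the number of *contributing* cells;
cells without a measurement in a bin are omitted from that bin (reported
as NA when a whole group is empty or all-zero). Non-responding sweeps
count as amplitude 0 in their bin. A cell is a responder when at least
one in-range sweep gated a current; its threshold is the smallest gating
deflection. Group comparisons: Mann-Whitney per bin and for thresholds,
Fisher's exact test for responder fractions.

Whether zero-amplitude sweeps of responder cells belong in the per-bin
averages is an assumption (taken as yes); the all-zero-bin NA convention
follows from it.

## Pressure-clamp Boltzmann fits

Per-patch peak currents are normalized to the family's maximal
magnitude, then fitted with y(P) = ymax / (1 + exp((P₅₀ − P)/s)). The
saturating amplitude ymax is a free parameter: a finite protocol never
fully saturates the channel, so the observed maximum underestimates the
asymptote, and pinning the amplitude at 1 would bias P₅₀ downward
(≈ −0.7 mmHg at s = 15 on the standard 10–150 mmHg protocol). With ymax
free the noiseless fit recovers the generating P₅₀ exactly, and the fit
is invariant to rescaling the raw currents. The group P₅₀ is the mean of
per-patch fits (not a pooled fit). Cell-attached (suction) protocols are
analyzed on |P|. All-zero families are flagged non-responding and
excluded rather than fitted; non-converged patches are excluded and
counted.

## Calcium imaging

ΔF/F = (F − F₀)/F₀ with F₀ the mean of the first 10 frames (5 s
interval). An epoch scores as a response when peak ΔF/F exceeds
max(0.1, 5 × baseline ΔF/F SD) — the threshold definition is this
module's own, stated and configurable. Cells failing the ATP viability
epoch are excluded from statistics on the later agonist epochs. No
bleaching correction is applied (traces are short).

## Exact statistics

- **Fisher's exact test**: hypergeometric probabilities computed as
  exact rationals; the two-sided p follows the point-probability rule
  (sum of all same-margin tables no more probable than the observed
  one), with a doubled-one-sided variant behind a flag. Degenerate
  margins give p = 1.
- **Mann-Whitney U**: full enumeration of group assignments (exact also
  under ties) when the pooled size is ≤ 12 or on request; otherwise a
  tie-corrected normal approximation with continuity correction *plus*
  the symmetric Edgeworth fourth-moment term, using the closed-form
  kurtosis of the null U distribution,
  γ₂ = −(6/5)(n²+m²+nm+n+m)/(nm(n+m+1)). The plain normal approximation
  disagrees with enumeration by up to ≈ 0.015 at n = m = 6; the
  Edgeworth correction brings worst-case disagreement below 0.002 there.
  Ties are handled with midranks and the variance tie correction; the
  no-ties kurtosis is retained under ties as an approximation.
- **Variance-ratio F test**: larger over smaller sample variance,
  two-sided p = 2·upper-tail capped at 1; degenerate zero-variance cases
  are flagged.

Fisher is intrinsically conservative on small discrete tables (attained
size ≈ 0.013 at n = 10 per group, approaching nominal only for larger
groups); the null-calibration tests account for this.

## Synthetic-data generators

The generators produce every input class with known ground truth.
Defaults are the experimental conditions where stated, and documented
choices where not:

- **Image scenes**: 5×5 grid of isotropic Gaussian spots (σ 600 nm) on a
  square 4.16 µm pitch, pixel 161 nm, peak 2000 counts over background
  200, Gaussian read noise sd 15 counts, optional Poisson shot noise
  (off by default). Pitch, pixel size and illumination statistics are
  assumptions (the imaging hardware constrains but does not fix them)
  and are flagged as such in the config. Exactly one (central) pilus
  moves, in the during frame only; deflections beyond half the pitch are
  rejected as collisions.
- **Current traces**: 10 kHz sampling, causal 4-pole Bessel low-pass at
  3 kHz (order and cutoff configurable; the filter family is not
  dictated by the amplifier spec, Bessel is the conventional choice).
  Events rise as A(1−exp(−t/τ₁)) for 5τ₁ (reaching 99.3% of A, recorded
  as the truth amplitude) and decay as exp(−t/τ₂); inward currents are
  negative at negative holding potentials (−40 mV chondrocyte-style,
  −60 mV HEK-style). Baseline noise is added after filtering so the
  trace baseline SD equals the specified value exactly. Per-event
  parameters are drawn log-normally around the phenotype means
  (positive, right-skewed quantities); SD 0 collapses to the mean.
- **Phenotypes**: reference parameter sets for chondrocyte-like
  (latency 3.6 ms, τ₁ 1.7 ms, responder probability 24/27, threshold
  252 nm), dedifferentiated-like (3.1 ms / 1.4 ms / 15/17 / 59 nm),
  TRPV4-like (τ₁ 0.5 ms, voltage-independent τ₂ and amplitude) and
  PIEZO1-like (τ₂ doubling at positive potentials). Population SDs are
  reconstructed from the reported s.e.m.·√n of each cohort.
- **Pressure families**: Boltzmann truth I = Imax/(1+exp((P₅₀−P)/s)) at
  the standard 10–150 mmHg, 20 mmHg-step protocol plus Gaussian noise.
  The default slope (10 mmHg) is derived from the protocol itself:
  normalizing each patch to its maximal measured current presumes the
  response has saturated by 150 mmHg, which at P₅₀ ≈ 87 mmHg requires
  s ≲ 13 mmHg.
- **Populations**: per cell, a Bernoulli responder flag and a log-normal
  gating threshold truncated to (0, 1000] nm; stimulus campaigns are
  jittered geometric series of 12 deflections over 10–1000 nm whose
  largest stimulus always reaches 1000 nm (an experimenter probes to the
  top of the range), so the observed responder fraction converges to the
  generator probability. Gated amplitudes scale with a saturating
  function of deflection (half-saturation 150 nm) so response grows
  across bins.
- **Fluorescence traces**: baseline, then step-to-plateau transients
  during each agonist epoch with exponential washout (τ 30 s). The
  noiseless peak ΔF/F equals amplitude/baseline exactly. Default
  schedule: ATP 60 s (viability; the duration is an assumption), 5 min
  washout, Yoda1 90 s, 5 min washout, GSK101 15 s.

Seeding: every generator takes a seed or `numpy.random.Generator`;
identical spec + seed gives bit-identical output. The pipeline fans a
single global seed out to per-stage child seeds by hashing the stage
name (SHA-256, reduced below 2³¹), so stages are independently
reproducible.

### What the synthetic benchmark does not show

The generators emulate the *statistical structure* of the recordings,
not their physics: no optical diffraction or depth-of-focus effects, no
cell bodies occluding pillars, no series-resistance or leak artifacts,
no single-channel (Markov) gating noise, no mechanical creep of the
elastomer, no dye bleaching. Passing recovery tests therefore
demonstrates that the estimators are correct and well-calibrated for the
assumed signal models at realistic noise levels — not that those models
capture every failure mode of real data. Population-level biology
(genotype differences, real thresholds) enters only through the
phenotype parameter sets.

## Problem sizes and tolerances in the test suite

Benchmarks are sized to run comfortably on one CPU: 200 frame pairs for
the localization RMSE, 500 events for noisy kinetics recovery, 100
patches for noisy P₅₀ recovery, 200 replicates for each power property
(cohorts of 24 vs 15 cells; patch groups of 11 vs 10), 2000 replicates
for null calibration of the tests. Fit tolerances: 1% for noiseless
kinetics, 0.1 mmHg for noiseless P₅₀, < 0.01 nm for noiseless
localization; oracle agreements: 2% (exponential grid), 0.5 mmHg
(Boltzmann grid), 0.01 (Mann-Whitney exact vs approximate at n = 6+6).

## Known limitations

- The three-frame protocol tracks no time-lapse dynamics and does not
  reconstruct the bending profile along the pilus shaft.
- The onset detector and the calcium responder threshold are package
  definitions; results depending on them should be read alongside their
  settings, which every output echoes.
- The Mann-Whitney Edgeworth correction uses the no-ties kurtosis under
  ties (the tie effect on the fourth moment is neglected).
- Patches whose currents are too small to normalize are excluded, not
  imputed; cohorts dominated by such patches yield group summaries with
  reduced n rather than a guess.
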