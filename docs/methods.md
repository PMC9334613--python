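# Methods

`nirsync` re-implements, as a tested pipeline, the analysis chain of a dyadic
fNIRS hyperscanning experiment: two players of a semi-computerized
Rock-Paper-Scissors game are recorded simultaneously with 16-channel
continuous-wave fNIRS over bilateral DLPFC and TPJ, and inter-brain synchrony
is quantified as band-averaged wavelet-transform coherence (WTC), compared
against a pseudo-dyad permutation null, and modeled with beta-family mixed
regression.  Because no raw data from such studies are publicly deposited,
the package ships a forward simulator whose outputs exercise every stage.

## Experimental design encoded in the scheduler

A session holds four conditions — Free Play, Prediction-Different Action,
Prediction-Same Action, Control — with Free Play always first and the rest in
a seeded random order.  Each condition runs two blocks of 30 trials with
one-minute resting phases before, between and after the blocks (12 rests per
session).  Free Play and Control trials last 8 s (Control decomposes into
3 s decision + 2 s button press + 3 s action); prediction trials last 15 s
(3 s prediction + 2 s button + 3 s action + 3 s observation + a 4 s
inter-trial interval that tops the printed phases up to the stated trial
length — published descriptions of such designs leave the ITI implicit,
so the scheduler makes the gap explicit).  Sampling rate is 7.81 Hz; a full session
is ~58 min.

## Forward model of the simulator

Per subject and channel, oxygenated-hemoglobin change is a sum of

* a band-limited (0.05–0.16 Hz) Gaussian process, split into an independent
  part and a part *shared* within the dyad's ROI.  `kappa(condition) *
  gain(condition, roi)` is the shared-variance *fraction*: the mixing
  weight is `w(t) = sqrt(kappa * gain)` with a `sqrt(1 - w^2)`-weighted
  independent signal, so marginal variance is constant, the expected
  inter-subject band correlation is ~kappa and band coherence rises as
  ~kappa^2.  Parameterizing kappa as a variance fraction (rather than as
  the raw mixing weight) keeps the low end of the coupling grid resolvable:
  with a raw weight, coherence grows as the fourth power and a
  kappa = 0.3 effect would sit below desk-scale estimator noise.
  kappa = 1 with noise off makes the two subjects' series identical
  (coherence 1);
* cardiac (~1.1 Hz) and respiratory (~0.25 Hz) oscillations with slow phase
  jitter, shared across a subject's channels (this is what heart-band QC
  detects);
* a Mayer-wave band (~0.08–0.12 Hz) component generated *independently per
  subject*.  This is deliberate and conservative: systemic physiology then
  adds in-band noise but can never masquerade as inter-brain coupling;
* 1/f drift and white measurement noise.

HbR is generated as −1/3 × the HbO composite plus a small independent white
term, giving the negative polarity real recordings show.  Concentrations are
demeaned, pushed through the modified Beer–Lambert law (MBLL) forward model,
and exponentiated into strictly positive two-wavelength intensities.

Default coupling (`kappa`): FreePlay 0.70, both prediction conditions 0.55,
Rest 0.30, Control 0.00, with a ×1.3 right-TPJ gain during Free Play.  These
encode the qualitative ordering the statistical pipeline is designed to
detect (task > rest > none, right-TPJ emphasis in free play); their
magnitudes are the package's choice, set to give the mixed model realistic
power at small dyad counts.  The simulator does not model gestures, motion
kinematics, EEG, or trial-by-trial behavioral structure, and its noise is
stationary — so passing tests demonstrate that the analysis recovers known
coupling structure under realistic spectra, not that it is robust to every
artifact of real recordings.

## Preprocessing

1. **Heart-band QC** — a channel passes if its Welch spectrum (8 s windows,
   both wavelengths pooled) has a local peak in 0.8–1.5 Hz at least 2× the
   median power of the flanking bands.  The original study used visual
   inspection; the SNR-ratio rule is a standard automated proxy and is only
   ever applied to synthetic data here.  At least two passing channels per
   ROI are required.
2. **Optical density** — `OD = -ln(I / mean(I))`, then demeaned per
   channel/wavelength.  Demeaning makes OD exactly linear in the (demeaned)
   concentration series, which is what gives the forward/inverse round trip
   its 1e-10 accuracy.
3. **Spline motion correction** — artifact intervals are flagged where the
   1 s moving standard deviation exceeds 5× its median; within each interval
   a cubic smoothing spline (csaps-style parameter p = 0.99) is fitted and
   subtracted; segment levels are then re-anchored using 10 s windows, and a
   level shift is applied only when it exceeds 5× the natural variability of
   window means — so baseline steps are removed (≥90% in tests) while
   genuine slow oscillation crossing a spike is left alone.
4. **Band-pass** — zero-phase (forward–backward) 3rd-order Butterworth,
   0.01–0.50 Hz.
5. **MBLL inversion** — per channel and sample a 2×2 solve with tabulated
   extinction coefficients (natural-log convention, 1/(uM·cm)), 3 cm
   source-detector distance and DPF 6.0 at both wavelengths (configurable;
   extinction table and DPF are rarely reported with such acquisitions, and
   coherence is amplitude-invariant so the choice cannot affect downstream
   results).

## Wavelet coherence

The CWT uses a complex Morlet (omega0 = 6 rad — the conventional value for
the widely used cross-wavelet toolbox; "cycles per frequency" phrasings
in the literature are ambiguous, so the parameter is configurable) on a
dyadic grid with 12 sub-octaves per octave, s0 = 2/fs, largest scale =
series length / 4.  It is computed by zero-padded FFT and matches a direct
time-domain convolution to ~1e-10 on every scale with at least four samples
per scale unit; the smallest dyadic scales (s < 4/fs, periods < 0.5 s) carry
sampling aliasing in any time-domain reference and are excluded from oracle
comparisons — they sit far below the 6.25–20 s analysis band.

Coherence follows the standard smoothed-cross-spectrum form with a Gaussian
time smoother (sd = scale) and a 0.6-octave boxcar across scales.  Band
averages take the arithmetic mean of R² over scales with Fourier period in
[6.25, 20] s (i.e. 0.05–0.16 Hz) and over the segment's samples, excluding
points under the cone of influence by default (the alternative is a flag;
with 60 s rests the COI would otherwise dominate).  Values are clamped to
(1e-6, 1 − 1e-6) so beta-likelihood inference is defined at the boundaries.

Per dyad and channel: each condition's two blocks are band-averaged
separately and the two values averaged; the 12 rest phases are pooled with
point-count weights into a single Rest value — 5 condition-level values per
channel.  Mean coherence depends on segment length (shorter records bias WTC
upward), which is why all inference is against pseudo-dyads with identical
segment structure rather than across raw condition means.

For throughput the pipeline restricts the scale grid to periods 3–40 s
(band averages are unchanged; the grid never touches the band edges'
smoothing support) and batches equal-length segments through the FFTs in
single precision; the public `wtc()` API keeps the full double-precision
grid.

## Pseudo-dyad permutation null

Each dyad's Subject 1 is re-paired with `n_permutations` (1000 in the full
profile) Subject 2 partners drawn with replacement from the other dyads,
aligned on the condition clock, and the coherence of the pseudo-pairs is
averaged per subject, channel and condition.  Because a draw's value depends
only on which partner was drawn, the average is computed exactly as a
multiplicity-weighted mean over unique partners — an algebraic identity that
reduces the cost from O(permutations) to O(dyads) coherence computations.

## Beta mixed model

Coherence values y in (0,1) are modeled as Beta(mu*phi, (1-mu)*phi) with
logit(mu) = X beta + Z b, b ~ N(0, diag(sigma^2)) over dyads.  The marginal
likelihood uses a Laplace approximation (per-group Newton modes with Fisher
scoring, observed-information log-determinant) maximized by L-BFGS; the fit
matches R glmmTMB to ~1e-3 in coefficients and standard errors in the test
suite's cross-check.  Fixed-effect covariances come from the Schur
complement of the joint (beta, b) information at the optimum.  Random-effect
covariance is diagonal; the declared random-slope structure is reduced in a
fixed order (interaction slopes → main-effect slopes → intercept-only) until
convergence, with the trail recorded.  Effects are tested by
likelihood-ratio tests of nested fits (Wald chi-square also available);
post-hoc pairwise contrasts use equal-weight estimated marginal means on the
link scale with Tukey studentized-range adjustment (which reduces exactly to
the unadjusted test for two levels).  Residual diagnostics are
normal-quantile residuals from the fitted beta distribution.

Two preset analyses mirror the study: the control analysis
`wtc ~ pairing * condition * region` on original + random pairs, and the
main analysis `wtc ~ condition * region` on original pairs (HbR by default —
the chromophore the control analysis validates).

## Scaled test profile and problem sizes

The acceptance suites run the full chain at desk scale: 6 dyads, 50
permutations, sessions shortened to 4–6 trials per block with 30 s rests
(the shortest sessions whose rest segments still reach the 20 s period edge
of the analysis band), the 8-channel (2 per ROI) or single-channel test
montage as appropriate.  Null calibration uses 200 simulated datasets;
GLMM parameter recovery 100 replicates of 30 dyads (intercept-only random
effects, sd 0.3, phi 30); the LR type-I simulation 200 null replicates; the
end-to-end qualitative check 20 runs.  `scripts/acceptance.py` recomputes
the same quantities at moderately reduced replicate counts and reports them
as JSON.

## Known limitations

* Diagonal random-effect covariance (no slope-intercept correlations).
* The permutation null is condition-matched and schedule-aligned; it does
  not implement phase-scrambling or circular-shift surrogates.
* WTC significance contours (Monte-Carlo, per the original toolbox) are not
  computed; inference goes through the GLMM + pseudo-dyads.
* The simulator's session clock is shared across dyads; real sessions have
  per-dyad condition orders, which the pseudo-pairing handles by aligning
  on condition labels, not wall clock.
* No short-separation regression or superficial-signal removal.
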