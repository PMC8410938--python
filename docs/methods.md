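# Methods

## Signal model and ratiometric readout

A FRET voltage indicator couples membrane potential *V* (expressed here in
percent units) into the two fluorescence channels with opposite sign:

    D(x,t) = offset + F_D · (1 − g_D·V(x,t)/100) · (1 + m_D·sin(2π f_hb t + φ)) + ε
    A(x,t) = offset + F_A · (1 + g_A·V(x,t)/100) · (1 + m_A·sin(2π f_hb t + φ)) + ε

The sinusoid is the heartbeat artifact: a common-mode multiplicative
modulation whose depth differs between channels (m_D ≠ m_A) because the two
cameras see different spectral bands of the hemodynamic absorption change.
ε is additive camera noise; counts are quantized and clipped to 12 bits.

After binning, dark-offset subtraction and pre-stimulus normalisation, each
channel is dimensionless with baseline 1. The equalization step estimates,
per pixel, the ratio g = |A(f_hb)| / |D(f_hb)| of spectral amplitudes at the
detected heartbeat frequency and rescales the donor's fluctuations:
donor′ = 1 + g·(donor − 1). Both channels then carry equal heartbeat
amplitude, so the artifact cancels in R = acceptor/donor′ while the
anticorrelated voltage deflections add. The readout is
%ΔR/R = (R − R₀)/R₀ × 100 with R₀ the pre-stimulus mean of R.

**Units of the recovered signal.** Equalization rescales *all* donor
fluctuations, including the voltage deflection, by g ≈ m_A/m_D =: r. To first
order the pipeline therefore reads out

    %ΔR/R ≈ (g_A + r·g_D) · V.

The synthetic generator defines its ground-truth amplitudes in *pipeline
readout units*: the default coupling is g_D = g_A = 1/(1+r)
(`GainCoupling.balanced`), which makes a configured amplitude of 0.195 appear
as 0.195 %ΔR/R in the noiseless limit. Second-order corrections are
O(V²/100) ≈ 10⁻⁴ % at the amplitudes studied. This choice is what lets
parameter-recovery tests compare recovered %ΔR/R directly against configured
truth.

## Synthetic forward model

* **Depolarisation kernel**: normalized difference of exponentials
  α(t) = (e^(−t/τ_decay) − e^(−t/τ_rise)) / α_max, delayed by an onset latency
  (default 10 ms) after each stimulus. The kernel has unit peak by
  construction, so the configured amplitude *is* the true peak.
  `RegionKernel.from_peak` solves the rise constant (Brent root find) to
  place the analytic peak at a requested latency; the default forepaw S1FL
  kernel peaks 59.83 ms post-stimulus with amplitude 0.195 %, the whisker
  S1BF kernel at 50.58 ms with 0.156 %, with τ_decay = 80 ms. This is the
  minimal smooth shape matching the three observables a trace constrains
  (latency, peak time, amplitude).
* **Hyperpolarisation**: a negative kernel of the same family with its own
  onset (default 100 ms — the slow component begins well after the fast
  peak), peaking at 180 ms with decay 250 ms and default amplitude
  0.04–0.05 %. Giving the slow component its own onset keeps the fast peak
  amplitude exactly equal to the configured value.
* **Heartbeat**: a single 10 Hz sinusoid (mouse heart rate under head
  fixation), modulation depths 2 % (donor) and 1 % (acceptor). A single tone
  suffices because the equalization uses only the dominant heartbeat peak;
  harmonics would add nothing to what the tests probe.
* **Optics/noise**: donor 1600, acceptor 1400, offset 100 counts;
  Gaussian noise σ = 10 counts per raw pixel, chosen once as a
  shot-noise-scale imaging floor. After 4×4 binning this gives ≈0.22 %ΔR/R
  noise per binned pixel and ≈0.012 % on a ~300-pixel region trace.
  Real per-trial variability also contains biological amplitude fluctuations,
  which the generator deliberately does not model: recovery tests quantify
  pipeline fidelity, not biology.
* **Rendering grid**: the voltage field is generated at the binned analysis
  resolution and upsampled by the bin factor, so analysis-side binning
  recovers homogeneous region blocks. This removes boundary-bin dilution
  that would bias amplitude recovery for reasons unrelated to the method.
  Dark frames (1–25) carry offset + noise only; vessel pixels render at
  offset level in all frames; 12-bit clipping is applied after noise.
* **Reduced sensor**: `SyntheticConfig.reduced(scale)` divides the
  1200×1920 sensor by an integer scale while scaling the pixel pitch
  (14.55 µm at binned full resolution), keeping the millimetre field of view
  and atlas geometry unchanged. Validation runs use scale 5 (240×384 raw,
  60×96 binned); unit tests use scale 10.
* **Behaviour camera**: a deterministic textured silhouette (so a ≥2 px
  displacement is guaranteed detectable) plus Gaussian noise (σ = 1 DN,
  8-bit). During a movement epoch a patch covering a configurable area
  fraction (default 5 %) is displaced by (3, 3) px. The stationary-reference
  ("fabric mouse") recording is 600 frames by default — longer than a trial,
  as a noise calibration should be. Neither the behaviour-camera resolution
  nor the reference-recording length is constrained by the protocol; both are
  configuration.

## Numerical and procedural choices

* **Frame indexing** is 1-based inclusive in all configs (matching lab
  conventions like "dark frames 1 to 25") and converted to 0-based in one
  function. The stimulus default is frame 125: 250 ms of recording before the
  excitation light plus 1000 ms of illumination.
* **Baseline/R₀ window** defaults to frames 31–120: a 90-frame, 900 ms
  window that ends before the stimulus. (A 30–120 inclusive window would be
  91 frames; 31–120 is the 90-frame reading consistent with the stated
  count.) Both windows are configurable.
* **Heartbeat detection** uses the magnitude of the discrete Fourier
  coefficient nearest the peak of the valid-pixel-mean amplitude spectrum
  within the 5–14 Hz band, computed on the lit pre-stimulus segment (frames
  26–124) after mean removal, no window function by default (Hann optional).
  The pre-stimulus segment avoids stimulus-evoked power leaking into the
  gain. If no peak stands ≥2× above the in-band median amplitude, the gain
  falls back to 1 with a provenance warning.
* **Per-pixel gains** are clipped to [0.2, 5] and median-filtered 3×3 to
  suppress noise-dominated pixels; a global-gain mode exists for comparison.
  Per-pixel gain noise leaves a small residual heartbeat in region traces
  that averages down with region size; with the default noise and ~300-pixel
  regions the net effect on recovered peak amplitude is a few percent
  (positive, since the 20–100 ms peak window spans a full heartbeat cycle and
  a max statistic picks up the crest). The donor is the rescaled channel;
  ΔR/R is invariant to that choice when the gain is exact.
* **Ratio validity**: donor positivity is required over illuminated frames
  only — dark frames contain no fluorescence and are never interpreted as
  ratios. Pixels with non-positive baseline F₀, vessel pixels, and pixels
  outside the hemisphere mask are excluded from every downstream average.
* **Vessel masking**: Otsu or fixed-threshold binarisation of a raw lit donor
  frame. The Otsu path applies only when the frame is genuinely bimodal
  (dark-class mean < ½ bright-class mean); otherwise it returns an empty mask
  with a warning, since thresholding a unimodal noise distribution would
  discard half the window.
* **Atlas rasterisation** uses pixel-centre containment with
  boundary-inclusive tie-breaks; first region wins where user polygons
  overlap. The packaged S1FL/S1HL/S1BF/M1/M2 polygons are approximate
  stereotaxic rectangles relative to bregma; they are a user-replaceable YAML
  input, and provenance records which layout was used. Alignment between
  animals is rigid (bregma translation + midline rotation), no scaling.
* **Metrics**: peak window 20–100 ms inclusive (frames stim+2 … stim+10 at
  100 Hz); baseline = 10 frames immediately before the stimulus (SD with
  ddof = 1); inclusion boundary is ≥ 2×SD (the literal complement of
  "less than 2×SD excluded"); ties in peak/minimum searches resolve to the
  earliest frame. Hyperpolarisation amplitude is reported as a positive
  magnitude with an explicit sign-convention field. Decay-to-50 % uses linear
  interpolation between bracketing frames (frame-resolution mode available)
  and is NaN — flagged, not an error — when never reached. Paired-pulse
  baselines are the mean of 2 frames (20 ms) immediately before each
  stimulus; a single-frame baseline is configurable but noise-dominated.
* **Asymmetry index**: the printed formula subtracts half the both-paw
  contacts; AI = (right − ½·both)/(right + left + both). A plus variant
  (which yields 0.5 for symmetric use at any `both` count) is implemented as
  an option; the minus variant is the default. For `both = 0` the two agree.
* **Movement calibration**: the default per-pixel threshold is the full
  excursion (max − min) of the stationary recording — the envelope of
  differences "between the frames". A max-against-reference statistic and
  percentile modes are available; the envelope is the default because the
  reference-conditioned maximum leaves a quiet trial whose own stimulation
  frame lands in the noise tail with ~0.5 % changed pixels, right at the
  classification boundary. All statistics satisfy the self-consistency
  invariant (the calibration stack itself classifies quiet, exactly 0 %
  changed pixels). The 0.5 % separator is strict (>), and the classifier
  records whether the exceedance falls within ±100 ms of the stimulus.
* **Map averaging** translates each trial's bregma to the canvas centre and
  rotates the midline to vertical with nearest-neighbour sampling — the most
  literal implementation of "no additional spatial or temporal filtering";
  each output pixel is a plain mean of exactly one input pixel per
  contributing trial. Pixels with no contributing trial are NaN, never
  rendered as 0. Trials are weighted equally (per-trial, not per-animal);
  per-animal weighting can be had by averaging per-animal maps first.

## Validation problem sizes

Parameter-recovery runs use 100 trials per condition at the scale-5 sensor
(240×384 raw, 60×96 binned) with the default noise floor: recovered mean
S1FL/S1BF peak amplitudes land within ~5 % of configured truth (the residual
is the max-statistic noise bias described above), and the mean recovered
time-to-peak is within ~2 ms of truth under 10 ms per-trial latency jitter.
Unit tests use scale 10 for speed. The inclusion-rule false-positive rate is
checked against an independent vectorized Monte-Carlo of the same rule.

## Known limitations

* The generator has no biophysical hemodynamics, breathing, photobleaching
  (optional linear/exponential multiplicative stress terms exist, default
  off), no action potentials, and no biological amplitude variability —
  passing recovery tests demonstrates pipeline fidelity on data satisfying
  the pipeline's own assumptions, not performance on arbitrary real
  recordings.
* The packaged atlas polygons are approximations; quantitative use on real
  data requires the lab's own traced layout.
* Heartbeat equalization assumes a common phase between channels and a
  quasi-stationary heart rate over the trial; a drifting heart rate smears
  the spectral peak and degrades the gain estimate.
* Whether the original processing estimated per-pixel or one global
  equalization gain is ambiguous; per-pixel is the default here and a global
  mode is provided.
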