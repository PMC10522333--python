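# Methods

`usvloc` localizes rodent ultrasonic vocalizations (USVs) on an interaction
platform and assigns them to individual mice by fusing two acoustic
localizers with complementary failure modes: delay-and-sum beamforming on a
64-channel overhead MEMS array ("cam64") and pairwise-TDOA localization on
four high-quality peripheral microphones ("usm4", SLIM-style).  This note
describes the models, the parameters that matter, the synthetic scenes used
to validate the system, and the numerical choices made where the design was
genuinely open.

## Scene model and coordinate conventions

All positions live in a platform-centred world frame: origin at the centre
of the 400 x 300 mm platform surface, x along the long edge, z up,
millimetres everywhere.  The default scene places the 64-microphone array in
a Vogel (golden-angle) Fermat spiral over a 160 mm circle at z = 465 mm,
shifted +65.2 mm along x; the four peripheral microphones sit 50/60 mm
beyond the platform corners at z = 121 mm; audio is sampled at 250 kHz.
The exact spiral coordinates of a physical array are not critical: every
algorithm takes microphone positions as data, so a measured geometry can be
substituted via the JSON scene config.

Localization is restricted to a fixed plane 10 mm above the platform
(approximately snout height), extended 50 mm beyond every platform edge
(500 x 400 mm scan surface).  No z-resolving localization is attempted.
The speed of sound defaults to 343 m/s (dry air at 20 degC, the housing
temperature); it is a config field.  The four-microphone localizer assumes
the same z = 10 mm source plane as the beamformer.

## Beamforming ("cam64")

For one call with per-channel snippet spectra `S_m(f)` the steered-response
power on the scan plane is

    P(x, y) = sum_f | sum_m S_m(f) exp(+i 2 pi f tau_m(x, y)) |^2 ,

with `tau_m` the travel time from the candidate node to microphone m.  The
steering phases conjugate-cancel the propagation delays, so power adds
coherently at the true origin.  (A common shorthand writes this sum without
the signal term, which would make it signal-independent; the implementation
uses the full steered-response-power form above.)

Numerical choices:

- Snippet spectra come from one FFT of the whole call interval (rectangular
  window).  The frequency set is the FFT bins inside the call's estimated
  band, decimated by a uniform stride to at most 64 bins; uniform spacing
  enables an exact phase-recursion evaluation (one complex exponential per
  grid, then one complex multiply per bin) that is ~10x faster than
  per-bin exponentials and bitwise-equivalent up to rounding.
- Two-step scan: coarse 10 mm grid over the full surface (node-centred,
  inclusive endpoints: 51 x 41 nodes), then a fine 1 mm grid over a
  30 x 30 mm window (31 x 31 nodes) centred on the coarse argmax, clipped
  at the surface boundary.  The reported origin is the local raw-power
  weighted average of the mainlobe: cells within 5 mm of the fine argmax.
  Averaging over the whole window was tried first and rejected — the
  sidelobe pedestal (which integrates to several times the mainlobe mass
  over 31 x 31 cells at 64 channels) drags the centroid toward the window
  centre by 1-2 mm whenever the true source sits off-centre.  Channels
  are uniformly weighted.
- Per call, SNR = max/std over the coarse full-surface field (population
  std).  1/SNR is the method's intrinsic uncertainty proxy, later
  calibrated to millimetres (below).  A constant field yields an infinite
  sentinel and the call is flagged unusable.

## Four-microphone TDOA localization ("slim")

For each of the six microphone pairs, the time difference of arrival is
estimated by generalized cross-correlation with parabolic sub-sample
interpolation, clamped to the physically possible range.  PHAT weighting is
the default (robust for frequency sweeps); plain cross-correlation is
available by flag.  Whitening is restricted to cross-spectrum bins inside
the call band and to bins above 1e-6 of the peak magnitude — whitening
leakage bins would otherwise swamp the correlation.  A pair with no
correlation peak above 4 standard deviations contributes nothing; at least
3 usable pairs are required for an estimate.

Each pair's TDOA constrains the source to a constant range-difference curve
(hyperbola branch) on the scan plane.  Curves are rasterized onto a 1 mm
accumulation grid with a Gaussian kernel of sigma = 2 mm applied to the
range-difference residual in millimetres.  (This is not exactly the
curve-normal distance — the gradient magnitude of the range difference
varies between 0 and 2 across the plane — but the approximation only
modulates the kernel width, not the zero set.)  The estimate is the
density-weighted centroid of all cells above 90% of the density maximum;
the uncertainty is the standard deviation of those cell positions, floored
at 1 mm to avoid zero-variance degeneracies.  Pairs are combined with
uniform weights.  This module is a reconstruction from the published
summary of the SLIM approach (pairwise manifolds, intersection density,
>90% spread rule), not a port of the original implementation.

## Detection, band rule, clock alignment

Calls are detected on the band-passed (30-110 kHz, zero-phase order-20
Butterworth; the zero-phase forward-backward form is our reading of the
"order 20" band-pass specification) peripheral channels with a
spectrogram band-energy detector: integrated in-band power per frame
(512-sample FFT, 75% overlap; ~488 Hz x 0.5 ms resolution), hysteresis
thresholds at +6/+3 dB over the per-channel median frame power, 5 ms
minimum duration, 10 ms merge gap; a call need only be detected on one
channel.  The per-frame peak statistic was rejected: the maximum over ~160
noise bins exceeds any usable threshold on pure noise.  This detector is
plumbing (the reference detector for real data is an external tool); its
thresholds are ours and were set for >=95% recall/precision at 10 dB
in-band SNR.

Each call's frequency band is the 10th-90th percentile of the per-frame
peak frequencies, broadened by 5 kHz at both ends, capped at 95 kHz at the
top (MEMS noise dominates above), with the lower end reset to 45 kHz when
the resulting range exceeds 50 kHz.  One peak per frame is assumed
(harmonics are not separated).  The band is additionally kept non-empty
(lower end at least 5 kHz below the top) so that ridges pressed against
the 95 kHz cap still yield a usable band.  Beamforming restricts its
frequency set to this band rather than time-domain filtering the
64-channel data — equivalent for a frequency-domain beamformer.

The two recorders run on independent clocks.  Two broadband clicks near
the start and end of each trial are detected on both streams and an affine
clock map (offset + drift) is fitted exactly through the two pairs.
Detected call times (peripheral-microphone clock) are mapped through this
fit when slicing the 64-channel recording.

## Assignment: Mouse Probability Index and fusion

The mouth of mouse k lies on the snout-to-head-centre line:
`mouth = snout + f (head_center - snout)`, f = +0.02 for manually-tracked
style markers and f = -0.15 (ahead of the snout) for automatic-tracker
style markers.  For a method's estimate with calibrated uncertainty sigma,

    P_k = N(origin - mouth_k; sigma^2 I_2),   MPI_k = P_k / sum_m P_m ,

an isotropic 2D Gaussian (dimensionality/isotropy is our choice; the
source description does not specify it).  Mice farther than 50 mm from the
estimate get P_k = 0 — without the gate, the MPI normalizes confidently
between uniformly implausible candidates.  The gate is applied inside the
MPI rather than only at selection.

The intrinsic uncertainties (1/SNR; >90% spread) only correlate with
millimetre error, so each method's values are scaled such that their mean
over all calls equals the method's mean residual distance to the nearest
mouth over the far condition (all snouts >100 mm apart, where the nearest
mouse is essentially always the emitter; with a single mouse every call
qualifies).  Calibrated sigmas are floored at 1 mm.

Fusion: per call, each method's top MPI is tested against 0.95 (and the
50 mm gate).  Exactly one reliable method: that method is selected.  Both:
the one whose estimate lies closer to its own top mouse wins, with exact
ties preferring the beamformer (higher intrinsic precision).  Neither: the
call stays unassigned, with the reason recorded (low MPI / distance gate /
no estimate).  The selection-stage variant that pre-picks the beamformer
whenever its field SNR exceeds 5 is available behind a flag (off by
default), as are two alternative fusion strategies for comparison
experiments (inverse-variance maximum-likelihood combination of the two
origins, and pure largest-MPI selection); the default rule is the one that
maximizes reliable assignments at minimal residual.

Pose is read at the temporal midpoint of each call, nearest frame, no
interpolation (the ~18 ms inter-frame interval is small against mouse
motion at these precisions).  A residual systematic shift between acoustic
and video frames (array-placement measurement error, typically 0.5-2 mm)
can be estimated as the mean (estimate - mouth) vector over assigned calls
and subtracted, with one re-run of the assignment.

## Camera model

Radial distortion follows `x_d = x_c + atan(r/lambda)/(r/lambda) (x_u -
x_c) Z_x` (and likewise in y); tangential distortion subtracts a term
proportional to the distance from the tangential centre scaled by the
platform size in the image.  Both maps are applied literally in their
printed forward form, radial first; inverses are numeric (bracketed root
find on the radius; fixed-point iteration) and round-trip below 1e-6 px.
Fitted parameter values for a physical lens are config-supplied; defaults
are identity-like, and synthetic tracks bypass distortion entirely.
Pixels are 0-based, origin top-left, y down; the world conversion flips y
and uses 0.815 mm/px with the camera's ground-point offset (-44.8, 0) mm.

## Spatial statistics

Relative positions are expressed in a polar frame on the emitter's snout:
radius = snout-snout distance, angle measured from the gaze direction
(head-centre -> snout at 0 deg) to the receiver, folded into [0, 180] deg
(no left/right preference assumed; the receiver marker is a parameter, so
abdomen- or tail-centred maps use the same machinery).  Histograms use
half-open 10 deg x 10 mm bins with an overflow radial bin beyond 200 mm,
so mass is conserved.  Group differences are assessed by rebuilding each
group's density-normalized histogram from 100 bootstrap resamples; per
bin, the most extreme up/down deviations from the observed density define
the confidence limits, and a bin is flagged when the observed difference
exceeds the combined limits of the two groups in either direction.  At the
default level this is deliberately conservative (measured null false-flag
rate is ~0, bounded at 2% in the tests).  Group-level tests (rank-sum,
Kruskal-Wallis, Spearman, Bonferroni) are thin wrappers over scipy.

## Synthetic scenes: what they emulate, and what they do not

The generator renders both microphone sets for moving mice on the
platform:

- Trajectories: smoothed, boundary-folded random walks of the body centre;
  gaze direction is an independent smooth angular walk; snout and
  head-centre markers sit +/-12.5 mm along the gaze.  The "close" profile
  keeps partners orbiting at ~40 mm (close-contact fraction matching
  courtship data: most frames within 10 cm snout-snout distance); "far"
  holds ~170 mm separation for the low-confusion regime; "free" walks
  independently.
- Calls: linear (or logistic) frequency sweeps, default 50-80 kHz, 40-60 ms,
  log-normal amplitude spread, emitted from the snout at z = 10 mm, one
  per ~180 ms slot.  A very-high-frequency subclass (90-110 kHz) can be
  mixed in to exercise the MEMS array's weakness.
- Propagation: anechoic; exact fractional-sample delays via FFT phase
  shift (inter-channel TDOA differences across the overhead array are
  fractions of a sample at 250 kHz, so sample rounding is not an option)
  and 1/r spherical spreading (gain 1 at 100 mm).  Sources are
  omnidirectional points — no snout directivity model, no body occlusion
  or reverberation (an optional attenuation/reflection term was considered
  and left out; the phenomena are only qualitatively characterized).
- Sensor noise: the MEMS model is flat Gaussian noise plus an independent
  differentiated component giving a ~+6 dB/octave power rise above a
  60 kHz knee; the peripheral model is flat.  Noise level is set to a
  requested in-band (30-110 kHz) SNR relative to the mean per-channel call
  power; generation is chunked so 64-channel scenes stay within a few GB.
- Clocks: the two recordings run on affine-related clocks (default offset
  12 ms, drift 1.00002) with two loud broadband clicks inserted on both.

Because the simulation is anechoic, uses exactly-known geometry, and emits
omnidirectional point sources, it is an *easier* regime than a real
recording: passing the accuracy bounds shows the algorithms are correct
and well-conditioned, not that a physical installation will reach the same
numbers.  Conversely, printed real-data accuracies serve as upper bounds
that the simulation must beat, which is the logic of the benchmark suite.

## Benchmark problem sizes

The standard benchmarks pool two 100-call trials per condition (dyadic
close-contact; wide-separation; single animal) at 10 dB in-band SNR, plus
a 5 x 5 noise-free static-source grid spanning the platform
(speaker-calibration style).  Multi-trial pooling mirrors the multi-trial
structure of real datasets and bounds the memory of the 64-channel renders
(one ~19 s trial at a time).  Reported values: median absolute 2D error of
assigned calls against ground truth (hybrid, and each method over its own
reliably-assignable subset via assignment re-runs with the other method
withheld), far-condition accuracy and assignment rate, single-animal
accuracy, and the static-grid median error.

## Known limitations

- The detector is not the reference real-data detector; overlapping calls
  are merged, harmonic stacks are not separated (rare in the target data).
- No multi-peak sound-field decomposition for simultaneous emitters.
- SLIM here is a reconstruction from a published summary, not the original
  analytic-manifold implementation; accuracy contracts (estimate + >90%
  spread rule) are honored, internals differ.
- The uncertainty calibration assumes the far condition is abundant enough
  to estimate a mean residual; datasets without far calls fall back to an
  unscaled (unit) calibration.
- Simulated accuracy is substantially better than printed real-data
  accuracy because the simulation omits occlusion, directivity and
  geometry error; see above.
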