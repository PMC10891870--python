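# Methods

This note documents the models implemented in `pigvoc`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical choices that matter.

## Kalman denoising (`pigvoc.denoise`)

The enhancer is the classic autoregressive formulation of Kalman speech
enhancement.  Within each 20 ms analysis frame the clean signal is an
order-*p* AR process; the state vector holds the last *p* clean samples,
the transition matrix **A** is the AR companion matrix, the observation
row is **H** = e₁ᵀ, the process noise is Q = diag(σ_e², 0, …, 0) with σ_e²
the AR residual variance, and the measurement noise variance *R* models
the stationary background.  Each sample passes through predict
(x(k|k−1) = A x(k−1|k−1), P(k|k−1) = A P A′ + Q), gain
(g = P H′/(H P H′ + R)), update (x(k|k) = x(k|k−1) + g(z − H x(k|k−1))),
and covariance update (P(k|k) = (I − gH) P(k|k−1)); the filtered sample is
H x(k|k).

Choices and defaults:

- **AR refit per frame** (20 ms), not once per recording: vocalizations
  are nonstationary while the noise is approximately stationary.  The AR
  model is fit to the *noisy* frame by the autocorrelation (Yule–Walker)
  method — the standard approximation when no clean reference exists.
- **AR order 12** (default): typical for speech-band spectra at 8–44.1 kHz;
  configurable.
- **R estimation**: variance of a supplied noise-only reference, else
  minimum statistics — the mean power of the lowest-energy 5% of frames.
- Explosive AR fits (poles on or outside the unit circle) are shrunk to
  pole radius 0.98; the covariance is symmetrized after every update to
  keep P positive semi-definite under round-off.
- `snr_db` is 10·log₁₀(Σclean²/Σ(test−clean)²), capped at 100 dB when the
  residual is zero.

On AR-process "voice" plus white noise at 5 dB input SNR the filter gains
about +2.5 dB (measured by `scripts/acceptance.py`); the improvement sign,
not its magnitude, is the tested property, since the gain depends on the
spectra of signal and noise.

## Endpoint detection (`pigvoc.endpointing`)

Four stages: (1) EMD of the waveform by cubic-spline envelope sifting
(Huang's SD stopping criterion, tolerance 0.2, ≤ 30 sifts, ≤ 6 IMFs; an
IMF is accepted when its extrema and zero-crossing counts differ by at
most one); (2) selection of the IMFs whose spectral centroid lies in a
configured band (default 0.1–14 kHz, clipped to Nyquist; a top-k-by-
correlation rule is selectable), then the Teager energy of their sum
(per-IMF TEO with summation available behind a flag); (3) a short-time
cepstral-distance track — the Euclidean distance between each frame's
magnitude real cepstrum (quefrency bins 1–12, log floor 1e−10) and the
mean cepstrum of the leading noise-only frames; (4) a two-level decision:
frames whose TEO energy exceed the high threshold seed segments, which
extend outward while above the low threshold, and frames adjacent to a
candidate boundary whose cepstral distance exceeds its threshold are
annexed (contiguously, at most 5 frames per boundary).

Thresholds are adaptive: high = noise mean + 5·s, low = mean + 2·s, where
the noise statistics come from the first 100 ms and s = max(std,
0.2·mean).  The floor on s matters: ten frames of noise underestimate the
spread of frame energies, and without it the low threshold sits inside
the noise fluctuation band and extends boundaries through noise runs.
Because mean and std both scale with the square of the waveform
amplitude, detection is invariant under gain changes.  Segments shorter
than 100 ms are dropped and gaps shorter than 150 ms merged.

On synthetic bursts at ≥ 10 dB SNR the detector recovers ≈ 99% of
boundaries within ±30 ms (50 seeded clips; the ±30 ms budget is ~3 hops
at the 20 ms/10 ms framing).

## MFCC features (`pigvoc.features`)

Pre-emphasis y(n) = x(n) − 0.98·x(n−1); 20 ms frames with 10 ms hop, full
frames only (1 s at 44.1 kHz gives ⌊(44100−882)/441⌋+1 = 99 frames);
Hamming window; power spectrum; 26 triangular mel filters (HTK scale,
m = 2595·log₁₀(1 + f/700)) spanning 0 to Nyquist; log with floor 1e−10;
orthonormal DCT-II; coefficients 0–12 kept.  c₀ is retained as the first
static coefficient rather than replaced by log-energy, keeping D = 13
without an extra energy term.  Deltas use the regression formula with
window N = 2 (denominator 2Σn² = 10) and edge replication; ΔΔ applies the
same operator to Δ.  Splicing concatenates frames t−3…t+3 with edge
replication: 39 × 7 = 273 inputs per frame.  Cepstral mean normalization
is deliberately not applied (available nowhere in the pipeline; adding it
would change the classifier contract).

## GMM-HMM (`pigvoc.gmm_hmm`)

One left-to-right HMM per call type: N = 5 states, π = [1, 0, …, 0],
transitions restricted to self-loop or advance (upper-bidiagonal,
row-stochastic, last state absorbing — chosen so whole-segment scores are
well defined), and per-state diagonal-covariance GMMs with K = 4
components by default (K = 1 gives the "base HMM" ablation).  Variance
floor 1e−3 on every dimension.

- **Flat start**: each training sequence is cut into N equal-duration
  blocks; state j pools the frames of block j, and component k is seeded
  from the k-th temporal sub-block.  This is fully deterministic and
  invariant under duplicating training sequences (a k-means seeding is
  not, which is why it was not used).  Initial transitions are 0.5/0.5.
- **Baum–Welch**: log-domain forward–backward; state, pair and component
  posteriors (γ, ξ, γ_mix); numerators and denominators accumulated over
  all sequences before dividing.  Zero transitions stay zero because they
  contribute zero expected counts.  40 iterations, relative log-likelihood
  tolerance 1e−6.  Empty components keep their previous parameters with a
  warning; weights are floored at 1e−8 and renormalized.
- **Decoding**: log-domain Viterbi with ties broken toward the lower
  state index; classification scores every class model and takes the
  argmax (Viterbi score by default, forward likelihood selectable).

Correctness is anchored by exhaustive path enumeration on N = 3, T = 6
instances (forward and Viterbi agree to 1e−10) and by hmmlearn as an
independent implementation of the forward pass.  The EM fixed-point test
initializes at the generating parameters of a well-separated model
(emission variance 0.0025, self-loops 0.995, 200 sequences of T = 700 —
sizes chosen so the sampling noise of one M-step sits below the 1e−3
movement bound) and checks that one iteration moves nothing beyond that
noise.

## Posterior network (`pigvoc.dnn`)

Input 273 → three ReLU hidden layers of 128 → softmax over 25 class-state
units (class-major indexing: unit = class·5 + state).  Training minimizes
mean cross-entropy on frames labelled by forced alignment: He-normal
initialization, Adam (lr 0.003, β₁ 0.9, β₂ 0.999, ε 1e−8), batch 100,
up to 10 epochs with a cap of 200 optimizer steps per epoch, stratified
10% validation split, early stopping after 3 non-improving epoch-end
checks, relative-loss tolerance 1e−6.  The update direction is descent;
gradients are exact (softmax+CE fused output delta, ReLU masks) and
verified against central finite differences to 1e−5 relative.  Training
is bit-deterministic given the seed.

## Hybrid decoding (`pigvoc.hybrid`)

State priors p(q) come from forced-alignment frame counts with add-one
smoothing, guaranteeing strictly positive priors.  Scaled log-likelihoods
are log p(q|x_t) − log p(q) (posteriors floored at 1e−12); the
class-independent per-frame term log p(x_t) is dropped — a perturbation
test confirms per-frame constants cannot change any decision.  Each class
is decoded in its own 5-state trellis with its π and transition matrix
from the trained GMM-HMM (the max-approximation of the path sum); the
label is the argmax of class scores.  A single 25-way softmax is used
rather than five separate 5-way ones.

## Synthetic data (`pigvoc.synthetic`)

Each clip is a harmonic source — fundamental f0 with a flat, rising,
falling or pulsed trajectory, harmonics at k·f0 with 1/k amplitudes —
shaped by a parallel bank of resonant (peak) filters at the spec's
formant centers, an amplitude envelope (sustained, or a raised-cosine
burst train), optional leading/trailing silence, plus background noise
(half white, half low-passed below 3 kHz, emulating fan/machinery noise)
scaled so the clip-level SNR against the clean reference is exact.  The
five default specs differ in f0 range (90–480 Hz), trajectory, harmonic
count and formants so their spectra occupy distinct bands from ~0–4 kHz
(humming) up to the Nyquist limit (howling); eating and panting are
deliberately confusable (both pulsed, overlapping formants).  Defaults:
16 kHz sample rate, 50 clips per class, 10 dB SNR, stratified 8:2 split.
Everything is deterministic given the seed, and every clip carries its
clean reference and true boundaries.

What the generator does **not** emulate: real glottal excitation and
vocal-tract dynamics, reverberation, overlapping animals, non-stationary
noise, recording-chain artifacts, and intra-class variability beyond
f0/duration/phase jitter.  Passing the end-to-end tests therefore shows
the pipeline is correctly assembled and separates classes whose cues
(f0, spectral envelope, temporal envelope) match its modelling
assumptions — it does not certify field performance on real recordings,
where class overlap is far larger.  On this synthetic task all three
classifiers sit near ceiling at 50 clips per class; the tested property
is the ordering (hybrid ≥ GMM-HMM within 0.02, GMM-HMM > 0.6), not the
absolute level.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
16 kHz fixtures, 50 clips per class end-to-end, 50 clips for boundary
recovery, 10 denoising trials, 100 enumeration instances, and the EM
simulations described above.

## Known limitations

- The Kalman filter fits AR coefficients to noisy frames; at very low SNR
  the fitted spectrum tracks the noise and the gain shrinks.
- EMD sifting on long recordings is O(sifts × n log n) and becomes the
  front-end bottleneck above a few seconds of audio.
- Whole-segment classification only: no continuous decoding over
  unsegmented streams, no language model, no lattice output.
- Diagonal covariances assume decorrelated features — reasonable for
  MFCCs, wrong for raw filterbank energies.
- `read_wav` handles PCM and float WAV only (no MP3/FLAC), mono or
  averaged stereo.
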