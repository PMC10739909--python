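# Methods

This note documents the models, estimators and numerical choices behind
`thetaflow`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Signal model and preprocessing

Recordings are time × channel arrays in microvolt-scale arbitrary units
with a channel table (label, region, probe, contact index).  The
canonical conditioning order is **downsample → notch → Laplacian →
artifact detection → epoching**.

* **Downsampling** uses polyphase resampling with the default
  Kaiser-windowed anti-alias low-pass (`scipy.signal.resample_poly`).
  Event times are kept in seconds and are unaffected.
* **Line-noise removal** applies a 2nd-order Butterworth band-stop of
  ±1 Hz at 60 Hz and its 2nd–3rd harmonics.  All IIR filters run
  **forward–backward (zero-phase)** by default: instantaneous phase feeds
  the transfer-entropy estimator, and phase distortion would corrupt the
  directed measure.  The effective filter order doubles; a causal
  single-pass mode is available per call.
* **Laplacian re-referencing**: interior contact N on a probe is
  referenced to the mean of contacts N−1 and N+1.  Edge contacts fall
  back to a bipolar reference against their single neighbor (default) or
  can be dropped; single-contact probes are dropped with a logged reason.
* **Artifact detection** flags samples beyond the channel mean ± k·SD
  (default k = 4, conventional range 3–4.5 enforced unless overridden),
  with statistics over the whole continuous channel; non-finite samples
  are treated as artifacts before thresholding; flags are dilated ±1 s.
  The signal itself is never modified — any trial whose epoch window
  touches a flagged sample is excluded with a recorded reason.
* **Epoching** uses half-open windows [start, end) in seconds relative to
  stimulus onset or response; time t maps to sample floor(t·fs), 0-based.

## Wavelet power and baseline normalization

Power is extracted with analytic Morlet wavelets (dimensionless center
frequency ω₀ = 6) on a logarithmic grid from 3 to 200 Hz with 32 voices
per octave, truncated below Nyquist.  The transform is
`mne.time_frequency.tfr_array_morlet` with `n_cycles = 6` (identical
parameterization).  Epochs are zero-padded so the longest wavelet fits
and cropped back afterwards; edge voxels sit inside the wavelet's cone of
influence and should be interpreted with care.

Each frequency row is **unit-gain normalized**: power is rescaled so a
sinusoid at a wavelet's center frequency yields power equal to its
squared amplitude.  L2-normalized wavelets would otherwise bias a tone's
spectral peak roughly one voice low on a fine log grid (the √σ_t gain
factor grows toward low frequencies); unit gain makes dB values
amplitude-interpretable and peak locations unbiased.

Power in dB (10·log₁₀) is z-scored per trial, channel and frequency
against the mean and SD of pre-stimulus dB power pooled over the
baseline windows of **trials of the same condition** (artifact samples
excluded from the normalizing distribution only).  The baseline window
length is not dictated by the task structure; the default is
[−0.5, 0) s, configurable.  Two alternative modes — pooling baselines
across all conditions, and normalizing against every time point of every
trial — support robustness checks; a planted band-limited power effect
keeps its sign across all three (tested).

Trial-averaged maps/traces subtract the mean over the 0.2 s before the
alignment event so traces start at zero at stimulus onset.  Channel
selection ("cue responsivity") marks a channel responsive when mean
3–6 Hz power in [0, 1) s exceeds [−0.3, 0) s in a one-sided unpaired
permutation test (1000 permutations, α = 0.05, uncorrected — this is
selection, not inference), run per condition and on pooled trials.

## Cluster-based permutation testing

For a paired condition contrast across observations (channels, or trials
in individual-subject mode): per-voxel paired t; a null of 1000 t-maps
from flipping each observation's condition labels independently with
probability ½; two-sided voxel p as the rank of |t| within the null |t|
at the same voxel (float-level ties counted — important at small n,
where the observed sign pattern recurs among permutations); voxels with
p below the cluster-forming threshold grouped into connected components
(8-neighborhood default, 4 available) separately for positive and
negative t; each observed cluster's size compared with the null
distribution of per-permutation maximum cluster sizes of the same sign
(significant above the 95th percentile).  The measured family-wise error
on identical-distribution conditions is ≈ 0.055 at nominal 0.05 (200
replicates; in the binomial CI).  The cluster-forming threshold defaults
to p < 0.05; a literal 0.5 is accepted via configuration for
compatibility with reports that print that value.

## Phase transfer entropy

Instantaneous phase comes from a zero-phase 3rd-order Butterworth
band-pass (default 4–5 Hz) followed by the analytic signal, wrapped to
[−π, π).  (Wavelet phase at band center is a recognized alternative;
filter+Hilbert was chosen as the default because the band is explicit
and the filter's passband is directly controllable.)

For a sender X and receiver Y at lag τ (default 100 ms = 50 samples at
500 Hz, rounded to nearest):

    PTE_X→Y = H(Y_t | Y_{t−τ}) − H(Y_t | Y_{t−τ}, X_{t−τ})

with plug-in entropies in bits (0·log₂0 := 0) from histograms of the
triplets (Y_t, Y_{t−τ}, X_{t−τ}) pooled across **all** retained trials
(never a single trial).  Bin widths follow Scott's choice,
w = 3.49·σ·n^(−1/3), computed per axis from that axis's pooled samples
with σ the ordinary (linear) SD of the wrapped phases; the bin count is
⌈2π/w⌉ over [−π, π).  Marginals are sums of the joint, so the chain rule
H(A|B) = H(A,B) − H(B) holds to machine precision (tested against a
brute-force sum over all outcome cells).

Both directions are computed from the same pooled samples with roles
swapped and combined as nPTE = PTE_X→Y/(PTE_X→Y + PTE_Y→X) − 0.5, which
is bounded in [−0.5, 0.5], exactly 0 for identical series, and exactly
antisymmetric under orientation swap.  A degenerate (0, 0) raw pair maps
to 0 with a logged flag so batch runs survive information-free windows.

**Estimator bias.** The plug-in estimate of each directed term is biased
upward, and the bias grows as the sample count shrinks or the bin count
grows.  Consequences worth knowing: the *magnitude* of nPTE from short
moving windows is not comparable to the time-averaged value (the
moving-window mean sits visibly above it in simulations — sign and time
course are the comparable quantities), and any contrast should compare
like against like (same window length, same trial counts).

**Time-resolved PTE** repeats the full computation in moving windows
(default 0.5 s, 10 ms step; 50 ms supported), pooling triplets across
trials within each window.  Stored timestamps are window *starts*
relative to the alignment event; plots may display centers, stored data
never does.

**Surrogate ("chance") test.**  Per iteration every pair's sender phase
series is shuffled, the receiver untouched, and the pair-averaged nPTE
recorded; p = (# null means ≥ observed)/n_iter.  The default shuffle is
**whole-trial exchange** (the sender's trials re-paired with the
receiver's by a random permutation): it destroys any sender–receiver
dependence while preserving each trial's temporal structure, so under
independence the null statistic is exchangeable with the observed one
and the p-value is calibrated (measured approximately uniform at κ = 0).
Within-trial sample permutation is available but **not** the default:
destroying the sender's autocorrelation shifts the histogram plug-in
bias of both directed terms (the null normalized PTE concentrates near
−0.25 for smooth band-limited phases even under independence), so that
null rejects everything.  The surrogate averages the *normalized* PTE
across pairs; the raw directed term suffers the same bias asymmetry.

## Condition-contrast statistics

* Paired permutation test: observed effect = mean(A) − mean(B); each
  permutation flips each pair's labels independently with probability ½;
  two-sided p = #(|null| ≥ |observed|)/n_perm.  The plain count ratio is
  the default (it can return 0); the (b+1)/(m+1) convention is an option.
* Benjamini–Hochberg FDR at q = 0.05 (`statsmodels`), reporting the
  largest raw p passing the step-up rule as the "FDR threshold".
* Two-way repeated-measures ANOVA on units × time × condition arrays
  (own sums-of-squares decomposition, verified against pingouin):
  F(time) against the units × time interaction, F(time × condition)
  against the three-way residual; the lower-bound sphericity correction
  multiplies both df of an effect by ε = 1/(k−1) before the p-value —
  the most conservative adjustment; η² = SS_effect/SS_total.  Missing
  cells are rejected, never imputed.
* Epoch-wise contrasts run the paired test per moving window across
  channel pairs and correct across windows with BH; significant windows
  carry the direction of the observed difference.

## Synthetic-data generator

The generator is the test bed, not a biophysical model.  Sender phase is
a noisy oscillator θ_X(t+1) = θ_X(t) + ω·dt + σ·√dt·ξ (carrier 4.5 Hz,
phase diffusion σ = 1 rad/√s, giving a realistic sub-Hz linewidth);
the receiver relaxes toward the sender delayed by the coupling lag,

    θ_Y(t+1) = θ_Y(t) + ω·dt + κ·g·sin(θ_X(t−lag) − θ_Y(t))·dt + σ·√dt·ξ,

with a fixed coupling rate g = 25 rad/s so κ ∈ [0, 1] spans independence
(exactly: at κ = 0 the phases are separate random walks) to tight lagged
locking (κ = 1: ~40 ms relaxation).  Coupling and per-condition power
gains act during each trial's post-stimulus window.  Signals are
amplitude·cos(θ) plus spectrally shaped 1/f noise (exponent 1, SD 0.5
per unit carrier amplitude), 60 Hz line noise, and optional sporadic
high-amplitude square-pulse artifacts (Poisson-counted per minute).
Multichannel sessions share one latent phase per region group with small
AR(1) per-channel phase jitter, one probe per group so Laplacian
referencing applies.  Response latencies are lognormal; retrieval
responses follow the 1 s stimulus plus a 0.5 s gap before the prompt.
All randomness flows from one seeded generator per dataset; identical
seed + config is byte-identical.

What it does **not** emulate: evoked (phase-locked) components,
cross-frequency coupling, gamma-band effects, epileptiform activity,
volume conduction, non-stationary background spectra.  Passing tests
demonstrate the estimators' correctness and calibration under the stated
generative assumptions, not robustness to everything real iEEG contains.

## Problem sizes used in the test suite

The replicate studies run at sizes chosen to make the statistical checks
informative while keeping the suite quick: direction recovery uses 100
seeds of the κ = 0.8 / 60-trial configuration (recovered 100/100 in the
freezing run; the test asserts ≥ 95); null-calibration suites use 200
replicates with 200 permutations/iterations each; the cluster
family-wise-error study uses 200 datasets of 12 paired observations on a
15 × 20 grid with 200 permutations.

## Known limitations

* Plug-in PTE values are bias-dominated in absolute terms; only
  contrasts and signs at matched estimation settings are interpretable.
* The sign-flip permutation tests treat pooled channels or pairs as
  exchangeable observations; channels from one subject are correlated,
  so pooled-observation p-values are anti-conservative for
  population-level claims (use per-subject analyses alongside).
* Scott's rule is applied per axis with the linear SD of wrapped phases;
  for strongly non-uniform phase distributions a circular bandwidth rule
  would bin differently.
* The EDF writer quantizes to 16 bits over each channel's observed
  range; per-channel round-trip correlation exceeds 0.999 for LFP-scale
  data but exact sample values are not preserved.
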