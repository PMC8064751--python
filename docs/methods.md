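# Methods

`optovis` analyzes extracellular recordings from mouse visual circuits
(V1, dLGN) during optogenetic perturbation of thalamic reticular (nRT)
inhibitory neurons: how the perturbation changes LFP band power, unit
firing, and the amount of visual information carried by spiking. Because
such recordings are rarely shareable, the package ships a synthetic-session
generator with stored ground truth; every analysis stage is validated by
parameter recovery on generated data.

## Data model

A session holds multichannel LFP (µV, channels × samples at `lfp_rate`),
electrode depths (µm below pia, positive downward, grouped by shank),
sorted units (spike times in seconds from recording start, mean waveform),
a running-speed trace (cm/s on a uniform grid), and stimulus/laser event
schedules. The on-disk container is a single HDF5 file:

```
/meta                   attrs: subject_id, region, opsin
/lfp/{data,rate,depths,shanks}
/units/<id>/{spike_times, mean_waveform, waveform_rate, channel_index}  attr: sort_class
/speed/{t,v}
/events/stimulus/{onset,duration,kind,direction,spatial_freq,temporal_freq}
/events/laser/{onset,duration}
```

Trial assembly counts spikes in a half-open window `[onset + 0.5 s,
onset + 1.5 s)` — one second starting 500 ms after grating onset, skipping
the onset transient. Half-open windows make counts partition time. A trial
is laser-on iff a laser pulse overlaps the stimulus span (pulses are
locked to stimulus onset, so overlap and onset-coincidence agree). A trial
counts as *running* iff its mean speed is strictly above the threshold
(default 2 cm/s, the midpoint of the 1–3 cm/s range typically needed over
ball-tracker noise; ties fall to *still*). Trials whose state changes
mid-trial are classified by the mean — no finer rule is defined.

## Synthetic sessions

The generator's defaults encode the study conditions the analyses assume:

* Schedule: 8 grating directions × 20 repetitions × 2 s, followed by 2 s
  gray, per laser condition, randomly interleaved (640 trials of schedule,
  320 analyzed gratings); gray-screen blocks instead carry a 4 s laser
  pulse every 20 s. The schedule is an exact function of the config; only
  the interleaving order is random.
* Tuning: von Mises in direction with a half-amplitude 180°-periodic
  lobe, normalized so the mean rate over the direction grid equals the
  class base rate regardless of concentration κ (default 3). Base rates:
  10 Hz broad-spiking (BS), 16 Hz narrow-spiking (NS); spontaneous
  gray-screen rate is 0.3× base. Locomotion multiplies rates by 1.5.
* Optogenetic drive: laser trials scale rates by class/state factors
  (BS 0.79 still / 0.67 running; NS 0.65) and *flatten* tuning curves
  toward their mean by `pattern_degradation` (default 0.5). Flattening at
  fixed mean rate is the simplest mechanism producing an information loss
  that rate matching cannot explain, which is exactly the contrast the
  count-matched decoder tests. Spikes are Poisson, conditionally
  independent across units given the condition (matching the decoder's
  independence assumption).
* Waveforms: parametric trough+peak templates whose summary features
  land near the empirical class centroids (BS: height 0.20 of trough,
  trough-to-peak 0.73 ms; NS: 0.34, 0.32 ms) with 4% relative jitter.
  The NS fraction defaults to 30%.
* LFP: 1/f^2.5 background (30 µV RMS) plus band-limited gamma noise
  (55 ± 12.5 Hz, 10 µV RMS when still) plus broadband stimulus-evoked
  noise. `gamma_run_gain` (1.5) and `gamma_opto_factor` (0.5) are *power*
  ratios — the measured band-power contrasts — so amplitude envelopes use
  their square roots.
* Locomotion: a two-state Markov chain at the 0.1 s speed-bin resolution
  (P(still→run) = 0.01, P(run→still) = 0.02 per bin, ≈ still two thirds of
  the time with ~5 s running bouts); running speeds uniform 5–15 cm/s,
  still 0–0.5 cm/s.
* Noise movies: spatially low-pass-filtered white noise (σ = 0.5 px)
  driving linear–nonlinear Poisson units with difference-of-Gaussians
  (center-surround) receptive fields and an exponential nonlinearity whose
  normalization keeps the mean rate at the configured base.

What the generator does **not** emulate: correlated variability between
neurons, bursting and refractoriness, adaptation within or across trials,
laminar structure in the LFP, eye movements, or any biophysics of the
nRT→dLGN→V1 loop. Passing recovery tests therefore demonstrates the
*estimators* are correct, not that real cortex behaves this way.

## Spectral analysis

Raw LFP is zero-phase band-pass filtered (Butterworth order 4,
forward–backward, 1–300 Hz). Time-resolved power comes from a complex
Morlet transform (σ_t = cycles/(2πf), default 7 cycles, recorded in the
output metadata) evaluated on a log-spaced 2–100 Hz grid. Power is
reported as a one-sided spectral density in µV²/Hz: `2·mean|W|²/(fs·Σ|ψ|²)`,
which for white noise of variance σ² equals `2σ²/fs`, the same scaling as
`scipy.signal.periodogram(..., scaling="density")`. The test suite holds
the band-integrated Morlet power of white noise to the periodogram total.
For long sessions the transform is evaluated on padded slices around each
trial window (padding covers the lowest-frequency wavelet's support), so
memory stays flat.

The 1/f^α background (α = 2.5) is flattened by *multiplying* power with
f^α; dividing would steepen the trend and contradict flat adjusted
spectra. A flag on the spectrum object forbids double adjustment. Band
summaries are the mean power over grid frequencies inside theta (4–8 Hz),
beta (15–30 Hz) and gamma (30–80 Hz); edges are inclusive except that
beta's upper edge is open — 30 Hz is the stated gamma lower edge, and the
bands stay disjoint. Current source density is the plain second spatial
difference `−(V_{i−1} − 2V_i + V_{i+1})/h²` (sinks negative, boundary
channels dropped, uniform spacing required, same-depth channels averaged
beforehand); no spatial smoothing is applied.

## Unit metrics

Waveforms are normalized so the trough is −1; the three features are the
positive-peak height relative to the trough, trough-to-peak time, and the
waveform slope 0.5 ms after the trough (central difference; a one-sided
variant was considered but the central difference is exact for locally
linear segments and less noise-prone). NS/BS classification is 2-means on
z-scored features with deterministic farthest-point initialization — it
reproduces the bimodal split without extra hyper-parameters — and the
cluster with the longer trough-to-peak is BS. The coefficient of variation
uses the sample SD (n−1). The "optimal grating" for evoked/baseline ratios
is the direction with the highest evoked rate, ties to the lowest
direction value. Spike-triggered averages use the frame containing each
spike (lag 0) and earlier frames at integer lags; the SU/MU call is an STA
signal-to-noise score (peak |STA| in z-units of the pixel noise floor at
the observed spike count) against a configurable threshold, default 5 —
the criterion itself is a package choice, exposed rather than hidden.

## Information

Mutual information between spike counts and stimulus classes is the
plug-in estimate on the response × class contingency table,
I(R,S) = H(S) − H(S|R) in bits, algebraically equal to the double sum over
the joint table (verified to 1e−12 against a brute-force implementation).
Response symbols are raw integer counts — no binning — with an optional
tail cap for small samples; classes default to the 8 movement directions.
No bias correction is applied by default (Miller–Madow is available
behind a flag): plug-in estimates are biased up by roughly
(|R|−1)(|S|−1)/(2T ln 2) bits at T trials, which the test suite checks by
simulation, and which is why "zero information" reads as a small positive
number.

## Decoding

The decoder is a Gaussian linear discriminant with diagonal covariance:
per-class feature means, a pooled within-class variance per unit (n−K
denominator) shared across classes, and empirical priors (an equal-priors
option exists; balanced designs make them equal anyway). Variances are
floored at 1e−6 × their mean (1e−9 absolute if all zero) so silent units
cannot produce degenerate likelihoods. Prediction maximizes
`log prior − ½Σ(x−µ)²/σ²`; exact ties resolve to the lowest class index.
Accuracy is leave-one-out cross-validated; the held-out refits are
computed by downdating per-class sufficient statistics, bit-identical to
naive refitting (tested). Orientation decoding groups directions 180°
apart (8 directions → 4 classes); the class count always follows the
stimulus set and is never hard-coded, since chance level depends on it.

Count-matched decoding draws neuron subsets of increasing size — without
replacement by default (a physical neuron cannot appear twice; the
with-replacement variant is a flag) — runs LOOXV per subset within each
laser condition, and pools (population spike count, correct?) pairs over
100 subsets per size. Pairs are binned by population count using
integer-width bins merged left-to-right until each bin holds ≥ 20 samples
in both conditions; per-bin accuracy carries a bootstrap SE (1000 binomial
resamples of the binary correctness flags). Because the same trials recur
across subsets, pooled samples are correlated and the bootstrap SE
understates the true spread; comparisons between conditions therefore use
bin-averaged contrasts, not single-bin significance. The trial-subsampling
error distribution (50 stratified subsamples at a caller-chosen fraction;
the fraction is a required parameter since no canonical value exists) is
provided separately.

## Group statistics

Channels and cells nest within mice, so condition effects are tested with
a subject-stratified permutation test: the statistic averages per-subject
mean differences with equal subject weight (neutralizing
pseudo-replication), and the null permutes condition labels within subject
(paired designs) or subject assignments (unpaired);
p = (1 + #{|perm| ≥ |obs|})/(1 + n_perm), two-sided, 10 000 permutations by
default. This replaces a nested/multilevel model fit — same inferential
target, fewer distributional assumptions; a paired t-test on subject means
is provided as a cross-check. Rank tests (Wilcoxon rank-sum/signed-rank,
zero differences discarded) and Spearman correlation with Bonferroni
adjustment wrap scipy.

## Problem sizes and reproducibility

Recovery and calibration checks run at deliberately modest sizes chosen to
give stable statistics: rate-factor recovery uses the full default
schedule (160 trials per laser condition, recovery tolerance 10%); gamma
gains use a 300 s gray block measured on 2 s state-pure windows
(tolerance 15%); the rate-vs-pattern contrast uses 16-unit, 80-trial
sessions over 20 seeds with 20 neuron subsets per size; permutation-test
calibration uses 4 subjects × 50 observations × 1000 simulations at 399
permutations. The pipeline fans a single seed out to per-subject and
per-stage child seeds via `numpy.random.SeedSequence`, so reruns are
byte-identical and stages can be reproduced in isolation.

## Known limitations

* Wavelet normalization and frequency gridding are package choices;
  absolute power values match other implementations only up to a global
  scale, so cross-study comparisons should use ratios or contrasts.
* The plug-in MI is biased at realistic trial counts; comparisons should
  stay within matched trial counts and symbol alphabets, or enable the
  Miller–Madow correction.
* The hierarchical permutation test assumes within-subject
  exchangeability under the null; strong within-subject autocorrelation
  would require block permutation, which is not implemented.
* Count-matched accuracy bins inherit correlation between pooled samples
  (see above); bootstrap SEs are per-bin descriptive, not inferential.
* The generator's conditional independence between units means decoding
  results say nothing about the effect of noise correlations.
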