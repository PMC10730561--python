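# Methods

## The decoding problem

In a two-talker ("cocktail party") listening situation, low-frequency EEG
activity phase-locks to the temporal envelope of the speech a listener
attends — *neural tracking*. Auditory attention decoding (AAD) exploits
this: a linear *backward* (stimulus-reconstruction) model maps time-lagged
multichannel EEG to an estimate of the attended speech envelope, and the
candidate talker whose actual envelope correlates best with the
reconstruction is declared attended.

`aadkit` implements this pipeline in two regimes — whole-trial offline
decoding with leave-one-out cross-validation, and a simulated real-time
loop with a sliding window and exponential-moving-average smoothing — plus
the statistics used to judge them (binomial chance bounds and the temporal
sensitivity of decoding to a mid-trial switch in the attended side). A
linear forward-model generator supplies synthetic EEG with known ground
truth so the whole pipeline can be exercised and validated without
recordings.

## Model

With preprocessed EEG $R(t,n)$ (channel $n$, analysis rate $f_s$ = 64 Hz)
and attended envelope $S(t)$, the reconstruction is

$$\hat S(t) = \sum_n \sum_\tau D(\tau, n)\, R(t+\tau, n),$$

where the lags $\tau$ span 0–250 ms (17 taps at 64 Hz): the EEG response
*follows* the stimulus, so reconstructing $S(t)$ uses EEG at and after $t$.
The weights solve the ridge normal equations on the lag-expanded design
matrix $R$,

$$D = (R R^{\mathsf T} + \lambda I)^{-1} R S^{\mathsf T},$$

with $\lambda = 10$ added to the raw diagonal of the covariance of z-scored
data — no eigenvalue or trace normalization, so the printed $\lambda$ is
exactly what enters the solve. Samples shifted past the trial end are
zero-filled, keeping the design the full trial length.

*Offline evaluation* is leave-one-out over the location-fixed trials: each
held-out trial is reconstructed with the element-wise average of the
decoders fitted on all remaining trials (averaging weights, not
predictions), correlated with both talkers' envelopes (Pearson, full trial
length including the zero-filled edge), and classified correct iff
$r_\text{attended} > r_\text{unattended}$ strictly. Ties and NaN
correlations (degenerate reconstructions) classify as incorrect. Accuracy
is the percentage of correctly classified trials.

*Real-time evaluation* replays the acquisition loop: EEG accumulates for
$W$ = 15 s, then analysis repeats every $M$ = 1 s, so window $i$ ends at
$W + (i-1)M$ seconds and a 60-s trial yields 46 windows. Each training
window is preprocessed on its own buffer and fitted exactly like the
offline model; the real-time decoder $\bar D$ is the equal-weight mean of
all snippet decoders over all training trials (14 trials × 46 windows = 644
at the default design). At test time each window's per-speaker correlations
$r_i$ are smoothed independently with an exponential moving average,

$$\hat r_i = \alpha r_i + (1-\alpha)\hat r_{i-1}, \qquad \hat r_1 = r_1,$$

with $\alpha = 0.1$, resetting at every trial boundary; the decision is the
speaker with the larger smoothed correlation. Raw (unsmoothed) correlations
are carried alongside because the switch-sensitivity analysis uses them.

## Preprocessing

EEG: common-average re-reference → zero-phase band-pass 0.5–8 Hz
(forward–backward Butterworth, order 3 per pass) → polyphase resampling
125 → 64 Hz (exact rational factor 64/125) → per-channel z-score
(population SD). Envelopes: magnitude of the analytic signal (Hilbert
transform) → same band-pass → resample to 64 Hz → z-score. In the
streaming loop the identical chain runs on the 15-s buffer only — causally
realizable — and envelope segments are cut from the stored preprocessed
envelopes and re-z-scored per snippet.

Numerical choices worth knowing:

- The filter family/order is a package choice (nothing canonical exists for
  this design); zero-phase filtering within the buffer is consistent with
  re-filtering the whole buffer every second.
- Zero-phase filtering on a 15-s buffer has edge transients; no padding or
  tapering is applied, and tests measure filter properties away from edges.
- Re-running the full chain on already-processed data is *not* an identity:
  in-band Butterworth attenuation near the 8 Hz edge changes mid-band
  content by a few percent per extra pass. The chain is applied exactly
  once per signal.
- A channel left with essentially no variance after common-average
  referencing (duplicated/flat electrodes) raises a degenerate-signal error
  rather than silently z-scoring float residue.

## Statistics

*Chance level.* The binomial bound is $100\,k^*/n$ where $k^*$ is the
smallest integer with $P(X \le k^*) \ge 0.95$ under $\mathrm{Bin}(n, p_0)$;
accuracies strictly above it are significant at 5%. This inverse-CDF
convention yields 65.38% for $n=26$, $p_0=0.5$ (two-talker trials) and 35%
for $n=60$, $p_0=0.25$ (four-alternative behavioral questions). Note the
bound is not strictly monotone in $n$ (the ratio $k^*/n$ jitters by ±1
count); it tightens reliably only over coarse increases in $n$.

*Temporal sensitivity.* After the attended side switches mid-trial, the
raw-correlation correctness sequence (1-s windows whose end time exceeds
the switch) is scanned for the first run of ≥ 5 consecutive correct
windows — "more than 5 s" is read inclusively at the 1-s resolution, which
is the only reading consistent with a 1-s minimum response. The response
time is the count of windows from the first post-switch window to the start
of that run (so immediate recovery = 1 s); with no qualifying run it is
capped at the full post-switch duration (30 s for a mid-trial switch in a
60-s trial). Correctness is judged against the attended *speaker identity*,
which is unchanged by the side switch.

## Synthetic data generator

Each channel of synthetic EEG is a linear mixture

$$\text{EEG}_n = g_\text{att}\,(k_n * S_\text{att})
             + g_\text{unatt}\,(k'_n * S_\text{unatt}) + \sigma\,\eta_n,$$

with per-channel temporal response functions $k_n, k'_n$ (damped random
oscillations over the 0–250 ms lag span, unit peak), speech-like envelopes
(band-limited rectified noise, z-scored), and $1/f$-shaped noise. Each
convolved drive is normalized to unit per-channel variance before gains, so
`noise_sd` reads directly as a noise-to-attended-signal amplitude ratio.
Signals are synthesized at 64 Hz and up-sampled to 125 Hz so generated
trials exercise the full preprocessing path.

Defaults replicate the experimental design: 30 one-minute 15-channel
trials, 26 location-fixed + 4 location-switching (switching trials placed
after the 14-trial training block), sides balanced 15/15, attended speaker
fixed to talker 1, switch times drawn on a 1-s grid between 45% and 55% of
the trial (27–33 s at 60 s; the grid keeps response times on the 1-s
analysis resolution). Model defaults: `gain_attended` 1.0,
`gain_unattended` 0.25 (a clearly separable 4:1 attended advantage),
`noise_sd` 1.0 (noise as strong as the attended signal per channel),
`lapse_s` 8.0 (after a side switch the effective gains swap for 8 s,
modeling transient disengagement before the listener re-acquires the
talker).

**What the generator does and does not emulate.** It embodies exactly the
linear, stationary neural-tracking assumption the decoder inverts. Real EEG
adds model mismatch the generator omits: non-stationary gains, attention
fluctuation within fixed trials, artifacts (blinks, EMG), volume
conduction, and electrode noise correlated across channels. Consequently
the synthetic task is *easy* for the decoder: correlation estimates over
960–3840 samples average stationary noise away, and with the 4:1 gain
margin both offline and smoothed real-time accuracy sit at 100% across
noise amplitudes well beyond the default (the monotone noise property in
the test suite is therefore satisfied at ceiling). Likewise the 8-s lapse
is diluted inside 15-s windows, so the measured switch response is
typically 1 s. Passing tests demonstrate the pipeline's correctness —
arithmetic, solver, bookkeeping, statistics — not field performance;
published nine-subject reference values (offline 90.60 ± 3.34%, real-time
78.37 ± 2.03%, sensitivity 7.97 ± 1.56 s) appear in reports as context
only and are not reproducible from synthetic data.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `passband_hz` | (0.5, 8) | Hz | analysis band for EEG and envelopes |
| `fs_acq` / `fs_proc` | 125 / 64 | Hz | acquisition / analysis rates |
| `lambda_reg` | 10 | – | ridge penalty, un-normalized |
| `lag_range_ms` | (0, 250) | ms | decoder lag span (17 taps at 64 Hz) |
| `window_s` / `step_s` | 15 / 1 | s | sliding-window width / update interval |
| `buffer_s` | 15 | s | initial accumulation before first decision |
| `ema_alpha` | 0.1 | – | EMA weight on the newest correlation |
| `gain_attended` / `gain_unattended` | 1.0 / 0.25 | – | forward-model stream gains |
| `noise_sd` | 1.0 | – | noise-to-attended-signal amplitude ratio |
| `lapse_s` | 8 | s | post-switch attention-lapse length |

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full 30-trial design for
the headline numbers (one noise-free and one default-noise session each),
the 5-level × 5-seed noise grid at full 26-trial offline scale, and
reduced 20–30-s trials for unit-level checks of the streaming machinery.

## Known limitations

- EDF output is a minimal single-record 16-bit writer (round-trip verified
  against the mne reader to within one quantization step); it is not an
  EDF+ annotator.
- The temporal-sensitivity cap equals the post-switch duration, so trials
  of non-60-s length cap at their own remainder, not at 30 s.
- No artifact handling (rejection, ICA, interpolation) — the acquisition
  chain being modeled has none.
- Per-trial envelope z-scoring is used offline (matching the per-snippet
  behavior); global standardization across a session is not offered.
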