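# Methods

This note records the models, conventions and numerical choices behind
`mibci`, and what the synthetic-data tests do and do not establish about real
recordings.

## Conventions

All event times are seconds from recording start; intervals are half-open
`[start, end)`; the sample holding time `t` is `floor(t · rate)`; amplitudes
are microvolts. A trial's phases are fixation (4 s), visual guidance (1 s),
motor imagery (5 s) and inter-trial interval (3 s), so the MI window on the
trial axis is `[5, 10)` s of a 13-s trial. These defaults live in
`PhaseTiming` and are configurable.

## Montage

The 27 sensorimotor electrodes form a 3 × 9 grid (frontocentral, central,
centroparietal rows). Neighbourhoods are the four orthogonal grid neighbours
(for Cz: FCz anterior, C1 left, C2 right, CPz posterior); edge electrodes
keep the two or three neighbours that exist and are flagged as *partial* in
Laplacian output, since no standard treatment exists for them. The three
bipolar cathodes sit 25 mm anterior of their anodes Cz, C4 and C3; they are
not 10/20 positions, so they are synthesized as primed labels (Cz′, C4′,
C3′) and their 2-D coordinates are schematic (one grid step = one unit).

## Band power

The BP estimator is: causal Butterworth band-pass, squaring, trailing moving
average over 1 s evaluated at every sample (the prefix shorter than the
window averages over the samples seen so far), then the natural logarithm.
Choices worth stating:

* **Filter order.** "Order 4" is read as the design order of the low-pass
  prototype (scipy's `butter(N=4, btype="bandpass")`, an 8-pole bandpass).
  A literal 4-pole bandpass attenuates 50 Hz by only ~23 dB from the 8–13 Hz
  band, which would let line-frequency artifacts contaminate the mu feature;
  the chosen filter reaches ~83 dB.
* **Log base.** Natural. Any base differs by a positive scale and LDA is
  affine-invariant, but fixing it keeps expected values exact in tests.
* **Floor.** The averaged power is floored at 1e-12 µV² before the log so
  silent inputs yield a finite value.
* **Streaming.** Filter state (`sosfilt` zi) and the window tail carry across
  blocks. Each output sample sums exactly the same window contents whatever
  the chunking, so block-streamed and whole-record processing agree bitwise.
* **Latency.** The trailing window delays information by up to 1 s: a signal
  change at time `t` is fully reflected in the features only at `t + 1` s.
  Consequently the discriminable region of a trial whose modulation occupies
  `[5, 10]` s extends to about `11` s, and tests on the selected calibration
  time accept `[5, 11]` s.

`zero_phase` (forward–backward) filtering is offered for offline analysis
only; the online path is strictly causal.

## Calibration

Per time point (every 250 ms over `[0, 13]` s, 53 points), the 40 feature
vectors are shuffled with a seeded permutation and split into 10 packets of
4; each packet is classified by a Fisher LDA trained on the other 36. The
fold error is misclassified/4; the reported error is the mean over folds, and
the reported model the element-wise mean of the 10 parameter sets. The fit's
sign convention (positive output = left hand) is enforced before averaging,
so the average is well defined. Near-singular pooled covariances (possible
with 36 vectors in 4-D) get a ridge of `1e-6 · trace(S_w)/4`. Ties in the
minimum-error selection go to the earliest time, favouring a faster-responding
online system. Both the CV-averaged parameters (default) and a refit on all
40 vectors at the selected time are available, since either reading of
"averaged parameters used online" is defensible.

## Online decoding

Frames occur every `rate / update_rate` samples (16 Hz at 256 Hz); the bar
values are read at the last sample of each frame interval. The hand dead
zone is symmetric (±θ) by default because the feedback display is a single
bar; an asymmetric lower bound is available. A rotation command requires the
LDA output strictly beyond the threshold, so `rotate_left` and `rotate_right`
are mutually exclusive by construction while `forward` may combine with
either. An optional dwell parameter (default 0) requires N consecutive
supra-threshold frames before a command is emitted; the default matches a
system whose only smoothing is the 1-s BP window.

## Evaluation

The ROC sweeps every unique output value (prediction: `output > threshold`),
so the curve is exact; ties produce diagonal segments and the trapezoidal
AUC then equals the midrank-corrected Mann–Whitney U statistic, which a test
verifies to 1e-9. The balanced operating point minimizes the Euclidean
distance to `R_TP = 1 − R_FP`, lower FPR on ties. Error-over-time summaries
average the cross-validated error over the trial-axis MI window `[5, 10)` s.

## ERD/ERS mapping

Power is estimated per trial from 1-s segments advanced by `rate/16` samples
(93.75 % overlap), rectangular window (a Hann taper is optional), scaled so
an in-bin tone of amplitude A reads A²/2, restricted to 4–45 Hz at 1 Hz
resolution, then averaged over the condition's trials. The relative change is

    ERD/ERS(f, t) = 100 · (P(f, t) − R(f)) / R(f)  [%],  R(f) = mean over 0–4 s,

so decreases are negative. (The subtraction is deliberately task-minus-rest:
the field reports ERD as negative values, and the convention here follows
that usage consistently.) Band curves are unweighted means over the band's
1-Hz rows, inclusive of both edges.

Pre/post-training comparison applies the Wilcoxon signed-rank test per time
sample within the `[5, 10)` s window, pairing per-trial band-curve values
across days by trial index. Trials are not physiologically paired across
days; the pairing is an interpretation (flagged here) that yields a valid
test under the null of equal distributions. At least 6 pairs are required;
identical inputs short-circuit to p = 1.

## Synthetic sessions

Each channel is the sum of

* 1/f^α Gaussian background (α = 1, spectrum flattened below 1 Hz), RMS 5 µV;
* band-limited stochastic rhythms (white noise filtered into 8–13 Hz and
  25–35 Hz), RMS 12 µV (mu) and 8 µV (beta) at C3/C4/Cz by default — pure
  sinusoids would make the BP estimator trivially easy and unrealistic;
* white sensor noise, SD 1 µV,

band-limited to 5–100 Hz (the acquisition filter) at 256 Hz. During the MI
phase of a matching class, the rhythm amplitude is multiplied by the
subject's factor `g` with linear 0.5-s ramps at the phase edges (avoiding
filter-edge ringing); band power therefore scales by `g²` on the plateau, and
analyses that quantify it skip the first half second of the window.

The default modulation depths are the post-training magnitudes the protocol
is known to produce (mu ERD −55 % at Cz for feet, −42 % at C4 for left hand,
−51 % at C3 for right hand; beta ERS +31 % at Cz for feet), with a
pre-training variant (−29/−23/−22/+21 %). The background/rhythm amplitude
ratio is fixed so that in-band background power is a few percent of rhythm
power; recovered ERD magnitudes are therefore diluted by roughly 2–4
percentage points (e.g. −52 % recovered for an injected −55 %), which the
±6-point recovery tolerance absorbs. Statistical granularity: with 50 trials
per class, a single session's band-curve ERD has a standard deviation of
about 5 percentage points, so recovery is asserted on means across 20 seeded
sessions.

What the generator does **not** emulate: volume conduction (channels are
independent, so Laplacian SNR gains on real data are not demonstrated),
eye-blink/EMG artifacts, non-stationary background, or learning effects
within a session. Passing tests show the pipeline recovers known injected
effects at realistic SNR and stays at chance under the null — not that any
particular human will reach a given accuracy.

## Problem sizes

Tests and the acceptance script use the protocol's own sizes: 40-trial
two-class calibration sessions, 50 trials per class for ERD recovery, 20
seeds for Monte-Carlo means, 10⁵ random directions for the LDA oracle and
10⁴ samples for the AUC/U-statistic identity. Null-hypothesis bands
(CV error in [0.30, 0.70], AUC in [0.45, 0.55]) are asserted on across-seed
means, matching their binomial-dispersion rationale; single-session
cross-validated errors are overdispersed relative to binomial because folds
share training data, and are bounded loosely.
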