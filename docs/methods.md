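# Methods

## Signal model of the synthetic sessions

A session alternates focusing (F) and mind-wandering (MW) states with
exponential dwell times (defaults: mean 45 s for F, 15 s for MW). The
exponential family is used because only mean dwell times are constrained by
the protocol; memorylessness keeps each state a one-parameter family. Every
MW dwell ends exactly at a mind-wandering button press, followed by a
questionnaire-filling gap (normal, 28 ± 12 s, floored at 5 s) and a refocus
press. The gap is carried as a third interval label `Q` so the state
intervals tile the session exactly; its oculometric parameters are those of
F. An MW dwell that would outlast the session produces no press and is
absorbed into a final F interval: an unreported episode is indistinguishable
from focusing in the event log, and ground-truth MW intervals are defined by
their closing press.

The pupil trace (px², positive outside blinks) is

    pupil(t) = baseline(state) + jitter(interval) + slope(state)·(t − t_state)
               + A·sin(2π f_b t) + ε(t)

with defaults baseline 2000 (F) / 1900 (MW), slope −2 (F) / +2 (MW) px²/s,
per-interval baseline jitter SD 50 px² (slow arousal drift between states —
without it, epoch means would separate the states almost perfectly, which no
real recording does), breathing amplitude 30 px² at f_b = 0.2 Hz (the task
is breath-paced), and white Gaussian measurement noise with SD 20 px². Gaze
is the screen center plus state-dependent jitter (SD 10 px in F, 20 px in
MW: gaze control loosens during MW). Configuration validation requires
baselines to exceed `breathing_amplitude + 3·noise_sd` so the trace stays
positive outside blinks.

Blinks are a state-rate Poisson process (10/min in F, 15/min in MW;
durations 0.05 s + exponential with state mean 0.15/0.25 s), drawn entirely
inside their host state interval (a draw crossing a press is resampled,
never truncated) and at least 0.5 s apart — real blinks essentially never
follow each other faster, and the spacing keeps ground-truth events
one-to-one with detected events under the 100-ms merge rule. During a blink
the pupil is exactly zero; 1–3 samples on each side are perturbed by
±300 px² (the tracker losing the pupil under the closing lid), and isolated
single-sample spikes of the same amplitude occur at 2/min away from blinks.
Everything injected is recorded in a `GroundTruth`.

Questionnaire answers are ordinal 1–7, uniform by default. The reported
episode duration is the true MW dwell rounded to the nearest second, so the
2-s exclusion rule exercises naturally (exponential dwells produce short
episodes). An optional coupling parameter ties Q1 linearly (plus noise) to
the epoch's pupil mean, making correlation targets controllable.

### What the generator does not emulate

Pupillary light/near reflexes, saccade kinematics and the main sequence,
eyelid biomechanics (blinks are hard zero plateaus), slow oscillations of
vigilance beyond the per-interval jitter, and unreported mind wandering
inside the recorded session. Passing tests therefore demonstrate that the
pipeline recovers what this model encodes, not that real recordings will be
as separable; on real data the velocity statistics are also heavier-tailed
than the Gaussian noise used here, which makes the 1.5σ flagging rule
relatively more conservative than it is on these traces (where it flags
≈ 13 % of samples and, after the 16-ms merge, interpolates ≈ 20 % — still
well under the 40 % epoch-rejection bound).

## Cleaning

Velocity is the per-sample first difference of pupil area (px²/sample); the
thresholds μ ± a·σ are scale-free with respect to this choice since μ and σ
share units. Threshold exceedance is strict, and thresholds are computed
once, in step 1, on the temporary blink-free data (the conservative mask:
zero-runs padded −100 ms/+300 ms, merged when closer than 100 ms); a
velocity sample is blink-free only if neither of its endpoints is masked.
"Situated around zero values" is quantified as within 100 ms of a zero-run
(`adjacency_s`, configurable), mirroring the blink-merge scale.

Step 2 refines each blink from its zero-run edges: onset/offset are walked
outward while the absolute velocity exceeds λ·σ_med, with
σ_med = sqrt(median(v²) − median(v)²), a median-based scale estimate robust
to the blink samples themselves, and λ = 6. The walk runs on the raw
(unsmoothed) first difference by default (`smooth_window = 1`): the
boundary perturbation is 1–3 samples wide, and any wider smoothing kernel
smears the edge spikes over its own support, costing exactly that many
samples of onset accuracy. With these defaults the median onset error on
generator-default sessions is 2 samples (≈ 8.3 ms). Blink-related artifact
intervals from step 1 are merged with the refined events for masking and
interpolation, but durations are always measured on the refined events;
events clipped at a record edge are kept for interpolation and excluded
from duration statistics. Interpolation is linear between the nearest valid
bracketing samples (nearest-value fill at record edges) and is applied
identically to pupil and both gaze channels.

A recording with zero velocity variance raises a degenerate-signal error —
the analogue of the manual screening step that would reject a dataset whose
artifacts span the whole recording.

## Epoching and filters

Windows are half-open [start, end) so abutting windows share no sample; the
CT window may touch, but not overlap, the full 10-s MW/F intervals of its
cycle. The 30-s rule applies to the refocus→MW interval within one cycle
(the only reading that prevents MW/F window overlap); "more than 40 %" and
"greater than 4 s" are strict. Filters are a conjunction of per-epoch
predicates, so they are order-independent; the selection report tallies
every rule an epoch violates (an epoch breaking two rules appears in both
tallies but is discarded once). A trailing refocus press with no subsequent
MW press still yields an F epoch — the subject demonstrably resumed the
task. An MW press without a linked questionnaire is a configuration error,
since answering was mandatory in the protocol.

## Features and statistics

Blink membership in an epoch is by onset time, which prevents double
counting across abutting windows; the rate factor is the exact 60/9 (6.67
is display rounding). The 1.5-s duration cutoff applies to all
blink-duration statistics but never to masking/interpolation. SDs use the
n−1 denominator. Epochs without blinks carry NaN for mean blink duration;
the classifier imputes the column mean. Per-epoch pupil slopes (not the
median-time-course slope) feed the condition contrast, because only
per-epoch values admit a rank-sum test.

The rank-sum z uses average ranks, the tie-corrected variance, and a 0.5
continuity correction, signed by the first sample's rank-sum deviation; it
is cross-checked in the tests against exact enumeration at small n and
against an independent asymptotic implementation. Degrees of freedom are
reported as n1 + n2 − 2, the convention of the field's reports. Raw
p-values drive the significance tiers by default; Benjamini–Hochberg is
available by flag. Sliding-window blink trends use ordinary least squares
on window statistics; with 50 %-overlapping windows adjacent statistics
share blinks, so the naive trend p-value is anticonservative — the null
calibration of the trend machinery is therefore demonstrated on
non-overlapping windows, and overlapping-window p-values should be read
descriptively.

## Classification

The SVM follows the reference configuration exactly: RBF kernel
K(u,v) = exp(−‖u−v‖²/2σ²) with σ = 1 (scikit-learn `gamma = 0.5`), box
constraint C = 0.2, features standardized to zero mean/unit SD before
cross-validation (the stated order of operations; `leak_free=True` refits
the scaler per training fold for methodologically clean use). Folds are
stratified to avoid empty-class folds at small n; per-repetition accuracy
is pooled correct/total over held-out folds (`fold_mean=True` gives the
fold-mean alternative). A master seed drives a per-repetition seed sequence
so any single repetition is reproducible in isolation. With σ = 1 in the
9-dimensional standardized space the kernel is quite local and C = 0.2
regularizes strongly, so accuracies saturate well below the Bayes rate —
mean MW-vs-F accuracy on the epoch-level model at 100 epochs/class is
≈ 0.81 with a seed-to-seed SD of ≈ 0.06.

## The epoch-level feature model

`synth.simulate_epoch_features` draws per-epoch feature vectors directly
from a normal model whose state means/SDs mirror the session generator at
the 9-s epoch scale, with the pupil-mean effect set to one pooled SD
(2000 vs 1900, SD 100). Control epochs sit midway between the MW and F
means, except that with probability 0.25 a CT epoch is drawn from the MW
distribution outright: control windows are cut from inside the focus
period, and nothing guarantees the subject was on task throughout them —
unnoticed or unreported mind wandering contaminates them. This
contamination is what makes F-vs-CT easier than MW-vs-CT (CT resembles MW
more than F), reproducing the observed ordering
MW-vs-F > F-vs-CT > MW-vs-CT; with CT exactly midway and uncontaminated the
two cross-pairs would be equally hard and the ordering a coin flip. The
0.25 rate equals the probability that an exponential MW dwell exceeds the
F dwell at the default means (15/(15+45)), i.e. the chance the midpoint
window falls after true MW onset.

## Problem sizes and numerical choices

The acceptance script uses 8 default 20-min sessions for the blink
benchmark, 4 for the end-to-end pipeline, and 6 replicate draws × 100
epochs/class × 50 CV repetitions for the pairwise accuracies — sizes at
which the Monte-Carlo error of each reported mean is several times smaller
than the effects being reported. Unit tests use 5-minute sessions and
reduced repetition counts for the same reason. Ties in merging are resolved
by sorting runs by start index; merging is order-independent (verified by
property test). Seeds are always derived from a single master seed via
`numpy.random.SeedSequence`.

## Known limitations

- No pupil foreshortening correction, saccade/microsaccade parsing, or
  normalization of pupil size; coordinates stay in screen pixels.
- The cleaning procedure interpolates a nontrivial share of Gaussian-noise
  samples by construction of the 1.5σ rule (see above); on real, smoother
  data the flagged fraction is lower.
- CT epochs extracted from simulated sessions come from inside focus
  intervals and are therefore F-like; the contaminated epoch-level model,
  not the session generator, is the vehicle for studying the three-way
  classification geometry.
- Classification is offline and epoch-based; no sliding-window or real-time
  detection is attempted.
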