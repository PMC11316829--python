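# Methods

## The problem

Person identification from single-lead ECG treats each enrolled subject as
one class and classifies individual heartbeats. Beat morphology is the
signal: the relative amplitudes, widths and latencies of the P, Q, R, S
and T deflections. Arrhythmia perturbs morphology to a degree that depends
on the arrhythmia type, so the package's evaluation protocol deliberately
separates a subject's normal and arrhythmic beats across the train/test
boundary to quantify that effect.

## Synthetic data model

Each subject is parameterized by five Gaussian wave components; a
zero-noise beat is

    y(t) = Σ_w a_w · exp(−(t − μ_w)² / (2 σ_w²)),   w ∈ {P, Q, R, S, T},

with t in ms relative to the R apex. Subject parameters are drawn
uniformly from physiologic ranges (P: 0.05–0.2 mV, σ 12–25 ms, −180 to
−120 ms; Q: −0.2 to −0.05 mV, σ 5–10 ms, −35 to −15 ms; R: 0.8–1.6 mV,
σ 7–14 ms, at 0; S: −0.4 to −0.1 mV, σ 5–10 ms, 15–35 ms; T: 0.1–0.4 mV,
σ 35–70 ms, 150–250 ms), which guarantees by construction that R dominates
and latencies are ordered P < Q < R < S < T. Rhythm: RR ~ Normal(μ, σ)
per subject with μ ∈ [600, 1100] ms, σ ∈ [20, 60] ms, clipped to
[400, 2000] ms. Baseline noise is white Gaussian, default sd 0.02 mV.
Records are assembled at 360 Hz (the MIT-BIH rate) by summing beats at
cumulative RR times; per-subject random streams are spawned from a single
seed, so records are bit-reproducible.

Arrhythmia labels map to explicit parameter edits held in one rule table
(`beatid.synth.DEFAULT_RULES`). The magnitudes are this package's design —
chosen to caricature the textbook electrophysiology of each beat type, not
fitted to any dataset:

| label | meaning | default transform |
|---|---|---|
| N | normal | identity |
| V | premature ventricular | delete P, QRS widths ×2.5, S ×(−1.5), preceding RR ×0.8 |
| A | atrial premature | P amplitude ×0.5, preceding RR ×0.7 |
| / | paced | pacing spike (1.2 mV, σ 3 ms, −60 ms), QRS widths ×2.0 |
| J | junctional premature | delete P, preceding RR ×0.8 |
| R | right bundle branch block | R′ bump (0.55 mV at +40 ms), QRS widths ×1.8 |
| F | fusion V+N | P ×0.5, S ×(−1.2), QRS widths ×1.7 |
| j | junctional escape | delete P, preceding RR ×1.3 (late) |
| a | aberrated atrial premature | P ×0.5, QRS widths ×1.4, preceding RR ×0.7 |
| f | fusion paced+normal | small spike (0.6 mV), QRS widths ×1.4 |
| \| | QRS-like artifact | delete P and T, R ×0.8, QRS widths ×0.7 |

Deletion is encoded as amplitude scale 0, which makes every rule
continuously interpolable: `scale_rules(rules, m)` moves all scale factors
linearly toward 1 (and shifts/extras toward 0), giving a severity dial
with identity at m = 0 and the defaults at m = 1. Prematurity acts on the
RR interval preceding the beat, not on the waveform, because segmentation
is R-anchored. The V transform is deliberately more drastic than the A
transform, mirroring the clinical picture that ventricular ectopy
reshapes the whole complex while an atrial premature beat mostly arrives
early with a deformed P wave.

What the generator does **not** emulate: rhythm-level dynamics (sustained
AF, bigeminy patterns), respiratory baseline wander, electrode artifacts,
multi-lead projections, and intra-subject drift over time. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
its conclusions hold under controlled morphology perturbations; they do
not certify clinical-grade accuracy on real populations.

## Segmentation

Windows are 181 samples, interpreted at 360 Hz (≈0.503 s). The R position
within the window follows the interval-proportion rule: with
PQ/QRS/T = 80/120/160 ms, the fraction of the window preceding R is
(PQ + QRS/2)/(PQ + QRS + T) = 140/360 ≈ 0.3889, i.e. r_index =
floor(0.3889 · 181) = 70. This is the only reading of those durations
that places the R-peak ahead of the window center; the alternative
PQ + QRS reading (0.5556) and plain centering (0.5) are selectable.
Windows are half-open, 0-based; beats whose window would cross a record
boundary are discarded and counted (kept + discarded = annotations).
Box statistics per sample position use linear-interpolation quantiles,
whiskers at the furthest observation within 1.5·IQR, outliers beyond.

## Scalogram

Complex Morlet (`cmor1.5-1.0` in PyWavelets), 12 voices per octave over
0.5–60 Hz at fs = 360 Hz (84 scales). The magnitude matrix is min-max
normalized per image (a constant matrix maps to all zeros), resized to
32×32 with bilinear interpolation using pixel-center (align-corners=false)
coordinates, flipped so low scales sit in the bottom rows, and mapped
through a fixed 256-entry rainbow lookup table stored as CSV package
data. Per-image normalization discards absolute amplitude; identity
information survives in the relative time–frequency layout. All of these
rendering choices are recorded in the image's provenance block.

## Network and training

Canonical plan (input 32×32×3): block 1 standard 3×3 conv 3→32 stride 2 +
batch norm + SeLU; blocks 2–5 depthwise 3×3 (strides 1/2/1/1) + BN +
activation + pointwise 1×1 (→64/128/256/512) + BN + activation, SeLU for
block 2 and GeLU for blocks 3–5; global average pool, dense 200 + ELU,
dense n_classes + softmax. Spatial trace 32→16→16→8→8→8→1. Convolutions
use cross-correlation with TF-style SAME zero padding and no bias; batch
norm has eps 1e-5, momentum 0.1, and contributes scale+shift per channel;
dense layers carry biases. SeLU uses λ = 1.0507, α = 1.6733; GeLU is the
tanh approximation x·½(1 + tanh(√(2/π)(x + 0.044715x³))) — a strict-CDF
mode without the leading x is available for comparison; ELU uses α = 1.

Parameter accounting is a closed-form ledger per layer and is asserted
equal to the instantiated network's total for both variants: 292,647
(separable) and 1,680,007 (standard twin) at 39 classes, ratio 5.74 ≈
5.7. The absolute counts depend on reconstruction details of the block
structure (one separable unit per block, standard stem); alternative
reconstructions can shift the absolutes substantially while barely moving
the ratio, so the ratio is the robust complexity statement.

Training: Adam (lr 1e-3, β = 0.9/0.999), batch 64, cross-entropy,
10 epochs, float32. The framework is pure NumPy with hand-derived
backward passes, verified against central-difference gradients in float64
and against direct-summation convolution oracles. Weight init and epoch
shuffling derive from one seed, so training is deterministic; argmax ties
at prediction time resolve to the lowest class index.

## Protocol

`N_vs_A` trains on every normal beat of each eligible subject and tests
on their arrhythmic beats (all types or one symbol); `A_vs_N` reverses
the pools; `N_vs_N` and `A_vs_A` split within one pool per subject at
train fraction 0.7 with a seeded shuffle. Eligibility requires at least
`min_beats` (default 2) in each required pool; within-pool scenarios
require enough beats to leave at least one on each side. Excluded
subjects are reported with reasons, never silently dropped. Metrics are
the five one-vs-rest confusion-matrix ratios per class with
macro-averaging; cells undefined by zero division are reported as NaN and
excluded from macro averages rather than coerced to 0. FAR/FRR curves
sweep the observed scores as thresholds (acceptance at score ≥ t); a
class with no genuine test samples yields an undefined curve. The CDF
curve is the empirical distribution of the probability assigned to the
true identity.

## Study conditions used in the tests

Desk-scale cohorts keep the suite fast while leaving wide margins:

- Normal-beat identification: 10 subjects × 200 N beats (noise 0.02 mV),
  70/30 N_vs_N split, 10 epochs — reaches 100% test accuracy against a
  95% requirement.
- Severity ordering: 10 subjects × 150 beats mixed 60% N / 20% A / 20% V;
  the model trains once on the N pool and is evaluated per type —
  A ≈ 0.99 vs V ≈ 0.28.
- Degradation with severity: the same model evaluated on V beats
  synthesized at rule magnitudes 0.1 / 0.3 / 1.0 — accuracy falls from
  ≈0.96 through ≈0.3 to a noisy floor near chance. Once identification
  has broken down, accuracy fluctuates on that floor, so the monotonicity
  test allows 0.05 slack on the final comparison.

## Known limitations

- The WFDB reader covers single-segment records in formats 16/212 with
  one annotator file — enough for MIT-BIH-style data, not the full format
  family (multi-segment records, other signal formats, calibrated
  baselines from .cal files are unsupported).
- The identity information in the synthetic cohort is stronger than in
  real populations (no intra-subject variability beyond additive noise),
  so absolute accuracies here overstate what real data would give; the
  protocol comparisons (orderings, degradations) are the meaningful
  outputs.
- Verification-mode operating-point tuning (equal error rates) is out of
  scope; FAR/FRR curves are reported, not optimized.
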