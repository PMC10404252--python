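# Methods

This note documents the models and procedures implemented in `valencemap`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot tell you about real recordings.

## Conventions

All times are seconds relative to stimulus onset (onset = 0); time bins
are half-open `[t, t + dt)` everywhere. The stimulus protocol is 4 s of
odor (ON window, `[0, 4)`) followed by 4 s of off-response window
(`[4, 8)`), with 4 s of recorded pre-stimulus baseline. Analysis windows
deliberately differ by use — 2 s of baseline for response classification,
4 s for the baseline-consistency filter, 1 s for delta-RMS — each
following the procedure it belongs to.

## Behavioral statistics

Each locust scores 0/1 per odor (palp opening). Per odor:
`total` = column sum, `norm_score = total / n_locusts`, and
`preference_index = norm_score − median(norm_score over odors)`, so the
median odor has index 0 by construction. Valence classes come from an
exact one-sided binomial test of the odor's total against a null success
probability equal to the median norm_score (the test is framed against
the median response; 0.5 or any other null is available via
`null_probability`), at alpha = 0.1: upper tail below alpha is
appetitive, lower tail unappetitive, otherwise neutral.

Cohort stability is assessed by subsampling: draw n locusts without
replacement, recompute preference indices, square the Pearson correlation
with the full-cohort indices, average over draws. At n = n_locusts every
draw is the full sample and the statistic is identically 1 (returned
exactly, not through floating-point correlation).

POR detection on palp-separation traces (30 fps): a response requires at
least 30 frames (1 s) between odor onset and 4 s after offset that exceed
the 2-s pre-stimulus baseline mean by 6.5 baseline s.d. *and* exceed an
absolute 1.5-unit gate (the tracking noise floor). Frames need not be
contiguous; a `contiguous` flag enables the stricter reading. The gate is
absolute, so the detector is deliberately not invariant to amplitude
rescaling (a property test documents this). A baseline-s.d. floor of 1e-6
units guards flat baselines. Per-locust normalization rescales all of a
locust's test traces by its global min/max into [0, 1]; flat trace sets
map to zero and are flagged.

## Spike-train processing

**Consistency filter.** A PN is kept only if its baseline rate (4 s
before onset) in every trial is at least 15% of its own maximum baseline
rate across all trials. This criterion targets drift and unit loss in
real recordings. On the stationary synthetic population it mostly
measures Poisson count dispersion — at 2 Hz the coefficient of variation
of a 4-s count is ~35% and many PNs fail by chance, with nothing actually
wrong — so the filter is validated on constructed drift fixtures and the
synthetic pipeline deliberately analyses the full population.

**Classification.** Per (PN, odor), per trial, at 50-ms bins: the trial
is ON-positive if any ON-window bin exceeds the trial's 2-s-baseline mean
by 6.5 baseline s.d.; OFF analogously on the OFF window; a trial is
inhibited-positive if no ON bin exceeds mean + 2 s.d. and the mean ON
rate is below the mean baseline rate. A pair is labeled when at least
half its trials are positive (5 of 10 at the recorded trial count), with
precedence ON > OFF > inhibited. Baseline statistics are per-trial by
default; pooled-across-trials statistics are available but measured
strictly leakier on sparse baselines (the pooled s.d. is smaller). Known
limitation: below ~2.5 Hz baseline, a 50-ms bin's mean + 6.5·s.d. falls
under 2 spikes, so any 2-spike bin triggers and the rule carries a ~1–2%
false-positive floor; at the 3–10 Hz baselines typical of PNs that
survive the consistency filter the false-positive rate is ≤1% (verified
by Monte Carlo on no-signal Poisson data).

**Delta-RMS.** For behaving-locust multiunit voltage (15 kHz): 4th-order
zero-phase Butterworth band-pass 300–6000 Hz, clip at ±5 baseline s.d.,
moving RMS with a 20-ms window, downsample ×150, 10-point moving average,
downsample ×5 (output 20 Hz), subtract the mean of the 1-s pre-stimulus
baseline. The chain is positively homogeneous up to the clipping stage,
and an in-band sinusoid of amplitude A plateaus at A/√2 (both are tests).

## Manifold structure

PCA is taken on the PN × PN covariance of the trial-averaged concatenated
bin matrix (e.g. 89 × 1760 for 80 ON bins × 22 odors), after subtracting
each PN's mean across all bins (centered covariance is the default;
uncentered is a flag). Projections onto the top eigenvectors are reported
per odor with the first bin subtracted (common origin) and a three-point
moving average. Eigenvector signs are canonicalized (largest-magnitude
component positive) so results are comparable across runs and against the
SVD oracle in the tests. Zero eigenvalues are kept and ordered last.

Odor clustering is complete linkage on correlation distance
(1 − Pearson r) between per-odor mean response vectors, with optimal leaf
ordering for display; constant vectors are rejected by id. Angular
valence similarity: for each odor, the mean angle (degrees, via
arccos of cosine similarity) to the other appetitive odors and to the
other non-appetitive odors (neutral pooled with unappetitive), reported
as net score = non-appetitive minus appetitive mean angle; positive means
appetitive-like geometry. Self-comparisons are excluded (21 angles per
odor on a 22-odor panel).

## Valence regression

The decoder is a single squashed linear unit,
`prediction = sigmoid(w·n + b)` on mean epoch spike counts per PN, fitted
by full-batch gradient descent on mean squared error from zero
initialization. The scalar "softmax" of the original formulation is the
logistic sigmoid — the only monotone squashing with range (0, 1) for one
unit. Convergence stops when the loss change falls below 1e-10 (default
cap 10 000 iterations); a persistent loss increase over a patience window
is reported as divergence.

The step size defaults to `"auto"` = 4·n / Σ‖x_i‖² (plus the bias input),
which sits safely inside the stability region implied by the loss
curvature bound (~ mean squared row norm / 4). For unit-scale 89-d
features this evaluates to ≈0.05, the conventional fixed step; for raw
spike-count features (tens per PN) a fixed 0.05 step is unstable, which
is why the scaled default exists. Features are not standardized.

Leave-one-odor-out cross-validation trains one model per held-out odor
(all folds share a vectorized descent). R² is reported as the squared
Pearson correlation between held-out predictions and targets (the
headline convention), with 1 − RSS/TSS also computed. Controls: shuffled
targets (one permutation per model; predictions then concentrate near the
mean target), cross-epoch prediction (ON-trained weights applied to OFF
features, and vice versa), pairwise weight-vector correlations within and
across epochs, and PN-subsampling Monte Carlo reporting mean LOOCV MSE
per subset size.

## POR-dynamics lasso

The design concatenates, for the four conditioning odorants, 2 s baseline
+ 4 s ON + 4 s OFF at 10 Hz: X is n_PNs × 400 of trial-averaged binned
spiking; y is the 400-point mean palp separation (traces averaged across
locusts, block-averaged 30 → 10 Hz). Stimulus onset lands at column 20 of
each 100-column segment. The fit minimizes
`(1/2T)‖y − X'w − b‖² + alpha‖w‖₁` with an unpenalized intercept and no
standardization — the scikit-learn scaling convention under which
alpha = 0.01 is meaningful and the weight-sign split (~20 positive / ~10
negative / ~57 zero of 89 on synthetic data) is stable. Every reported
solution is certified by its KKT residual (< 1e-6); the test suite also
checks solutions against an independent proximal-gradient solver and the
monotone shrinkage of ‖w‖₁ along an alpha grid. Per-odor prediction
quality is the Pearson r between predicted and observed segments with a
two-sided t-test on n − 2 degrees of freedom. The baseline segment of y
is included in the loss (the 400-point construction implies it); weight
dissection averages weights across the six paradigm models, groups PNs by
sign, and reports group mean time courses and within-group rate–weight
correlations.

## Hebbian neuron/anti-neuron network

Two decoding units read the full ensemble's 50-ms trial-averaged activity
X over the four conditioning odors. W1 and W2 are exact least-squares
decoders of binary row targets Y1 (1 during hexanol and isoamyl-acetate
ON bins) and Y2 (benzaldehyde and citral ON bins), solved from the normal
equations; a ridge term of 1e-8·trace/n is added only if X X' is
singular, with a warning. Thresholds: theta1 = (1 + eps)·max(X'W1) so DN1
is silent everywhere before learning; theta2 = half the maximum of X'W2
(a per-odor half-max variant is a flag). PNs split into two near-equal
ensembles by comparing mean hexanol vs benzaldehyde ON responses, ties
going to the smaller group. "Responding to" an odor uses the
peak-activity criterion — any trial-averaged ON bin above the baseline
mean + 6.5 baseline s.d. — which is robust for the weak shared responders
that carry cross-learning; the trialwise classification mask is also
available. Conditioning adds `delta · (mean reward-bin activity ⊙ mask)`
to W1, with delta = 0.25 and the mask = ensemble-1 ∩ responders to the
conditioned odor; one collapsed update per session by default, per-trial
sessions available. Readout: `DN_i(t) = max(x(t)·W_i − theta_i, 0)`,
`POR(t) = max(DN1 − DN2, 0)`.

The threshold headroom eps defaults to 0.45, not a hair above the
pre-learning maximum: after learning, the potentiated ensemble's ordinary
baseline firing alone drives DN1 by roughly
`delta · Σ x̄_i · x_baseline,i`, and with any realistic spontaneous rate
that exceeds a ~1% headroom — the model would then predict palp opening
before the stimulus and to non-appetitive odors. The feasible band is
bounded above by the requirement that the conditioned odor's drive still
cross threshold; 0.45 sits near its center. "No POR" to benzaldehyde and
citral after conditioning is assessed as a peak below 5% of the learned
response: least-squares ringing plus Poisson bin noise occasionally
produces single-bin excursions of a percent or two, which could never
satisfy a sustained behavioral detection criterion.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses assume,
at the study's scale: a 26-locust × 22-odor Bernoulli POR matrix with
per-odor innate probabilities (5 appetitive, 9 neutral, 8 unappetitive,
panel mean ≈ 0.4); piecewise-constant-rate Poisson spike trains for 89
PNs × 22 odors × 10 trials; and 30-fps palp traces with ON-paradigm
(peak inside the stimulus) or OFF-paradigm (peak after offset) learned
dynamics over Gaussian noise (s.d. 1 unit, clipped at 0), amplitude 10
units.

PNs are partitioned into four pools — appetitive-ON (38%), appetitive-OFF
(22%), non-appetitive-ON (24%), non-appetitive-OFF (16%). An odor
recruits a prefix of its class pools, nested by drive strength
(appetitive: its POR probability; non-appetitive: 0.5 + 0.35·(1 − p),
compressed so appetitive ensembles stay broadest), with the first 70% of
each pool forming the class core. Recruited PNs add a gain of
`on_gain · (0.5 + strength)` Hz (defaults: on_gain 20 Hz, off_gain
15 Hz) on a 2-Hz baseline: stronger valence recruits more PNs *and*
drives them harder, the trend seen in recordings. A fixed 20% of the
appetitive-ON pool is weakly cross-driven (0.25·on_gain) by every
non-appetitive odor — the shared responders that make cross-learning
possible, and the knob (`cross_activation`) whose zeroing abolishes it.
Each odor also gets two weak idiosyncratic extra responders from its
class's OFF pool; they are deliberately weak so that odor identity, not
single-PN quirks, carries the valence signal. Non-recruited PNs are
inhibited (to 20% of baseline, persisting through the OFF window) with
probability 0.5·(1 − p), so inhibition deepens as valence falls.

What passing tests on these data show: the pipeline's statistics,
decoders and the conditioning model behave as designed when their
assumptions hold, and parameters are recovered from data that contain
them. What they do not show: performance on real recordings. Real PN
populations have heterogeneous and drifting baselines, adaptation,
odor-specific temporal patterning within the ON window, correlated noise
across neurons and trials, and much higher-dimensional response
variability — the synthetic top-3 PCA components capture ~77% of
variance, against ~30% reported for the recordings. The generator's
nested, deterministic recruitment is a deliberate simplification; the
deposited recordings are the only ground for quantitative claims about
the biology.

## Problem sizes

Unit tests run on reduced populations (typically 24 PNs, 7 odors, 5
trials); the acceptance checks and `scripts/acceptance.py` run the full
synthetic scale (89 PNs, 22 odors, 10 trials, 26 locusts), with 100-draw
behavioral resampling, 20 shuffled-control fits, five-seed conditioning
runs, and a 1000-pair no-signal classification control. The whole
acceptance computation completes in well under a minute on one CPU.
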