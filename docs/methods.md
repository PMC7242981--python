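# Methods

This note documents the models, algorithms, and numerical choices behind
`vocspan`. It is written for users who want to know precisely what each
stage computes and what the synthetic cohort does and does not emulate.

## Noise-band vocoding

The vocoder simulates cochlear-implant hearing by discarding spectral fine
structure while preserving temporal envelopes. The signal is analyzed into
contiguous frequency bands, each band's envelope is extracted and smoothed,
and the envelopes modulate band-limited noise carriers that are summed into
the output.

**Filterbank.** Analysis bands are rectangular (brick-wall) filters
implemented as FFT bin masks: bins with `low ≤ f < high` are kept, all
others zeroed. This makes adjacent channels exactly complementary, so the
filterbank tiles its range with no gaps or overlap, and merging adjacent
bands is exactly energy-preserving — the property that lets the 8- and
4-channel conditions be derived from the 16-channel edge list by merging
pairs and quadruples of bands. The canonical 17-edge preset spans
100–10000 Hz with edges approximately equally spaced on the Greenwood
frequency–place map `F = A(10^{a·x} − k)` with the standard human
constants A = 165.4, a = 2.1, k = 0.88 (with these constants the preset
edges deviate from exact equal cochlear spacing by at most 3.7% of one
step; with k = 1 the deviation is 14.8%, so k = 0.88 is retained). The
edge list itself is normative; the Greenwood map is exposed for building
other filterbanks and for verifying spacing.

**Envelope.** Per band: brick-wall band-pass → analytic amplitude via the
Hilbert transform → causal 4th-order Butterworth low-pass at 300 Hz →
clamp small negative ringing to zero. The smoothing filter is applied
forward-only: zero-phase filtering is reserved for recording
preprocessing, where phase distortion across a whole utterance matters;
inside the vocoder a causal envelope is the common convention, at the cost
of ~1 ms envelope delay (tests align for it). Modulation below ~50 Hz is
preserved (correlation ≥ 0.95 with the imposed envelope after alignment);
modulation above ~600 Hz is attenuated to a residual depth ≤ 0.2.

**Carriers and level.** Each channel's carrier is white Gaussian noise,
brick-wall limited to the channel band and normalized to unit RMS, drawn
from a single seeded generator in channel order (low to high), so a given
(signal, spec, seed) triple is bit-reproducible. The summed output is
rescaled to the input RMS; absolute playback level is a calibration matter
outside the file domain. The top band of the 16-channel preset
(7826–10000 Hz) may legitimately carry no energy for low-passed speech
recordings; that is not an error.

**Recording preprocessing** applies a 4th-order Butterworth band-pass
(default 80 Hz – 20 kHz) forward and reverse (zero phase) and normalizes
the peak to 0.9 full scale.

## Recall-list generation

**Digit lists** (lengths 2–9 over digits 1–9) exclude any adjacent pair
with |Δ| ≤ 1: ascending/descending runs *and* immediate repeats both
support chunking, which would contaminate the memory measure. Lists are
rejection-sampled from the uniform distribution over all sequences, so the
distribution over valid sequences is exactly uniform (verified by
chi-square over the 56 valid length-2 pairs). Zero is excluded because a
nine-token digit vocabulary of clearly distinct spoken forms is the
convention; the alphabet is configurable.

**Word lists** (lengths 1–6) draw from a 60-word CVC inventory over a
restricted phoneme set (initials /w d p s ʃ m f v tʃ h/, finals
/w d p s ʃ m f v tʃ z/, vowels /æ ɑ e ɛ i o u/). Constraints:

- within a list, no phoneme repeats in the same word position;
- each word is used 3 or 4 times per block and 10 or 11 times across the
  three blocks;
- across lists of equal length, the list means of neighborhood density and
  log frequency differ by at most 0.5 pooled SD (configurable) — both
  attributes affect serial recall, so they must not be confounded with
  list identity.

The usage bounds fix the design size: 3–4 uses of 60 words per block
requires 180–240 word slots, so the default is 10 lists of each length
1–6 per block (210 slots); across three blocks exactly half the words are
used 10 times and half 11 times. A per-word block-quota matrix with equal
column sums is drawn first; each block's multiset is then partitioned into
phoneme-valid lists by randomized greedy construction (singleton lists are
pre-selected from a lexically tight neighborhood, since a one-word list
mean cannot be averaged toward the center), and lexical balance is reached
by swap repair: exchanging one word instance between two lists preserves
all lengths and usage counts, so the repair only has to respect phoneme
validity. The search combines directed moves (evict the most offending
word from the extreme list of the worst-balanced group) with random
proposals including sideways moves, targets 90% of the tolerance so the
hinge objective keeps a gradient near the finish, and rebuilds from a
fresh partition when stuck (budget 200k proposals, 8 rebuilds). On
failure it raises with the residual imbalance — constraints are never
silently violated.

An independent validator re-implements every rule with no shared code and
names each violation; presentation ordering forbids consecutive
same-length lists and forces an easy opener (≤ 6 digits or ≤ 4 words).

## Scoring

Serial recall is scored positionally: response slot *i* is correct only if
it equals target slot *i*; missing positions are wrong, surplus response
items ignored, and no edit-distance realignment is attempted. Word lists
score the three CVC phonemes separately (partial-word credit). Sentences
use order-free one-to-one key-word matching on case-folded,
punctuation-stripped tokens with no morphological credit — strictness is
the reproducible choice when human scorers' leniency rules are unknown.
Condition accuracy pools counts (Σ correct / Σ slots) across all list
lengths, weighting each slot equally; mean-of-trial-proportions is
available behind a flag.

## Statistics

**PCA composites** decompose the correlation matrix of a
participants × conditions accuracy table (columns standardized, ddof = 1).
Loadings are unit-norm eigenvectors with every component's sign fixed to a
positive mean loading; scores project the standardized data. Components
with eigenvalue > 1 are retained by default; the serial-recall analysis
retains component 2 by explicit override (its eigenvalue is below 1, but
prior evidence identifies it as vocoder sensitivity). Eigenvalues sum to
the number of variables and reconstruct the correlation matrix to 1e−8.

**Correlations** are Pearson or Spearman with the two-sided
t-approximation p. Spearman is the default for accuracy/ability/covariate
relations (bounded, possibly nonlinear scales); cross-resolution sentence
accuracies use Pearson. Bonferroni family sizes are always supplied by the
caller — a family of 6 for the matched-condition serial-vs-sentence grid
(threshold .0083), 8 for components × outcomes (.0063), grid size for the
attention tables — never inferred.

**SMA regression** (slope = sign(r)·sd(y)/sd(x)) is used for fit lines
when both variables carry error; it errors on zero correlation, where the
slope sign is undefined.

**RT analysis.** Incorrect trials are discarded. Trimming removes all
values above mean + 4·SD of the current set and iterates to a fixed point;
only the upper tail is trimmed, per condition (matching the per-condition
fitting). Geometric means summarize conditions; paired condition costs are
tested with the Wilcoxon signed-rank normal approximation: zeros dropped,
average ranks, tie-corrected variance, and a 0.5 continuity correction.
The continuity correction is on by default because without it the
approximation misses the exact permutation p by up to ~0.07 at n = 8,
versus ≤ 0.02 with it; it can be disabled. Note one consequence of tie
correction: if all n paired differences are identical, the variance
shrinks and |Z| exceeds the distinct-ranks ceiling (4.94 at n = 32).

**Ex-Gaussian fits** maximize the exact likelihood of the
Gaussian-plus-exponential convolution (via the exponentially modified
normal density) under L-BFGS-B with σ, τ ≥ 0.5 ms. Initialization is
moment-based: τ₀ = max(∛(m₃/2), 1) from the third central moment (an
ex-Gaussian has m₃ = 2τ³), μ₀ = mean − τ₀, σ₀² = max(var − τ₀², 1).
Non-convergence is flagged, not raised; ≥ 50 observations are required
(the study design uses 80 per condition so the tail parameter is
estimated without bias). Identities E = μ + τ and Var = σ² + τ² hold for
the fitted parameters to within sampling error.

**Condition contrasts** replace a mixed-effects model: with complete
(balanced) data and a participant random intercept, the fixed-effect
condition estimates equal the condition means, so the module reports
means plus paired t contrasts against the 16-channel reference. The
original mixed-model degrees of freedom are not reproduced.

## Synthetic cohort

The generator emulates a 32-participant study so that every downstream
stage runs on data with the believed statistical structure. Five
standard-normal latents per participant: serial ability, sentence skill
(correlated 0.73 with serial ability), vocoder sensitivity, reasoning
(correlated 0.35 with serial ability), and speed (correlated −0.35 with
serial ability and −0.45 with reasoning). The correlation matrix is built
from these primary parameters with implied cross-terms and sampled by
Cholesky factorization (non-positive-definite configurations error).

Every digit slot, phoneme slot, and key word is a Bernoulli draw with
p = logistic(intercept − length penalty·(length − mean length) + skill
slope·latent − vocoding penalty·vocoder sensitivity + block noise). Digit
conditions carry zero vocoding penalty. Block noise (a per-participant,
per-condition state term) keeps conditions from correlating perfectly,
matching the observed cross-condition correlation level. Intercepts are
solved by Gauss–Hermite quadrature plus root finding so expected pooled
accuracies equal the targets exactly (sentences 88.1/77.1/39.1% with SDs
5.6/6.4/7.2% — for sentences the total latent SD is solved jointly with
the intercept to hit the SD target — digits 81% everywhere, words
86/82/65%). The variance shares (block-noise fraction 0.15 of sentence
latent SD; vocoder-sensitivity fractions 0, 0.20, 0.25; word vocoding
slopes 0.10/0.25/0.60; block SD 0.22 on the serial tasks) were chosen
once so the implied between-condition correlation structure reproduces
the published dominant eigenvalues (≈2.4 of 3 for sentences, ≈4.4 of 6
for serial recall) and loading patterns; they are configuration, not
fitted quantities.

Reaction times are ex-Gaussian: RT = N(μ + 60·speed + condition cost, σ)
+ Exp(τ), 80 trials per condition, with per-participant condition costs
N(145, 15) ms for cue switching and N(153, 15) / N(16, 5) ms for Stroop
incongruent/congruent offsets relative to neutral. One percent of trials
are replaced by contaminants uniform on [mean + 5 SD, mean + 10 SD] so
iterative trimming is exercised; a 150 ms physiological floor applies.
Covariates: the reasoning index is 103 + 10.8·reasoning latent (rounded,
clipped to 55–145); the four sustained-attention percentiles are
independent noise, mirroring their null role.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: slot outcomes are conditionally independent
given the latents (real recall errors cluster within trials — order
swaps, whole-word failures), there is no serial-position curve within a
list, no learning or fatigue across blocks, no phonetic confusion
structure in wrong responses, and the congruent-vs-neutral Stroop offset
(16 ms) is reliably detected here whereas the original data showed no
significant difference — medians of paired differences need not be
additive in the way a fixed offset is. Headline group statistics are
reported as medians over replicate cohorts; single 32-participant cohorts
show the expected sampling scatter (e.g. composite correlations ranging
roughly 0.45–0.8).

## Problem sizes and determinism

Default analyses run a 32-participant cohort (ample for interactive use);
calibration checks in the test suite use 4,000–10,000 participants where
a law-of-large-numbers comparison is intended, and replicate studies use
31–100 cohorts, sizes chosen to make the Monte-Carlo error small relative
to the tolerances being checked. All randomness flows from a single seed
through named child streams (cohort, recall, RT, covariates), so every
stage is independently reproducible; analysis outputs are bit-identical
across reruns on the same inputs, and run manifests record seeds, config
snapshots, and input/output checksums.

## Known limitations

- The mixed-effects comparison is deliberately simplified to balanced
  paired contrasts; unbalanced cohorts must be completed or participants
  dropped before analysis.
- Key-word scoring gives no credit to morphological variants; human
  scorers may have been more lenient.
- The word-list balancer is a stochastic search: rare pathological
  inventories can exhaust its budget, which raises an explicit error
  rather than relaxing a constraint.
- WAV I/O is mono only and never resamples; inputs whose Nyquist
  frequency falls below the top filter edge are rejected rather than
  silently degraded.
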