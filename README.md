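# vocspan

Tools for studying how **verbal serial recall predicts recognition of
spectrally degraded speech**. When speech is processed through a noise-band
vocoder — the standard acoustic simulation of cochlear-implant hearing —
sentence recognition falls as the number of spectral channels drops, but
*individuals keep their rank*: the same listeners do well (or poorly) at
every resolution, and their short-term memory for spoken lists is a strong
predictor of that shared ability. `vocspan` implements the full
computational chain needed to run and analyze such a study:

- **`vocspan.vocoder`** — noise-band channel vocoding with rectangular
  (brick-wall) analysis bands spaced on the Greenwood frequency–place map
  (presets: 16/8/4 channels tiling 100–10000 Hz), Hilbert envelope
  extraction with a 300-Hz 4th-order Butterworth smoother, seeded noise
  carriers, and zero-phase recording preprocessing.
- **`vocspan.lists`** — constrained generation of recall stimuli: digit
  lists with no ±1 or repeated adjacent digits, CVC word lists with
  position-wise phoneme distinctness, per-word usage quotas (3–4 per
  block, 10–11 overall), and lexical balancing of neighborhood density
  and word frequency across equal-length lists; plus an independent
  validator and presentation ordering.
- **`vocspan.scoring`** — positional serial-recall scoring, phoneme-level
  scoring with partial-word credit, order-free key-word scoring for
  sentences, and pooled accuracy aggregation.
- **`vocspan.stats`** — correlation-matrix PCA composites with the
  eigenvalue-greater-than-1 rule, Pearson/Spearman correlation cells with
  explicit Bonferroni families, standard major axis regression
  (slope = sign(r)·sd(y)/sd(x)), iterative mean + 4 SD outlier trimming,
  geometric-mean reaction-time costs, tie-corrected Wilcoxon signed-rank
  Z, and maximum-likelihood ex-Gaussian fits (μ, σ, τ).
- **`vocspan.cohort`** — a synthetic 32-participant cohort with correlated
  latent abilities whose defaults encode the study conditions, so the
  entire pipeline runs and is testable without any human data.
- **`vocspan.pipeline` / `vocspan.session`** — the analysis chain over
  trial-level CSV tables, with run manifests for reproducibility, and a
  CLI (`vocspan vocode|make-lists|score|analyze|simulate`).

## The model in brief

Sentence accuracy at resolution *c* for participant *i* is summarized as
the pooled proportion of key words correct; the participants × resolutions
matrix is reduced by PCA of its correlation matrix, and the first
component score is the **composite sentence-recognition ability**. Serial
recall (digits and words at each resolution) is reduced the same way:
component 1 is overall serial recall ability, component 2 vocoder
sensitivity. Reaction-time distributions are modelled as **ex-Gaussian**,
the convolution of N(μ, σ²) with Exp(τ) (mean μ + τ, variance σ² + τ²),
with τ indexing attentional lapses; condition costs (cue switch, Stroop
interference) are differences of per-condition geometric means tested by
Wilcoxon signed-rank.

## Worked example

```python
import numpy as np
from vocspan.cohort import CohortConfig
from vocspan.session import simulate_session, run_pipeline

paths = simulate_session(seed=7, out_dir="session", config=CohortConfig())
bundle = run_pipeline(paths["trials"], paths["covariates"], "analysis",
                      rt_path=paths["rt_trials"])

print(np.round(bundle.sentence_pca.eigenvalues, 3))
print(np.round(bundle.accuracy.mean(), 3).to_dict())
print(bundle.cost_tests.round(2))
```

Output from this exact run:

```
[2.109 0.523 0.368]
{'digit_16': 0.822, 'digit_8': 0.803, 'digit_4': 0.804,
 'word_16': 0.856, 'word_8': 0.816, 'word_4': 0.662,
 'sentence_16': 0.881, 'sentence_8': 0.749, 'sentence_4': 0.366}
                              median_cost_ms  wilcoxon_z     p
contrast
switch_cost                           144.03        4.94  0.00
stroop_incongruent_neutral            160.56        4.94  0.00
stroop_incongruent_congruent          144.34        4.94  0.00
stroop_neutral_congruent              -23.34       -2.69  0.01
```

Reading this: sentence recognition averaged 88/75/37 % at 16/8/4 channels
for this simulated cohort, and a single principal component with
eigenvalue 2.11 (of 3) captures the shared individual ability across
resolutions. Every simulated participant is slower when the categorization
cue switches, with a median cost of 144 ms; the Wilcoxon Z of 4.94 is the
one-sided ceiling for 32 participants with distinct ranks. Values vary
from cohort to cohort exactly as a real 32-participant sample would;
`vocspan.pipeline.replicate_study` quantifies that scatter.

To vocode an actual recording:

```bash
vocspan vocode --channels 4 --seed 1 speech.wav speech_4ch.wav
```

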