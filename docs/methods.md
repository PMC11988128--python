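# Methods

This note records the modelling decisions behind `hanrisk`: the cohort
rules, the synthetic data generator, the architectures, the objective, the
evaluation protocol, and the numerical choices — including the places where
the design was genuinely open and a choice had to be made.

## Cohort rules and observation windows

A patient enters the cohort only if older than 30 years at the index date.
Cases (patients with a diagnosis date) must additionally have at least one
note before diagnosis and have enrolled at least five months before it.
The index date anchors everything: the diagnosis date for cases, the last
GP visit for controls — these are the only two dates the windowing scheme
needs.

* **Cases** contribute visits in `[diagnosis − 29 months, diagnosis − 5
  months]`: two years of history ending five months before diagnosis, so
  the model never sees the immediate pre-referral period.
* **Controls** contribute visits in `[last visit − 25 months, last visit −
  1 month]`: the matching two years ending one month before the last visit.

Months are fixed 30-day intervals. Calendar months would make window
membership depend on which month a diagnosis falls in; a fixed interval is
deterministic and testable. Patients with no in-window visit are dropped.

Each in-window visit becomes one sentence: the marker tokens `S O E P` are
kept as literal text, each followed by its field's tokens; an empty field
contributes its marker only. Structured predictors (age at index date, sex,
and counts of the 11 lung-cancer-associated ICPC codes A04, B80, B82, P17,
R02, R05, R24, R95, T03, T08, L04) are computed over the same window —
13 predictors in the default configuration; the vector length is
configurable because coded-predictor sets vary between extractions.

**Length exclusion.** Documents whose total word count strictly exceeds the
empirical 99.7th percentile (the 3-sigma convention) of the corpus are
excluded. The percentile is recomputed per corpus; an alternative reading —
a fraction of a fixed hardware cap — is supported through the `quantile`
argument but not the default. With heavy-tailed but realistic length
distributions this removes at most ~0.3% of patients.

**Split.** 60/20/20 train/tune/test by patient, stratified on the outcome
by largest-remainder allocation within each label stratum, seeded. Fewer
cases than folds is an error rather than a silent degenerate split.

**Tokenisation** (for ingesting raw text): lowercase, split on whitespace,
strip edge punctuation, keep internal hyphens — the simplest scheme
consistent with unigram embeddings. The synthetic generator emits tokens
directly, so this path only matters for real data.

## Synthetic cohorts

The generator exists because the study-type data (GP notes linked to a
cancer registry) cannot be public. It emulates the features the pipeline is
sensitive to, and nothing more:

| feature | default | what it emulates |
|---|---|---|
| prevalence | 0.004 | rare outcome (~0.4%) |
| age, cases | Normal(68, 11) years | older case population (median ~68) |
| age, controls | Normal(52, 17.8) years | general adult population (median ~52) |
| visits/patient | neg. binomial, mean 8, dispersion 4 | overdispersed visit counts over a 36-month span |
| words/field | Poisson(5) | short SOEP fields |
| background text | Zipf(1.07) over 2000 synthetic Dutch-looking pseudo-words | heavy-tailed token frequencies, which embedding training assumes |
| signal tokens | 5 symptom-like tokens, rate 0.30/sentence in cases in-window, 0.01 elsewhere | case-enriched early symptom mentions |
| ICPC counts | Poisson, mean 0.6/code (cases) vs 0.2 (controls), dated in-window | elevated coded-symptom activity in cases |
| sex | Bernoulli(0.5) both classes | no sex effect is modelled |

Signal tokens are planted preferentially in the S field (70%) else E,
mimicking symptom mentions, and — crucially — only *inside the window that
cohort preparation will select* for cases. This makes the generator a
ground-truth instrument: with rates 1.0/0.0 every prepared case document
contains signal and no control document does, so an architecture that
cannot recover it is broken, not unlucky.

What the generator does **not** emulate: Dutch grammar, note-internal
discourse structure, comorbidity correlations, coding practice variation,
or temporal trends in prevalence. Passing tests on synthetic cohorts
therefore demonstrates that the machinery is correct and can recover known
signal under the stated conditions — not that any particular performance
level will transfer to real notes.

## Embeddings

Skip-gram with negative sampling, implemented in vectorised numpy:
dynamic context windows (radius uniform on 1..window), 5 negatives drawn
from the unigram^0.75 distribution, SGD with a linear learning-rate decay
from 0.025, single-threaded for bit-reproducibility. Defaults dim=100,
window=5, min_count=5, epochs=5 — conventional skip-gram settings, all
exposed because nothing pins them. The skip-gram variant (rather than CBOW)
is the package's choice and is flagged as such.

The vocabulary is built exclusively from training-fold sentences; the
out-of-vocabulary vector is all-zeros, so tune/test-only tokens contribute
nothing to the recurrent input rather than injecting noise. Embeddings are
frozen downstream — the training loop asserts the matrix is unchanged.

## Architectures

All six models are masked forward computations on a small reverse-mode
autodiff core (`hanrisk.autodiff`, float64). Masking is strict: padded
words and sentences carry the recurrent state through unchanged, receive
zero attention weight, and never change any output probability (asserted to
1e-6 in tests; the construction makes it exact up to rounding).

* **HAN** — word-level BiLSTM (forward‖backward concatenation) + attention
  (`u = tanh(W h + b)`, weights `softmax(u · ctx)` over unmasked positions),
  then the same scheme at sentence level. The per-visit probability head is
  a single shared affine+sigmoid on the sentence-level recurrent states —
  the minimal head consistent with computing an individual probability for
  every visit. Default widths 50/50 per direction, attention 100.
* **HAN-Combined** — structured predictors are standardised with
  training-fold mean/std, passed through a ReLU layer (width 16), and
  concatenated to the document vector before the output layer.
* **HN** — both attention layers replaced by masked mean pooling; no
  attention parameters exist in the model (asserted by introspection).
* **LSTM (flat)** — each visit represented by its BiLSTM final states;
  patient vector is the unweighted mean over visits; replication retained.
* **PSGNN** — sliding 3-word phrase windows over the concatenated document,
  phrase vectors through a ReLU hidden layer, mean over phrases, logistic
  output. No hierarchy, attention, or replication.
* **CNN** — two width-3 ReLU convolutions over each visit's words with max
  pooling to a visit vector (replication heads per visit), then max pooling
  over visits. Replication is per visit, matching the scheme used by the
  recurrent models. A visit too short to support two convolutions maps to
  the zero vector.

## Objective and optimisation

The target-replication loss is
`L = (1−λ)·ℓ(p, y) + (λ/T)·Σ ℓ(p_i, y)` with binary cross-entropy ℓ,
masked visits excluded from the mean. λ defaults to 0.5 with a tuning grid
{0, 0.25, 0.5, 0.75, 1}. At λ=0 the loss reduces *exactly* to the final
cross-entropy. Probabilities are clipped by 1e-7 inside ℓ for numerical
safety; the analytic gradient is verified against central finite
differences for every architecture.

Optimisation: Adam (lr 1e-3), batch size 32, gradient clipping at global
norm 5, at most 50 epochs with early stopping (patience 5) on tuning-fold
AUROC; best-epoch parameters are retained. Batches are formed once and
their order shuffled per epoch — embeddings are frozen, so re-embedding per
epoch would buy nothing.

**Output-bias initialisation.** The output and visit heads start at the
training-fold outcome log-odds. With a rare outcome, an optimiser like Adam
otherwise spends its first few hundred steps walking the bias to the base
rate (its step size is ~lr per step regardless of gradient magnitude)
before any discriminative learning begins; starting at the log-odds removes
that plateau entirely. This mattered in practice: on the separable
benchmark cohort the same model moved from chance-level to >0.99 tuning
AUROC within two epochs once the bias started at the base rate.

No class reweighting or resampling is applied: the model trains at natural
prevalence, and the probability scale is kept honest for the Brier score
and calibration analysis.

Hyperparameter search (`tune_grid`) is exhaustive on the tuning fold; ties
break toward smaller λ, then smaller width.

## Evaluation protocol

* **AUROC** via midranks — exactly the Mann–Whitney pair statistic
  (ties count one half).
* **AUPRC** as average precision with step interpolation over descending
  unique thresholds. Trapezoidal PR interpolation is deliberately avoided:
  it over-estimates the area, and the two estimators can legitimately
  disagree on the same predictions.
* **Brier** = mean squared error of the probabilities; tables render ×100.
* **Threshold metrics** at `p ≥ cutoff` (inclusive; default cutoff 0.004,
  the outcome prevalence). A rate with a zero denominator is reported as
  undefined (NaN), never as 0. `1/PPV`, rounded, is the number of high-risk
  patients to test per detected case.
* **Calibration**: LOWESS of the outcome on the predicted probabilities,
  restricted to p ≤ 0.30, fraction 2/3. Robustness iterations are turned
  off (`it=0`): with a rare binary outcome they treat the positive
  outcomes as outliers and shrink the curve toward the majority class —
  observed directly on Bernoulli-calibrated simulations.
* **Uncertainty**: percentile bootstrap, 1000 resamples of
  (label, probability) pairs without stratification; a resample lacking one
  class is redrawn so rank metrics stay defined. Model comparisons resample
  *paired* predictions on identical patients and declare p < 0.05 when 0
  falls outside the central 95% interval of the differences.

Whether the original protocol stratified its resampling is unknowable from
the outside; unstratified-with-redraw is the plain percentile method plus
the minimal fix for degenerate resamples, and is documented as such.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on desk-scale cohorts chosen
as the smallest sizes at which each property is sharply decidable: 10,000
patients for generator marginals (binomial case counts, median ages,
Poisson ICPC means), 2,000 patients for the separable signal-recovery
benchmark (embedding dim 32, hidden 16 per direction, ≤10 epochs), 5,000
points for calibration recovery, and a 3,000-patient rare-outcome
experiment (prevalence 0.02, moderate signal) for the end-to-end
HAN-vs-ablation comparison. The separable benchmark uses prevalence 0.2:
imbalanced enough to exercise the rare-outcome machinery, with enough cases
(~400) that AUROC on the held-out fold is a sharp criterion.

## Known limitations

* Token streams are bag-like within fields; there is no within-field syntax
  for attention to exploit beyond token identity, so attention's advantage
  over mean pooling on synthetic corpora is smaller than on real notes.
* The autodiff core favours clarity over speed; it is adequate for
  desk-scale cohorts (thousands of patients), not for hundreds of
  thousands.
* The "17 predictors" of some descriptions of this predictor set cannot be
  reconciled with the 13 enumerable inputs (age + sex + 11 codes); the
  predictor vector length is configurable and defaults to 13.
* Dropout is implemented (inverted, on the document/pooled vector) but
  defaults to 0; regularisation was not needed at desk scale.
* Checkpoints serialise the parameter dictionary as `.npz` with a JSON
  config sidecar; they are runtime artifacts, not exchange formats.
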