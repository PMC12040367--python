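# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limits of what the tests demonstrate.

## Cohort construction

A patient enters the analysis with an *index date*. For cases the
registry supplies only the diagnosis month, so day 15 is used as the
diagnosis-date estimate and the index date is that mid-date shifted
back by the lead time (default 5 calendar months; 2–6 supported, other
positive leads allowed with a warning). For controls the index date is
one calendar month before the last recorded contact of any kind (note
or coded episode — the data model does not distinguish contact types).
Calendar-month arithmetic clamps the day-of-month (Mar 31 − 1 mo →
Feb 28/29), which keeps the shift order-preserving and unambiguous.

The observation window is the half-open interval
`[index − 24 months, index)`; events dated exactly at the index date
are excluded, so nothing can be counted twice at a boundary. Selection
keeps patients aged ≥40 at index (age from year of birth with a
mid-year convention), with first contact at least 24 months before the
index date, and — by default at window level — at least one non-empty
note inside the window (a record-level variant is available via
`require_text=False` plus caller-side checks). Exclusions are counted
with a fixed precedence (age → history → text; first matching reason
wins) so the selection step table is deterministic and reconciles
exactly: input = retained + Σ excluded.

Tokenisation is deliberately minimal and deterministic: lowercase,
digit runs to `<num>`, punctuation stripped, whitespace split. It is
idempotent, which lets phrase re-merging operate on stored token
streams.

## Phrase detection and SGNS

Adjacent pairs merge into a phrase unit `a_b` when
`(c(ab) − δ)·N/(c(a)·c(b)) > τ` with all counts ≥ `min_count`
(defaults δ=5, τ=10, min_count=5, one pass; more passes grow phrases
one word per pass). Merging is left-greedy and non-overlapping, and the
same left-greedy rule re-merges unseen documents against the frozen
vocabulary.

The embedding is skip-gram with negative sampling over the unit
vocabulary: d=100 dimensions (smaller in the scaled-down experiments
below), window 5 (dynamic: the effective radius at each position is
uniform on 1..w), k=5 negatives from the unigram distribution raised
to 3/4, subsampling threshold t=1e-3 (a unit with corpus frequency f
is discarded with probability 1 − √(t/f), per epoch), 5 epochs,
linearly decaying learning rate from 0.025. Input vectors start
uniform in ±0.5/d, output vectors at zero.

Two implementation details stabilise the batched SGD: the decay
schedule is computed from the actual first-epoch pair count (not an a
priori estimate), and per-batch updates are clipped elementwise at 0.2
— within a batch, many pairs can touch the same very frequent unit's
row, and the summed update otherwise diverges after a few epochs.
Training is single-threaded and bit-reproducible given the seed.

A document embeds as the unweighted mean of its in-vocabulary units'
input vectors (order-free, scale-stable under a linear model);
an inverse-frequency-weighted mean is available behind a flag.
All-out-of-vocabulary documents map to the zero vector with a flag.
Vocabulary, phrases, code selection and scalers are fitted on the
training split only; tuning/test and held-out-centre documents are
processed with the frozen model.

## Risk models

`TO` regresses the outcome on the embedding; `TC` on the embedding plus
age (continuous years), a female indicator, and raw in-window counts of
the selected ICPC codes. Columns are standardised with training-split
means/SDs (frozen thereafter; zero-variance columns get SD 1). Fitting
is damped-Newton IRLS on the (optionally ridge-penalised) Bernoulli
log-likelihood; convergence at relative log-likelihood change < 1e-8 or
100 iterations. Unpenalised fits detect separation (coefficient norm
blow-up or a numerically perfect fit) and raise with the advice to use
ridge. The pipeline default is a mild ridge (λ=1) because ~50–100
embedding columns can separate desk-scale cohorts; the AIC selection
stage, which operates on the low-dimensional coded model, is
unpenalised.

Backward AIC elimination starts from all 15 candidate codes in a
coded-features-only model (age + sex + counts; selection jointly with
the embedding is available behind `aic_with_embedding`), repeatedly
removes the code whose removal most decreases AIC = 2k − 2·lnL, stops
when no removal decreases it, and breaks exact ties by removing the
alphabetically-last code. Selection runs on the training split only,
to keep the test split untouched by any fitted choice. Note the
well-known property that a pure-noise predictor survives AIC with
probability P(χ²₁ > 2) ≈ 0.16; backward elimination prunes most, not
all, noise.

## Evaluation protocol

AUROC is computed by the rank (Mann–Whitney) method with tie-halving;
AUPRC is average precision with tied scores grouped (step
interpolation, which avoids optimistic trapezoids at low prevalence);
Brier is the mean squared probability error. Calibration uses deciles
of predicted probability by default (quantile bins survive heavy class
imbalance; equal-width available). The classification rule is
`score ≥ threshold ⇒ positive`; the PPV-anchored threshold is the
feasible cutoff flagging the most patients (maximal sensitivity at the
constraint), found by scanning all distinct scores, and infeasible
targets are reported as absent rather than forced. Confidence
intervals are 95% percentile bootstrap over patients (B=1000,
unstratified by default; resamples lacking a class are skipped and
counted, >50% skipped is an error); for operating points, the
threshold is re-derived inside each resample so the PPV stays fixed
across iterations. Point estimates are computed on the original set,
not the bootstrap mean.

Internal validation uses an outcome-stratified 60/20/20
train/tune/test split (per-class counts match the fractions to ±1).
The tuning split is reserved for hyperparameter search (an optional
ridge grid scored by tuning AUROC); by default no tuning runs, and the
split is simply held out. External validation retrains the entire
pipeline once per centre with that centre excluded, scores the held-out
centre, stacks the held-out prediction sets, and recomputes metrics on
the stacked set (not an average of per-centre metrics). Stacked
metrics are verified to equal metrics of the concatenated triples.

## The synthetic cohort

The generator emulates the features of multi-centre GP data this
analysis depends on, with one seeded RNG stream so a config + seed is
byte-reproducible:

* **Outcome**: Bernoulli per patient (default prevalence 0.5%;
  experiments below use 2–4% to keep desk-scale case counts workable),
  with per-centre prevalence multipliers (default 0.6–1.4, rescaled to
  preserve the overall rate). Cases carry a diagnosis month near the
  end of their history; history spans 32–60 months so a 24-month
  window plus any 2–6 month lead always fits.
* **Demographics**: age bands 40–59/60–69/70–79/≥80 with separate
  weights for cases (0.204/0.341/0.319/0.136) and controls
  (0.542/0.213/0.148/0.097), and female rates 46.1% vs 52.5% — cases
  are older and slightly more often male, as in routine-care
  lung-cancer cohorts. These demographic differences are real signal;
  the `as_null()` constructor equalises them (and the centre
  prevalence multipliers) to produce a genuinely label-independent
  cohort.
* **Notes**: per month, Poisson(note_rate) notes (default 0.4/month ≈
  5 contacts/year); each note is a bag of Poisson(8) background tokens
  from a Zipf-like 800-token vocabulary, plus Poisson(signal rate)
  symptom tokens from a 6-token signal set, plus centre style tokens.
  The signal rate is 0.5/note at background and is multiplied by
  `signal_gain` (step profile, default ×3) during the 12 months before
  diagnosis. The note-volume and signal-rate defaults were chosen so
  that a strong-signal cohort (gain 10) has an information ceiling —
  the AUROC of the in-window signal-token count itself — near 0.93,
  matching the order of discriminability this kind of analysis is
  meant to detect; with the volume of a low-attending population the
  ceiling drops below 0.85 regardless of method, because a sizeable
  fraction of cases then has no note at all inside their elevated
  months.
* **Centre drift** (all gated on `centre_shift > 0`): Dirichlet-
  perturbed background unigrams, per-centre disjoint style tokens, a
  share of symptom mentions written as centre-local variant tokens
  (default 30%), and per-centre symptom-documentation intensity
  multipliers (default 0.6–1.4). Jointly these make leave-centre-out
  validation degrade relative to internal validation: a model trained
  on all centres can use in-vocabulary style/dialect tokens to correct
  for site effects, while a model that never saw a centre cannot.
* **ICPC episodes**: per code, Poisson at a base rate per patient-year
  (R05 cough 0.3/yr down to R24 haemoptysis 0.005/yr), multiplied for
  cases during the pre-diagnostic year on the five informative codes
  (×2–3.5).

What the generator does **not** emulate: real clinical language (notes
are bags of abstract tokens — sufficient because the embedding and the
document mean are order-insensitive), comorbidity structure beyond the
listed codes, visit-pattern changes at diagnosis, or de-identification
artifacts. Consequently, passing recovery tests shows the pipeline
correctly extracts a planted lexical signal under realistic prevalence,
volume and drift — not that real Dutch GP notes carry such a signal.
Control note volume can be set separately from cases
(`control_note_rate`) to probe volume confounding; by default the two
are equal, so no volume signal exists.

## Problem sizes used in the recovery experiments

The acceptance-style experiments run at sizes chosen to make each
property sharply decidable: oracle equivalence on 300–1000 random
instances of n ≤ 50; logistic recovery at n = 50 000; AIC recovery at
n = 20 000 × 10 seeds; strong-signal and null pipeline recovery at
n = 20 000, prevalence 2%, embedding d = 50 with 2 epochs (the
document-mean geometry saturates early, so extra epochs change little);
external shrinkage at n = 16 000, prevalence 4%, with the style-token
rate raised to 1.5/note so the internal model's site correction — the
mechanism that makes internal exceed external — is well expressed.
Bootstrap coverage uses 3000 outer replications, which pins the
coverage estimate to ~0.4% Monte-Carlo error.

## Known limitations

* The document representation is a mean of unit vectors, so the
  embedding behaves largely as a fixed linear projection of unit
  frequencies; semantic quality of the vectors matters less than in
  sequence models, and properties of the full pipeline should not be
  read as evidence about embedding quality per se.
* At desk scale, leave-centre-out folds train on 75% of the cohort
  versus the internal split's 60%, which partially offsets drift; the
  shrinkage comparison is therefore run at sizes where training is
  saturated.
* AIC retains each pure-noise predictor with probability ≈ 0.16, so
  "all noise dropped" is not an attainable guarantee of the selection
  stage.
* Percentile-bootstrap CIs are slightly anti-conservative for small
  samples; measured coverage for a Gaussian mean at n = 200 is ≈ 94%.
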