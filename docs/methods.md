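# Methods

## Problem

An emergency-department (ED) visit for dyspnoea must be triaged toward
acute heart failure (AHF), exacerbated COPD (eCOPD), pneumonia, or some
other condition before blood tests or imaging are available.  The package
classifies such an *index visit* from everything recorded about the
patient *before* it: time-stamped coded events (diagnoses, complaints,
medications, procedures, binned laboratory results) from six care
contexts — primary care, outpatient specialist care, ED care, inpatient
care, ambulatory (ambulance) care, and "others" (pharmacy, laboratory,
radiology, smoking status) — together with per-period vital signs and the
onsite triage variables of the index visit itself.

Labels are multilabel by construction.  The four flags are derived from
the visit's main ICD-10 diagnoses by prefix matching on the dot-stripped
code: AHF = {I11.0, I13.0, I13.2, I50}, eCOPD = {J44}, pneumonia =
{J10.0, J11.0, J12–J18}; any code outside these sets raises "other".
More than one flag may be true and no normalisation ever couples the four
predicted probabilities.

## Model

The classifier is a three-layer hierarchical attention network over a
visit laid out as an M × 6 grid: the observation window (default 52
weeks) is cut into M = 10 equal periods, period 0 nearest the index time,
and events are grouped by (period, context), chronologically ordered
within a cell with ties broken by code string so the input is canonical.

Each layer applies the same two blocks:

* an encoder of bidirectional GRUs,
  h_t = [GRU→(x_1..x_t) ‖ GRU←(x_T..x_t)], with the standard gates
  r_t = σ(W_r x_t + U_r h_{t−1}), z_t = σ(W_z x_t + U_z h_{t−1}),
  n_t = tanh(W_n x_t + r_t ⊙ U_n h_{t−1}), h_t = (1−z_t) ⊙ n_t + z_t ⊙ h_{t−1};
* an attention pool, u_t = tanh(W h_t + b), a_t = softmax_t⟨u_t, q⟩ with a
  learned query q, pooled vector s = Σ_t a_t h_t.

Layer 1 turns each cell's event-embedding sequence into a context
embedding (empty cells contribute a learned per-context embedding so the
next layer always sees six inputs).  Layer 2 encodes the six context
embeddings of a period and concatenates the pooled vector with the
period's continuous variables.  Layer 3 encodes the M period
representations and concatenates the pooled vector with the onsite
variables; a two-layer feed-forward head with a softplus output emits
eight non-negative evidences, a pair (e⁺_j, e⁻_j) per label.

Event embeddings (d = 16) are initialised by skip-gram with negative
sampling over per-patient chronological code sequences and fine-tuned end
to end.  The attention form (tanh projection + learned query) follows the
document-classification attention family; it is a design choice of this
package, as is the exact loss below.

## Evidential output and loss

Each label carries a Beta opinion with α_j = e⁺_j + 1, β_j = e⁻_j + 1,
S_j = α_j + β_j.  The reported score is the Beta mean p̂_j = α_j/S_j and
the uncertainty u_j = 2/S_j (1 when no evidence has been collected).  The
per-label loss is the Bayes risk of the squared error under the Beta
opinion plus an annealed KL term that shrinks evidence contradicted by
the label:

    L_j = (y_j − p̂_j)² + p̂_j(1−p̂_j)/(S_j+1)
        + λ_t · KL( Beta(1+(1−y_j)e⁺_j, 1+y_j e⁻_j) ‖ Beta(1,1) ),

with λ_t = min(1, epoch/10).  The identity
E_{p~Beta}[(y−p)²] = (y−p̂)² + p̂(1−p̂)/(S+1) is exercised in the tests by
numerical integration (the α=2, β=1, y=1 case equals 1/6).  The total
loss sums over the four labels and averages over the batch; training is
Adam (lr 3·10⁻³, batch 32, 20 epochs, global-norm gradient clip 5),
deterministic under a fixed seed.

## Numerical and implementation choices

* Missing numerics (D11): value 0 plus an observed-indicator channel, for
  both per-period variables (last observation per period per variable)
  and onsite variables; observed values are standardised with
  training-set means and standard deviations per variable.
* Event sequences are capped at the 32 most recent events per cell when
  packed for the network (the stored bundles keep everything); with the
  default event volume (median ≈ 352 events over 60 cells) the cap binds
  rarely and keeps a training epoch linear in the realistic tail.
* Rare codes (corpus frequency < 5) and unknown codes map to a reserved
  NA token rather than being dropped; a reserved EMPTY token (embedding
  pinned at zero) pads sequences.
* The recurrence and its backpropagation-through-time run in compiled
  (numba) kernels inside a small reverse-mode tape written for this
  package; every fused op (GRU, masked softmax, Beta-KL) is verified
  against central finite differences, and the full forward against an
  independently written straight-line reimplementation.
* Attention softmax over an all-padded group returns an all-zero row; the
  caller substitutes the learned empty-cell embedding, so no NaNs arise
  from degenerate visits.
* Ties: within-cell event order breaks timestamp ties by code string;
  argmax selections in the attention plots break ties to the lowest
  index; ranking ties break by code string.

## Evaluation protocol

Micro AUROC pools all (visit, label) pairs, so each visit carries the
same weight across its four labels; ties count ½ (Mann–Whitney
convention).  The headline protocol is 10-fold cross-validation
stratified by the full label pattern with, per fold, 10 evaluations on a
random 90% subsample of the held-out fold, summarised by the median and
2.5–97.5 percentiles of the 10×10 matrix.  "90% bootstrap" is read as
subsampling without replacement — the only reading that uses exactly 90%
of the evaluation set — with sampling with replacement available behind a
flag.  The reported operating point per label is the maximum sensitivity
among thresholds whose specificity exceeds 75%, found by exhaustive scan
over observed scores.  Degenerate bootstrap samples (a single pooled
class) record NaN with a warning.  Subgroup summaries (age ≤ 75 vs > 75,
sex, history of all three diseases) restrict the same machinery to a
visit mask.

## Interpretability

The importance of one event occurrence is the product of its three
attention weights: event-in-cell × context-in-period × period-in-visit.
Occurrences of the same code are summed within a visit and the per-visit
maps are summed (not averaged) over the cohort; codes are then ranked
descending.  Because every level's weights sum to one, a visit's total
importance mass never exceeds one.  Continuous and onsite variables
bypass the event pathway and are therefore absent from the ranking — a
faithful limitation of the statistic.  Per-visit attention-plot data
(period bars, context bars of the argmax period, top-n event bars of the
argmax context) is exported as JSON.

## Synthetic cohorts

The generator produces the statistical structure the network assumes,
with known ground truth:

* Latent disease indicators drawn independently at prevalences (0.155,
  0.140, 0.133); the "other" label is their completion (≈ 63% here; a
  real cohort's joint label dependence would shift this, and 58.1% is
  plausible under mild negative dependence we do not model).
* Events per visit ~ LogNormal matched to median 352 and IQR 134–838
  over a one-year window; code draws are multinomial over a V = 200
  universe with mildly Zipf-like background rates.
* Signal is planted in code *rates*: each of the four labels owns k = 5
  disjoint signal codes whose rate is multiplied by e^γ (γ = 1.5) when
  the label is active, so sequence-level attention — not only
  bag-of-codes presence — is rewarded; each signal code has a home care
  context (70% of its emissions) so context attention is testable.
* Vital signs (temperature, heart rate, respiratory rate, systolic blood
  pressure, oxygen saturation) are label-dependent Gaussians, observed
  both as timeline events and as onsite triage values, missing completely
  at random at rate 0.02 (mirroring the ~2% missing triage temperature a
  real cohort shows).
* Label noise flips each disease indicator independently (default 0,
  option ≈ 0.05 to emulate un-adjudicated chart labels, consistent with
  reported 1.9–6.6% inaccuracy ranges).
* An optional history-signal mode plants qualifying prior diagnosis
  events (DX:I50 / DX:J44 / DX:J18) with configurable probabilities given
  the label, which is what the nine-feature baseline keys on.

Because the model is fully specified, the exact per-label posterior
log-odds of every visit follow by enumerating the eight latent
configurations (multinomial code likelihood + Gaussian vital likelihood +
Bernoulli history likelihood); their AUROC against the realised labels is
the ceiling no classifier can beat, and the network is measured against
it.  One subtlety: with zero signal the posteriors collapse to the prior
logits, which are constant per label, so each per-label AUROC is exactly
0.5 while the *pooled micro* AUROC still exceeds 0.5 on prevalence
differences alone — chance discrimination is a per-label statement.

What passing tests on this cohort do **not** show: robustness to
care-consumption bias, realistic ICD-10 co-occurrence structure, drifting
coding practice, or informative missingness — none of which the generator
emulates.

## Baseline

The comparison model uses nine expert features — age, sex, history of
heart failure / COPD / pneumonia anywhere within five years, an ED
diagnosis of AHF / eCOPD / pneumonia within one year, and triage
temperature — with missing numerics completed by an iterative
random-forest (MissForest-style) imputer that stops when the total change
in imputed values first increases, and four one-vs-rest gradient-boosted
tree scorers (lightgbm, depth 6, 200 rounds).  The baseline is scored by
the *same* cv_bootstrap code path as the network.

## Problem sizes used by the test-suite and acceptance runs

The default study is n = 2000 visits (≈ 1.8 M events), 20 training
epochs, a 75/25 train/test split, skip-gram pretraining for one epoch;
unit tests use lighter cohorts (n ≈ 100–600 with reduced event volumes)
chosen so each module's property remains the one under test.  At these
sizes the oracle ceiling is ≈ 0.9998 micro AUROC and the trained network
reaches ≈ 0.996 held out, recovering 18/20 planted codes in the top 30
of the cohort ranking.

## Known limitations

* S-curve hyperparameters (attention dimension, FFN width, learning
  rate) were chosen once at desk scale; no search was performed.
* The evidential KL uses the uniform Beta(1,1) reference; alternative
  references (e.g. prevalence-matched) are untested.
* The importance statistic inherits attention's identifiability caveats:
  a code can be predictive yet under-weighted if its signal is absorbed
  by correlated neighbours in the same cell.  Recovery of planted codes
  is noticeably seed-sensitive: cohorts/initialisations whose trained
  attention is less peaked let frequent background codes accumulate
  importance mass by sheer occurrence count, so top-30 membership can
  range widely between seeds even when discrimination is at ceiling.
  Classification quality is therefore a poor proxy for ranking quality.
* cv_bootstrap retrains the supplied estimator per fold; with the full
  network this is the full protocol but costs 10 trainings — the
  CLI `smoke` path demonstrates it at reduced scale.
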