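# carenet

Hierarchical attention diagnosis of emergency-department dyspnoea from
longitudinal EHR event streams.

When a patient presents to an emergency department short of breath, the
question at triage — before any blood test or image — is whether this is
acute heart failure (AHF), exacerbated COPD (eCOPD), pneumonia, or
something else.  Everything the health system already recorded about the
patient is available at that moment: years of time-stamped coded events
(diagnoses, complaints, medications, procedures, binned laboratory
results) from six care contexts, plus the triage variables of the visit
itself.  `carenet` turns that history into four label probabilities with
calibrated-by-construction uncertainty, and explains each prediction by
showing *when*, *where* and *which* events mattered.

The package is aimed at methods researchers in clinical ML and
biostatistics: every stage — cohort simulation with known ground truth,
skip-gram pretraining, the network, the evaluation protocol, the
interpretability statistic, and an expert-feature baseline — is a tested,
seedable library component with an sklearn-style estimator surface.

## The model

A visit is laid out as an M × 6 grid: M equal time periods (default 10
over 52 weeks, period 0 most recent) by six care contexts.  Three stacked
(bidirectional-GRU encoder + attention pool) layers mirror how a
clinician scans a chart:

1. events in a (period, context) cell → context embedding,
2. the six context embeddings of a period, concatenated with the
   period's vitals → period representation,
3. the M period representations, concatenated with the onsite triage
   variables → patient representation.

Each attention pool computes u_t = tanh(W h_t + b),
a_t = softmax⟨u_t, q⟩, s = Σ_t a_t h_t.  A feed-forward head emits, per
label j, a non-negative evidence pair (e⁺_j, e⁻_j) defining a Beta
opinion with α_j = e⁺_j+1, β_j = e⁻_j+1: the reported score is the mean
p̂_j = α_j/(α_j+β_j) and u_j = 2/(α_j+β_j) quantifies ignorance.  Labels
are never normalised against each other, so p̂'s may sum past 1 (a visit
can be both AHF and eCOPD).  The loss per label is the Beta-Bayes risk of
the squared error plus an annealed KL that shrinks evidence the label
contradicts.  Predictions are ranked cohort-wide by the attention
product a_event × a_context × a_period summed per code — a single list
of every code ordered by diagnostic contribution.

Because the intended regional EHR data cannot be shipped, the package
carries a generator that emulates its structure — LogNormal event volumes
(median 352/visit/year), planted label-dependent signal-code rates with
home contexts, label-dependent vitals, missingness, optional label
noise — together with the exact Bayes posterior of every synthetic visit,
so recovery can be measured against a known ceiling.

## Worked example

```python
from carenet import (SimConfig, generate_cohort, bayes_oracle_auc,
                     build_vocabulary, build_bundles, TimelineConfig,
                     CareNetClassifier, SkipGramEmbeddings, build_corpus,
                     micro_auroc, cohort_ranking, visit_event_importance)
from carenet.simulate import VITAL_CODES

cohort = generate_cohort(SimConfig(n_visits=2000, seed=7))
tokens = cohort.events[~cohort.events.code.isin(VITAL_CODES)]
vocab = build_vocabulary(tokens, min_count=5)
bundles = build_bundles(cohort.events, cohort.visits, vocab,
                        TimelineConfig(), numeric_codes=VITAL_CODES)
y = cohort.labels_array()

emb = SkipGramEmbeddings(vector_size=16, epochs=1, random_state=1)
emb.fit(build_corpus(tokens, vocab), len(vocab))
clf = CareNetClassifier(n_epochs=20, random_state=0,
                        init_embeddings=emb.embeddings_)
clf.fit(bundles[:1500], vocab_size=len(vocab))
scores = clf.predict_proba(bundles[1500:])

print("held-out micro AUROC", round(micro_auroc(scores, y[1500:]), 3))
print("Bayes ceiling       ", round(bayes_oracle_auc(cohort)["micro"], 3))

ranking = cohort_ranking(
    [visit_event_importance(s) for s in clf.explain(bundles)], vocab)
planted = {c for cs in cohort.truth.signal_codes.values() for c in cs}
print("planted codes in top-30",
      sum(r.code in planted for r in ranking[:30]), "/", len(planted))
```

On one CPU this trains in a few minutes and prints

```
held-out micro AUROC 0.996
Bayes ceiling        1.0
planted codes in top-30 18 / 20
```

i.e. the network closes to within ~0.004 of the information-theoretic
ceiling of this cohort, and the attention-product ranking surfaces 18 of
the 20 planted signal codes among its first 30 entries — the remaining
mass sits on frequent background codes, which is exactly the failure
mode the statistic is known for.

## Command line

`carenet` exposes the pipeline as subcommands over the documented
TSV/JSON formats, each writing its resolved config next to its outputs:

```
carenet simulate --n 2000 --seed 7 --out runs/cohort
carenet pretrain --data runs/cohort --seed 7 --out runs/emb
carenet train    --data runs/cohort --embeddings runs/emb/embeddings.tsv \
                 --seed 7 --out runs/model
carenet evaluate --data runs/cohort --seed 7 --out runs/eval
carenet rank     --data runs/cohort --model runs/model/checkpoint.npz \
                 --out runs/rank
carenet smoke    --seed 7 --out runs/smoke     # tiny end-to-end pipeline
```

`evaluate` runs the full protocol — 10-fold cross-validation stratified
by label pattern with 10 evaluations per fold on 90% subsamples of the
held-out fold — and reports the median (2.5–97.5 percentile) micro AUROC
plus, per label, the maximum sensitivity at specificity > 75%.

## Layout

- `src/carenet/ehr.py` — records, labels, timeline segmentation,
  vocabulary, TSV dialects, visit bundles
- `src/carenet/simulate.py` — synthetic cohorts + exact Bayes oracle
- `src/carenet/embeddings.py` — skip-gram pretraining
- `src/carenet/network.py` — the hierarchical attention network and
  evidential head (`CareNetClassifier`)
- `src/carenet/_autodiff.py` — the small reverse-mode tape it runs on
- `src/carenet/evaluation.py` — micro AUROC, CV/bootstrap matrix,
  sensitivity at a specificity floor, subgroups
- `src/carenet/interpret.py` — attention-product importance and plots
- `src/carenet/baseline.py` — nine expert features, MissForest-style
  imputation, boosted trees
- `src/carenet/cli.py` — the `carenet` command
- `docs/methods.md` — model, assumptions, design choices, limitations
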