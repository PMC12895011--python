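# histomil

Attention-based multiple-instance learning (ABMIL) for recurrence-risk
prediction from whole-slide-image patch embeddings, with a cross-validated
benchmarking stack, survival evaluation against actual recurrence, and
perturbation-based interpretability — all exercisable end-to-end on
synthetic embedding cohorts.

## Who this is for

Transcriptomic assays such as the PAM50-based ROR-P score stratify
recurrence risk in ER-positive, HER2-negative breast cancer, but they are
not universally available.  H&E slides are.  A common research programme
is therefore: embed each slide's tissue patches with a pretrained encoder,
train a weakly supervised bag-level model to predict the assay score, and
ask (a) how well different encoders support that prediction, (b) whether
the predictions stratify *actual* recurrence, and (c) which tissue regions
the model really uses.  `histomil` implements that programme for anyone
who has per-slide bags of patch features plus a clinical table; it never
touches slide pixels or encoder weights itself.

## The model

A slide is a bag `X = {x_1 .. x_N}`, `x_i` in R^d.  The gated attention
head computes

    h_i   = Dropout(ReLU(W1 x_i))                        d -> L
    a_i   = w^T ( tanh(V h_i) ⊙ sigmoid(U h_i) )          L -> D -> 1
    α     = softmax(a),   z = Σ_i α_i h_i
    out   = W2 z          (2 logits, or 1 continuous score)

with L = 512, D = 384, dropout 0.25 by default.  Classification separates
low/medium from high ROR-P (cutoffs 11.76471 and 52.94118; high is the
positive class); regression predicts the continuous score.  Evaluation
uses participant-stratified 10-fold cross-validation (slides of one
participant never straddle folds), ROC AUC with DeLong comparisons,
Pearson r with Meng's z comparisons, Benjamini–Hochberg correction,
Youden-J threshold selection on pooled validation predictions, and a
survival stack (Harrell's C with a jackknife test for correlated
C-indices, Breslow–Cox with Wald tests, log-rank, cumulative recurrence)
under 10-year administrative censoring.  The perturbation module tests
region necessity (remove the region) and sufficiency (keep only the
region) with paired t-tests and Cohen's d, and greedily searches for a
minimal patch set that flips a low-risk slide to a high-risk prediction.

The MIL head and its training loop are implemented in NumPy with analytic
gradients (verified against finite differences in the test suite), so the
package has no deep-learning framework dependency.

## Worked example

```python
import numpy as np
import histomil as hm

# synthetic cohort: 200 participants, 32-d embeddings, strong planted signal
cfg = hm.GeneratorConfig.strong_signal(n_participants=200, seed=11)
bags, masks, records, truth = hm.generate_cohort(cfg)

head = hm.ABMILConfig(input_dim=32, embed_dim=128, attention_dim=64,
                      task="classification", seed=5)
table, models, folds = hm.crossvalidate(records, bags, head, k=10, seed=5)

test = table[table.split == "test"]
auc = hm.roc_auc(test.prob_high, test.target.astype(int))
print(f"out-of-fold AUC: {auc:.3f}")

score = lambda b: float(np.mean([m.positive_probability(b) for m in models]))
nec = hm.necessity_test(score, bags, masks)
print(nec.summary())
```

prints (abridged):

```
out-of-fold AUC: 0.986
paired perturbation test on n=60 slides
mean delta = -0.8752
t = -60.234, two-sided p =  1.1e-54, Cohen's d = -7.776
```

The AUC of 0.986 says the cross-validated classifier recovers the planted
high-risk signal nearly perfectly at this signal strength.  The necessity
test's mean delta of -0.88 says that removing the (true) tumor-mask
patches from the 60 slides the model called high-risk drops the predicted
high-risk probability by 0.88 on average — the model's positive calls
depend on exactly the region that carries the signal, and the paired
effect size (Cohen's d about -8) makes that dependence unambiguous.

A command-line interface mirrors the library:
`histomil simulate|train|crossval|evaluate|survival|perturb|benchmark|external-eval`
(see `histomil --help`).

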