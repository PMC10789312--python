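# mkbmc — multi-kernel classification of case–control microbiome data

`mkbmc` predicts a binary health outcome (case vs control) from 16S-style
microbiome profiles: an OTU count table, a rooted phylogenetic tree with
branch lengths, and optional numeric covariates such as age.  It is aimed
at researchers analyzing targeted-sequencing cohort data who suspect that
*several forms* of microbiome–outcome association coexist — abundance
versus presence/absence signals, carried by phylogenetically clustered
versus scattered taxa — and who want a classifier that combines those
forms rather than betting on one distance metric.

## The method

Four classic microbiome distances are first **boosted** by per-feature
association strength.  Each branch (tree metrics) or OTU (non-tree
metrics) gets a weight `a_r ∝ −log10 p_r` from a marginal association test
on the training labels (Welch t-test for abundance, χ²/Fisher for
presence), up-weighting outcome-associated features inside the distance:

- weighted UniFrac  `d_w(i,j) = Σ_r b_r a_r |p_ir − p_jr| / Σ_r b_r a_r (p_ir + p_jr)`
- unweighted UniFrac — same ratio on presence indicators `I(p_ir > 0)`
- Bray–Curtis  `d_BC(i,j) = Σ_r a_r |p_ir − p_jr| / 2`
- Hamming  `d_H(i,j) = Σ_r a_r |I(p_ir>0) − I(p_jr>0)|`

Each distance becomes a Gaussian kernel `K = exp(−d²/2σ²)` (σ = mean
pairwise training distance), one more kernel per covariate.  Kernel
weights `w_l` minimize the entropy-regularized alignment objective

    min_w  −Σ_{i,j} Σ_l w_l K_l(i,j) CC(i,j) + ρ Σ_l w_l log w_l,
    s.t. Σ w_l = 1, w_l ≥ 0,

where `CC` is +1 for same-class pairs and −1 otherwise; the solution is
the closed form `w = softmax(S_l / ρ)` with `S_l = Σ K_l·CC`, and ρ is
tuned by 5-fold cross-validated AUC on a grid from 0 to ρ_max.  Each
sample is then scored by a *similarity t-score* — the Welch t-statistic
comparing its combined-kernel similarities to training cases versus
controls — and a univariate logistic model on that score yields case
probabilities.  The learned `w_l` double as a readout of which signal
form (and which covariate) drives the prediction.

A Dirichlet-multinomial simulation engine (negative-binomial sequencing
depths, tree-clustered or scattered signal OTUs, logistic outcome models
on summed abundance or presence counts) makes every stage testable
without any external data.

## Worked example

Simulate a study in which the abundance of one phylogenetically tight OTU
cluster raises disease risk, fit on the training half, and evaluate on
the held-out half:

```
mkbmc simulate --scenario I --model A --beta 2 --n 200 --q 100 --seed 7 \
      --out-prefix demo
mkbmc fit --counts demo.train.counts.tsv --tree demo.tree.nwk \
      --metadata demo.train.metadata.tsv --seed 1 --out model.json
mkbmc predict --model model.json --counts demo.test.counts.tsv --out probs.tsv
mkbmc evaluate --probs probs.tsv --metadata demo.test.metadata.tsv
```

`fit` prints the fitted state:

```
{
  "kernel_weights": {
    "weighted_unifrac": 1.0,
    "unweighted_unifrac": 0.0,
    "bray_curtis": 0.0,
    "hamming": 0.0
  },
  "rho": 0.0,
  "rho_max": 16384.0,
  "beta0": 0.407,
  "beta1": 0.231,
  "training_auc": 0.808
}
```

Cross-validation selected ρ = 0 (winner-take-all), and the weight landed
on the boosted weighted-UniFrac kernel — exactly the metric matching the
planted signal form (an abundance signal on related taxa).  `evaluate`
then reports held-out performance at the 0.5 probability cutoff:

```
{
  "auc": 0.8591,
  "sensitivity": 0.77,
  "specificity": 0.75,
  "cutoff": 0.5,
  "n": 200
}
```

A test AUC of 0.86 against an oracle ceiling of roughly 0.86 at β = 2
means the classifier recovered essentially all of the signal the
generative model put in.  The same workflow is available from Python via
`mkbmc.fit` / `mkbmc.predict_proba`; `mkbmc replicate` repeats a scenario
end-to-end and summarizes AUCs with 2.5/97.5% quantiles.

See `docs/methods.md` for the model's assumptions, parameter defaults,
and what the simulation does and does not emulate.

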