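# hmmdriver

Cancer-weighted profile-HMM scoring of amino acid substitutions:
classifying somatic missense changes as **drivers** (cancer-promoting) or
**passengers/neutral polymorphisms**.

## The problem and the method

Most amino acid substitutions observed in tumour genomes are passengers —
they hitchhike with the clone but do not contribute to carcinogenesis.
Generic pathogenicity predictors conflate "damaging" with
"cancer-promoting": they catch drivers but also flag inherited-disease
mutations and many passengers. This package implements a cancer-specific
variant of hidden-Markov-model substitution scoring.

A substitution at protein position *i* is scored against the profile HMM
whose domain assignment covers *i* with a significant e-value (≤ 0.01)
and, among competing models, has the largest information gain — the
Kullback–Leibler divergence Σ *p* ln(*p*/*q*) of the match-state emission
vector *p* from a SwissProt-like background composition *q*. With
wild-type and mutant emission probabilities *P<sub>w</sub>*, *P<sub>m</sub>*
at the mapped match state, the **magnitude of effect** is

```
score = ln( P_m · (W_p + δ) / ( P_w · (W_c + δ) ) )
```

where *W<sub>c</sub>* and *W<sub>p</sub>* are per-model **pathogenicity
weights** — the relative frequencies of cancer-associated and putatively
neutral catalogue variants mapping onto the model — and δ = 1.0 is a
pseudo-count guarding against zero weights. Conserved positions
(*P<sub>w</sub>* high, *P<sub>m</sub>* low) and cancer-enriched models
(*W<sub>c</sub>* large) push the score negative; scores at or below the
decision threshold **τ = −0.75** are called CANCER.

The evaluation toolkit implements the matching protocol: the six
normalized performance parameters (accuracy, precision, specificity,
sensitivity, NPV, MCC computed from per-class rates, so accuracy is the
mean of sensitivity and specificity), cumulative true/false-positive ROC
curves with block-wise tie handling, grid-search threshold derivation,
leave-one-out and k-fold cross-validation that rebuilds the weight table
without the held-out variants, and Woolf-interval odds ratios for
comparing weighting schemes.

Because the original variant catalogues and domain-model libraries are
large external resources, the package ships a synthetic-data module that
generates complete, self-contained study fixtures (HMMER3 profiles,
domain assignments, labelled catalogues, truth tables) with planted
effect structure; all tests and the acceptance script run on those.

## Worked example

```python
import hmmdriver as h

bundle = h.generate_scenario()          # default planted scenario, seed 7
model = h.DriverMutationModel(bundle.variants, bundle.assignments, bundle.registry)
results = model.fit()                   # estimates the weight table
print(results.summary())
```

```
Cancer-weighted substitution classifier
======================================================
variants in catalogue:     1000
variants mapped to models: 1000
models with weights:       4
total cancer mapped:       500
total neutral mapped:      500
threshold (tau):           -0.75
pseudo-count (delta):      1
weight mode:               relative
e-value cutoff:            0.01

Pathogenicity weights
------------------------------------------------------
model        n_cancer n_neutral      w_c      w_p
SYN000            223        34    0.446    0.068
SYN001             56       223    0.112    0.446
SYN002            174        43    0.348    0.086
SYN003             47       200    0.094    0.400
```

Cancer variants were planted preferentially on SYN000/SYN002, neutral
ones on SYN001/SYN003, and the estimated weights recover that split.
Scoring one planted driver and one planted neutral polymorphism:

```python
df = results.predict([("PROT0014", "I147M"), ("PROT0003", "Q162L")])
```

```
protein_id substitution  score                label model_id  match_state   p_w   p_m   w_c   w_p
  PROT0014        I147M -3.597               CANCER   SYN002          147 0.714 0.024 0.348 0.086
  PROT0003        Q162L -0.122 PASSENGER_OR_NEUTRAL   SYN003          162 0.552 0.382 0.094 0.400
```

I147M hits a conserved isoleucine (emission 0.714 → 0.024) on a
cancer-enriched model and scores −3.60, well below τ = −0.75; Q162L swaps
between two tolerated residues on a neutral-enriched model and scores
−0.12. On the full planted catalogue the fit reaches normalized accuracy
0.93 and MCC 0.87 (`results.training_metrics()`).

The same pipeline is scriptable from a shell:

```
hmmdriver simulate --seed 7 --out bundle/
hmmdriver build-weights --variants bundle/variants.tsv --assignments bundle/assignments.tsv \
    --hmm-dir bundle/ --out weights.tsv
hmmdriver predict --variants bundle/variants.tsv --assignments bundle/assignments.tsv \
    --hmm-dir bundle/ --weights weights.tsv --out predictions.tsv
hmmdriver evaluate --predictions predictions.tsv --labels bundle/variants.tsv --roc roc.tsv
```

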