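# lncsubloc

Cell-line-specific prediction of the subcellular localization — cytoplasm
versus nucleus — of long non-coding RNAs (lncRNAs), from sequence alone.

Where a lncRNA accumulates constrains what it can do: nuclear lncRNAs act
in transcription and chromatin regulation, cytoplasmic ones in
translation control and signaling, and the same transcript can localize
differently in different cell lines.  `lncsubloc` turns this into a
per-cell-line binary classification problem and provides every stage of
the workflow for computational biologists who want to train, audit or
apply such models without any web service.

## Method

**Labels.**  For gene *g* in cell line *c*, the cytoplasmic/nuclear
relative concentration index is the log-ratio of compartment expression,

    CNRCI(g, c) = log2( FPKM_cytoplasm / FPKM_nucleus )

with CNRCI > 0 labeled *cytoplasm* (positive class) and CNRCI < 0
*nucleus*; zero or undefined values (a compartment with zero expression)
are dropped.  Sequences longer than 10,000 nt are removed, redundancy is
reduced at 90% identity by greedy longest-first clustering (identity
estimated as shared 12-mer containment), and each cell line is split
80/20 into training and validation with stratified,
largest-remainder-rounded class allocation.

**Descriptors.**  Each sequence maps to 1,223 named features:

- 123 *composition* descriptors — dinucleotide composition (16),
  reverse-complement dinucleotide classes (10), nucleotide repeat index
  (4), Shannon entropy (1 + 4), distance distribution (4), and type-I
  pseudo di-/trinucleotide composition (19 + 65);
- 1,100 *correlation* descriptors — Moran, Geary, Moreau–Broto and plain
  autocovariance, cross-covariance and auto-cross covariance of 12
  standardized physicochemical property profiles (helical geometry,
  nearest-neighbour thermodynamics, composition) at lags 1–2, plus
  type-I/type-II pseudo compositions (TCC 264, DACC/TACC 288 each,
  TAC/NMBAC/MAC/GAC 24 each, SC/PC pseudo 65/17 each).

**Selection and models.**  Features are ranked by greedy mRMR (ANOVA-F
relevance against the labels, mean |Pearson r| redundancy against the
selected set); 13 classical classifiers (random forest, gradient
boosting, XGBoost, decision tree, MLP, linear/RBF SVM, Gaussian naive
Bayes, QDA, AdaBoost, k-NN, logistic regression, Gaussian process) are
compared by stratified five-fold cross-validation and hold-out
validation using seven metrics: SENS, SPEC, PREC, ACC, MCC, F1 and ROC
AUC.  Feature importance is profiled as the Pearson correlation of each
descriptor with CNRCI, and its range across cell lines flags descriptors
whose role varies between cellular contexts.

A built-in generator simulates the whole setting — class-tilted Markov
sequences (CpG-enriched cytoplasmic, TpG/T-enriched nuclear) with a noisy
CNRCI read-out — so every stage is testable offline.

## Worked example

```python
from lncsubloc import (SyntheticConfig, simulate_dataset, feature_matrix,
                       ClassifierSpec, train_evaluate, stratified_split,
                       assign_labels)
from lncsubloc.dataset import CYTOPLASM
import pandas as pd

seqs, cnrci, truth = simulate_dataset(SyntheticConfig(n_sequences=300, seed=7))
records, dropped = assign_labels(list(zip(cnrci.gene_id, cnrci.cnrci)), "CL1")
labels = {r.gene_id: r.label for r in records}
print(f"{len(records)} labeled genes ({dropped} dropped)")

X = feature_matrix(seqs, "correlation")            # 300 x 1100 DataFrame
y = pd.Series({i: int(labels[i] == CYTOPLASM) for i in X.index})
train_ids, val_ids = stratified_split(labels, test_fraction=0.2, seed=7)
model, metrics = train_evaluate(X.loc[train_ids], y.loc[train_ids],
                                X.loc[val_ids], y.loc[val_ids],
                                ClassifierSpec("xgboost"), seed=7)
print(f"validation: AUC={metrics.auc:.3f} ACC={metrics.acc:.3f} "
      f"MCC={metrics.mcc:.3f} SENS={metrics.sens:.3f} SPEC={metrics.spec:.3f}")
```

which prints

```
300 labeled genes (0 dropped)
validation: AUC=0.999 ACC=0.983 MCC=0.967 SENS=0.964 SPEC=1.000
```

i.e. of the 300 simulated genes all had a usable (finite, non-zero)
CNRCI, and an XGBoost model on the 1,100 correlation descriptors
recovers the planted compositional signal almost perfectly on the 60
held-out genes.  The same flow runs from the shell:

```bash
lncsubloc simulate --n 300 --seed 7 --out-dir sim/
lncsubloc train sim/sequences.fasta sim/cnrci.tsv --out-dir run/ --families correlation
lncsubloc predict sim/sequences.fasta run/CL1/best_model.joblib --out preds.tsv
```

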