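# hsesite

Structure-based prediction of **sumoylation sites** — lysine residues that
reversibly bind SUMO (small ubiquitin-like modifier) proteins — from
**half-sphere exposure (HSE)** features. Sumoylation is implicated in
neurodegenerative disease, immune disorders and cancer, and roughly half of
known sites do not follow the classical ψKxE/D sequence motif, which limits
purely motif-based predictors. This package is for bioinformaticians who
want a transparent, fully testable pipeline that predicts sites from the
*structural* neighbourhood of each lysine instead of amino-acid
co-occurrence patterns.

## Method

**Features.** For every residue *i*, a sphere of radius R = 12 Å around its
Cα is split into two half-spheres by a plane through the Cα, and the Cα
atoms of other residues are counted in each half:

* **HSEβ-up / HSEβ-down** — the plane is normal to the Cα→Cβ vector; the
  half containing Cβ (the side-chain side) is "up".
* **HSEα-up / HSEα-down** — the plane is normal to the pseudo-vector
  u = −[(Cα<sub>i−1</sub> − Cα<sub>i</sub>) + (Cα<sub>i+1</sub> − Cα<sub>i</sub>)],
  which needs no Cβ.

Each annotated lysine K is described by a 31-residue segment
S = {A<sub>−15</sub>, …, A<sub>−1</sub>, K, A<sub>1</sub>, …, A<sub>15</sub>}
(windows crossing a terminus are completed by mirror reflection), giving a
**124-dimensional vector** (31 positions × 4 HSE measures).

**Balancing.** Confirmed negatives vastly outnumber positives (the
reference benchmark has 780 positive and 21,353 negative lysines across 448
proteins), so the majority class is under-sampled with **NearMiss-1**: keep
the N<sub>min</sub> majority samples with the smallest mean Euclidean
distance to their 3 nearest minority samples, yielding a balanced 780/780
set.

**Classifier.** A binary CART decision tree (Gini impurity, exhaustive
"best" splits, minimum node size 2, unlimited depth), implemented from
scratch so the split mechanics are testable. Leaf positive-class fractions
are the prediction scores M.

**Evaluation.** Stratified k-fold cross-validation (k = 6, 8, 10) reporting

    Sens = TP/(TP+FN)   Spec = TN/(TN+FP)   Acc = (TP+TN)/N
    MCC  = (TP·TN − FP·FN) / √((TN+FP)(TP+FN)(TP+FP)(TN+FN))

plus ROC curves (Sens vs FPR over all score thresholds) with trapezoidal
AUC, vertically averaged across folds on a fixed FPR grid with per-point
standard deviations.

## Worked example

Everything is reachable from the `hsesite` CLI (or the `hsesite` Python
package). With no benchmark download, the synthetic generators stand in:

```bash
# a 40-residue ideal helix, then per-residue HSE from its coordinates
hsesite synth helix --n 40 -o helix.pdb
hsesite hse --pdb helix.pdb -o profile.tsv
head -4 profile.tsv
```

```
protein_id  position  residue  hse_a_up  hse_a_down  hse_b_up  hse_b_down
helix       1         K        0.0       7.0         0.0       7.0
helix       2         K        0.0       8.0         0.0       8.0
helix       3         K        0.0       9.0         0.0       9.0
```

Each row counts Cα neighbours within 12 Å on the side-chain ("up") and
backbone ("down") sides of the residue; on this ideal helix the two HSE
variants agree exactly, as they must (their sums both equal the total
neighbour count).

```bash
# imbalanced feature-level dataset with a planted class signal,
# NearMiss balancing, then 6-fold cross-validation
hsesite synth dataset --n-pos 100 --n-neg 1000 --effect 2.0 --seed 7 -o features.csv
hsesite balance --features features.csv -o balanced.csv
hsesite crossval --features balanced.csv --folds 6 --seed 1 -o report.json
```

```
wrote 1100 samples (100 pos / 1000 neg) to features.csv
balanced dataset: 100 positive / 100 negative -> balanced.csv
6-fold CV: mean AUC 0.795 (accuracy 0.795, MCC 0.593) -> report.json
```

The report holds per-fold and summary metrics; here the fold means are
sensitivity 0.761, specificity 0.830, accuracy 0.795, MCC 0.593 — the tree
recovers a 2-SD planted shift on 5 of 124 features well above chance, while
a null dataset (`--effect 0`) stays at AUC ≈ 0.5.

For real structures, `hsesite hse --pdb your.pdb --chain A`, a FASTA of the
sequences and a TSV of annotated lysine positions feed
`hsesite encode`, then `balance`/`train`/`predict`/`crossval` as above.

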