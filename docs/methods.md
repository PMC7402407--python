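# Methods

## The model

The predictor treats sumoylation-site identification as binary
classification of annotated lysines. Its modelling assumptions are:

1. the local structural environment of a lysine — how buried each residue
   in a 31-residue window is, and on which side of the backbone its
   neighbours sit — carries class information;
2. that environment is summarised adequately by the four half-sphere
   exposure counts per residue;
3. a single decision tree over the resulting 124 features is expressive
   enough to capture the class boundary on a balanced dataset.

No sequence-composition features are used at all; the window's amino-acid
identities enter only through validation (the centre must be a lysine).

## Half-sphere exposure

For residue *i* with Cα position **c**ᵢ, the neighbour set is every other
residue *j* with ‖**c**ⱼ − **c**ᵢ‖ ≤ R. The counts split this set by the
sign of ⟨**u**, **c**ⱼ − **c**ᵢ⟩ for an orienting vector **u**:

* HSEβ: **u** = **c**β − **c**α of residue *i*;
* HSEα: **u** = −[(**c**ᵢ₋₁ − **c**ᵢ) + (**c**ᵢ₊₁ − **c**ᵢ)].

Conventions that the mathematical definition leaves open are explicit
configuration on `HseConfig`, with these defaults:

| parameter | default | rationale |
|---|---|---|
| `radius` | 12 Å | the conventional HSE sphere radius |
| `inclusive_radius` | True (≤ R) | a fixed, documented choice; flips only measure-zero boundary cases on real coordinates |
| `tie_rule` | down | neighbours exactly on the dividing plane; any fixed rule works, but it changes counts on symmetric synthetic geometry, so it is configurable |
| `alpha_points_outward` | True | the negated flank sum points away from the backbone, approximating the Cβ direction, so HSEα and HSEβ agree in sign on ideal geometry |

Degenerate inputs: a residue with no flanking Cα (single-residue chain) has
HSEα undefined — counts are stored as (0, 0) with `alpha_defined=False`,
never silently treated as a measurement. Missing Cβ (glycine, incomplete
models) falls back to the HSEα pseudo-vector for HSEβ, recorded in
`beta_fallback`. Perfectly collinear flanks give a zero pseudo-vector; all
neighbours then fall to the tie rule and the residue is flagged
`degenerate`. No sequence-separation exclusion is applied: every residue
other than *i* itself may be a neighbour, including *i* ± 1.

Both variants count the same neighbour set, so `up + down` is identical
across variants wherever both are defined — this conservation is asserted
property-style in the tests and is a cheap integrity check on any profile.

## Window encoding

Out-of-range window positions are reflected about the terminal residue
(p → 2 − p below the start, p → 2L − p past the end, iterated). This is the
simplest reflection satisfying "the segment always has 31 residues"; the
alternative convention of reflecting about the site itself would change
which residues are duplicated but not the dimensionality. A length-1
sequence cannot be padded and is rejected. Feature order is offset-major,
measure-minor — measure m ∈ {αup, αdown, βup, βdown} at offset o lands at
index 4·(o+15) + m — fixed and documented because both the stored models
and the feature-matrix CSV depend on it.

Lysine positions are 1-based indices into the parsed sequence. PDB author
numbering (including insertion codes) is kept alongside and can be emitted
as a mapping table, because curated site annotations are
sequence-positional while structures are not. Per-residue HSE values may
come either from coordinates (`compute_profile`) or from a precomputed
profile TSV, which also admits real-valued, sequence-predicted profiles.

## Balancing

NearMiss-1 with 3 neighbours on raw (unscaled) features: for each majority
sample, the mean Euclidean distance to its 3 nearest minority samples;
retain the N_minority smallest, ties broken by original row index. The
implementation is in-package (exact `scipy` pairwise distances rather than
an approximate neighbour search, so a naive reference computation matches
it bit-for-bit) and is deterministic. Balancing is applied once, globally,
before cross-validation — this matches a balanced-benchmark workflow in
which the 780/780 set is the published object; note that it lets the
balancing step see samples that later land in validation folds, so fold
metrics describe the balanced benchmark, not deployment on raw imbalanced
data. Per-fold balancing can be had by composing
`nearmiss_undersample` with the fold indices, but is not the default.

## Decision tree

CART with Gini impurity, exhaustive best-first splits over all features and
all midpoints between consecutive distinct values, `min_samples_split = 2`,
no depth limit. Determinism: ties in gain resolve to the lowest feature
index, then the smallest threshold, so refits are bit-identical and models
serialise to stable JSON.

One deliberate numerical choice: a zero-gain split on an impure node is
**accepted**, not treated as a stopping condition. Gini gain is
non-negative for every split (concavity), and parity-structured data — XOR
being the canonical case — have *only* zero-gain first splits; stopping
there would freeze training accuracy at 50% on data a two-level tree
separates perfectly. Growth still terminates because every split strictly
partitions the node; leaves arise at pure nodes, nodes below
`min_samples_split`, at `max_depth`, or when all features are constant
within the node. Consequently internal nodes reduce weighted impurity by
≥ 0, not strictly > 0, and on any consistent dataset the fully grown tree
reaches training accuracy 1.0.

## Evaluation

Sensitivity, specificity, accuracy, FPR and MCC are computed from integer
confusion counts; any metric whose denominator is zero is reported as
`None`, never as 0. Reported values are rounded to 3 decimals, half away
from zero. ROC curves sweep every distinct score (plus sentinels), and AUC
is the trapezoidal integral, which equals the Mann–Whitney pair-count
statistic with half-credit for ties — the test suite checks that identity
against an independent pair-counting oracle to 1e−12.

Cross-validation uses seeded, stratified folds by default (sizes differ by
at most one); on a balanced dataset stratification is near-neutral but
stabilises small-fold metrics, and a flag disables it. Because fold-mean
metrics and pooled-confusion metrics can differ slightly, both summaries
are emitted. Fold ROC curves are combined by vertical averaging: each
fold's TPR is interpolated onto a fixed 101-point FPR grid and the mean and
standard deviation are taken per grid point, so threshold-dependent
variability is visible as a band around the mean curve.

`implied_confusion` inverts rounded (sensitivity, specificity) pairs back
to integer counts for a known class balance (nearest integer, half away
from zero). It exists to check published metric tables for internal
consistency: the acceptance tests reconstruct each benchmark row's
confusion matrix from its printed sensitivity/specificity on the 780/780
set and verify the printed accuracy and MCC to 3 decimals.

## Synthetic data

The generators define the conditions under which the pipeline is tested:

* **Helix chains** — Cα on an ideal helix (rise 1.5 Å/residue, radius
  2.3 Å, twist 100°/residue) with Cβ 1.5 Å radially outward; optional
  seeded jitter. Used for geometry sanity checks (conservation, rigid-motion
  invariance, reader/writer round trips).
* **Point clouds** — uniform points with a minimum separation of 3.5 Å
  (rejection sampling); adversarial inputs for the HSE oracle-equivalence
  tests against a naive O(n²) pure-Python reference.
* **Planted-signal datasets** — 124-dimensional vectors of baseline counts
  (10 per measure) plus unit Gaussian noise; positive sites get an
  `effect_size`·SD shift on the HSEα-up coordinates of the central five
  window positions. Feature-level planting isolates
  classifier-and-evaluation correctness from geometry. Class sizes default
  to the benchmark's 780/21,353 in the acceptance computation.

What these fixtures do **not** emulate: real backbone geometry statistics,
correlated noise between neighbouring window positions, the benchmark's
sequence-redundancy structure (the real benchmark was filtered to < 40%
pairwise sequence identity with an external clustering tool before
annotation — a documented preprocessing step outside this package), or any
amino-acid composition signal. Passing the signal-recovery tests therefore
demonstrates that the pipeline recovers a known class difference of a given
magnitude at the stated sample sizes — not that real sumoylation data
carries such a difference.

Problem sizes in the test and acceptance runs — 100 oracle chains of up to
80 residues, signal-recovery at 200+200 samples with 6 folds over 5–10
seeds, one 780/21,353 balancing run — were chosen so the full suite
completes in well under a minute of tree fitting while keeping Monte-Carlo
bands (AUC ∈ [0.4, 0.6] under the null) comfortably wide.

## Known limitations

* Single-chain, single-model PDB handling only; no mmCIF, no fetching.
* The tree has no pruning or ensembling; on noisy data it overfits to its
  training folds by construction (scores are then mostly 0/1, which
  coarsens the ROC).
* NearMiss-1 with raw distances is sensitive to feature scale; HSE counts
  share a scale, so no standardisation is applied.
* Undefined metrics propagate as `None`; downstream aggregation skips them
  rather than imputing.
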