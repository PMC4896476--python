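# Methods

## Problem and model

`skinsense` classifies small molecules as skin sensitizers or
non-sensitizers. The mechanistic rationale is the adverse outcome pathway
for sensitization: the initiating event is covalent modification of skin
proteins by an electrophile, so structural evidence of electrophilic
reactivity, similarity to known sensitizers, and statistical QSAR signal
are complementary lines of evidence. The workflow therefore combines five
signed votes:

* **m₂, m₃, m₄** — binary QSAR classifiers stratified by sensitizer
  potency. Model-2 is trained on Extreme (X), Strong (St) and
  unknown-potency (S) sensitizers versus all non-sensitizers (N); model-3
  on Moderate (M) vs N; model-4 on Weak (W) vs N. A model-1 (X + St versus
  a diversity-selected N subset of equal size) is available for analysis
  but is not part of the shipped workflows, as model-2 covers its classes.
  Each predicts +1 (sensitizer) or −1.
* **s_similarity** — +1/−1/0 from the most similar reference molecules at
  Tanimoto ≥ 0.6 over hashed linear-path fingerprints (paths of 1–7 bonds,
  1024 bits; the widely available equivalent of OpenBabel's FP2). 0 when
  no reference passes the cutoff, or when sensitizers and non-sensitizers
  tie at the maximal coefficient. A coefficient of exactly 1.0 triggers an
  InChIKey comparison — full 27-character equality, not prefix matching,
  so stereoisomers are not conflated — to confirm identity.
* **s_substr** — +1 if any SMARTS alert for a skin-protein reactive group
  matches, else −1 (not 0: the absence of reactive groups is evidence
  *against* sensitization).

The consensus is Score = Σ vote·weight(component, predicted direction)
with the knowledge-based weight schemes KB-a…KB-d; KB-b is the default
(best performing). The sign of the score gives the label; an exact zero is
indeterminate. Because every built-in weight is a multiple of 0.1, sums
are rounded to 10 decimals before the sign test, making the zero
comparison exact. Two workflow bundles are predefined: PW-1 =
{2C2RF, 3C2RF, 4C2RF} and PW-2 = {2C4RF, 3C2RF, 4C2RF} (default).

As an alternative integrator, a meta-classifier (one-hidden-layer
perceptron or linear-kernel SVM) can be trained on the raw five-vote
matrix with 10-fold cross-validation; it always commits to a class. Raw
votes (not weighted contributions) are used as meta-features — the simpler
reading, and the weights are themselves derived from the votes.

## Feature selection

Descriptor set [A] is chosen per model by a Welch two-sample two-tailed
t-test at α = 0.05 (95% confidence); features with zero variance in both
classes are excluded. Subset reduction uses CFS merit

    merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)

with Pearson correlation for continuous features and point-biserial
(Pearson on the 0/1 coding) against the class. Search is best-first over
the subset lattice: an open list ordered by merit (ties broken
lexicographically by sorted feature indices, so results are deterministic
and independent of input order), expanding the best node into all
neighbors reachable by **adding or removing one feature**, and stopping
after 5 consecutive non-improving expansions. The removal moves matter:
with add-only expansion the search can lock onto a greedy path containing
a redundant feature and terminate before backing out of it, which on about
1% of small random instances misses the global optimum. With the
add/remove neighborhood the search matched exhaustive enumeration on
1200/1200 random instances of up to 10 features.

Five descriptor-set recipes feed the model variants: set-1 =
reduce(A ∪ B); set-2 = reduce(A) ∪ B; set-3 = reduce(A) ∪ C; set-4 =
reduce(A) ∪ reduce(B); set-5 = A ∪ B ∪ C. [B] (reactive-group
fingerprints) and [C] (literature mechanism fingerprints) are retained
whole in sets 2/3/5 so that mechanistic bits are never discarded by the
statistics; [C] is never reduced.

## Classifier variants and validation

Variant codes `<model 1–4><split D|S|C><set 1–5><classifier>` span a
4×3×5×5 = 300-variant grid. Split methods: D shuffles and cuts 80/20; S
applies the 80/20 cut per class (guaranteeing proportional representation
within one molecule per class); C is a shuffled 10-fold partition, with
the reported accuracy the mean over folds and the final model refit on the
full pool. Classifier families map to their standard scikit-learn analogs:
J48 → decision tree, MLP → one-hidden-layer perceptron (16 units), RF →
random forest with 100 trees, SL → L2 logistic regression, SMO →
linear-kernel SVM — library defaults otherwise; these are functional
analogs, not bit-exact replicas of any other toolkit, so per-variant
accuracies are not expected to reproduce any external table. Y-randomization
refits a variant on permuted training labels (10 runs by default),
evaluating against untouched test labels; a sound model's real accuracy
exceeds every permuted run by a wide margin.

Diversity selection: "least average similarity" picks the k molecules with
the smallest mean pairwise Tanimoto to the rest of the candidate pool
itself (self excluded; ties broken by id). The reference pool for the
model-1 non-sensitizer pick is the non-sensitizer pool — the natural
reading of avoiding redundancy within the class being subsampled. The
stratified representative pick fills per-class quotas
(X/St/S/M/W = 10 each, N = 50 by default) greedily by max–min diversity.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| t-test α | 0.05 | descriptor selection significance (95% CI) |
| best-first stale cutoff | 5 | non-improving expansions before stop |
| Tanimoto cutoff | 0.6 | minimum coefficient to count as similar |
| fingerprint | 1024 bits, paths 1–7 | path-based hashing resolution |
| RF trees | 100 | the one non-default classifier setting |
| CV folds | 10 | split method C and meta-training |
| Y-randomization runs | 10 | permuted-label refits |
| weight scheme | KB-b | direction-specific component weights |
| workflow | PW-2 | variant bundle {2C4RF, 3C2RF, 4C2RF} |
| seed | 20160607 | default for all stochastic operations |

## Synthetic data

The benchmark generator emulates a curated sensitization dataset at desk
scale: each sensitizer grafts one reactive fragment (enone, aldehyde, acyl
halide, benzylic bromide, epoxide or isocyanate — each keyed to a default
alert) onto one of 26 drug-like scaffold templates with a random inert
decoration; non-sensitizers use the same scaffolds with inert substituents
only and are verified to match no alert. Defaults mirror the curated
parent set's class structure: prevalence 420/571 ≈ 0.74 and potency mix
X:St:S:M:W = 18:32:206:90:74. Structures are unique by InChIKey; grafting
retries are bounded (10 per molecule). The Gaussian descriptor-table
generator plants `n_informative` features at a chosen standardized mean
separation for testing selection and training in isolation.

What the generator does **not** emulate: real chemical-space breadth (26
scaffolds versus thousands of chemotypes), pro-haptens requiring metabolic
activation, potency-correlated descriptor structure, label noise, or
alert-free sensitizers. Because every synthetic sensitizer carries a
literal alert substructure, the end-to-end task is nearly separable — the
held-out CCR ≥ 90% result validates the plumbing (features → variants →
votes → consensus → metrics), not real-world predictive performance.

## Numerical and procedural choices

* Welch (unequal-variance) t-test throughout; p-values from SciPy.
* Correlations computed once per candidate matrix and cached;
  zero-variance columns get correlation 0.
* Tanimoto of two empty fingerprints is defined as 1.0 (both featureless
  at this resolution ⇒ maximally similar).
* The equal-similarity tie rule applies at the maximal coefficient only,
  since scoring is by *highest* similarity.
* Alert matching uses unique-atom-set substructure matches; one pattern
  matching twice still contributes a single +1 vote, with all mechanisms
  and atom indices reported.
* Indeterminate predictions are excluded from all four metric
  denominators and reported separately; display rounding is two decimals,
  half-up. Degenerate tallies (a class with no determinate predictions)
  raise rather than return NaN.
* Molecules that fail SMILES parsing or sanitization are skipped with a
  count, mirroring upstream exclusion of structures that fail conversion;
  no 3D generation or energy minimization is performed (all features here
  are 2D). Salts/mixtures are not desalted beyond default sanitization.
* Dataset invariants: records are deduplicated by InChIKey; two records
  sharing a CAS number but differing in structure are an error.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to keep the
full check fast on a single CPU while preserving the statistical structure
each check needs: a 543-molecule working set for assembly arithmetic, a
400-molecule benchmark (80/20 split) for the end-to-end workflow, 200
molecules for Y-randomization, 100 random instances of ≤ 10 features for
the CFS/exhaustive comparison, and 20 replicates of 1000 null features for
t-test calibration.

## Known limitations

* The shipped alert library is a curated set of domain-standard
  electrophile SMARTS, not a reproduction of any specific published
  pattern collection; a custom YAML/CSV library is a drop-in replacement.
* The built-in descriptor provider is a compact 2D set (20 descriptors);
  the full descriptor engines used in published QSAR work are pluggable
  but not reimplemented.
* Classifier internals follow scikit-learn, so decision boundaries differ
  from Weka-era implementations even at matched settings.
* The consensus can be wrong with high confidence when similarity and
  alerts agree on the wrong side; ablation (`ablate`) quantifies each
  component's contribution.
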