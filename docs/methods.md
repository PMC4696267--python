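# Methods

## Fingerprints and similarity

Molecules are reduced to labeled heavy-atom graphs (RDKit parses the SMILES):
atom labels are element plus heavy-atom degree (`C3` = carbon bonded to three
heavy atoms, hydrogens implicit), bond labels are `- = # :` for
single/double/triple/aromatic. The fingerprint of a molecule is the set of
distinct canonical atom-environment strings of radius 0, 1 and 2 bonds,
present/absent only (no counts). The canonical string of an environment is
produced by iterated label propagation: at each step an atom's string becomes
its previous string followed by the lexicographically sorted list of
`bond-label + neighbor-string` terms. Sorting makes the string a pure
function of the labeled graph — the same molecule entered with any atom order
yields identical bits, and a disconnected molecule's fingerprint is the union
of its fragments'. An atom stops contributing new substructures once its
bond-ball stops growing, so a lone atom contributes exactly one.

Substructure strings map to bit indices through an explicit, persisted
dictionary rather than hashed folding. This is lossless: two distinct
substructures can never collide on one bit, and the dictionary travels with
any serialized model so indices stay meaningful. Tanimoto similarity is
|A∩B|/|A∪B|, with the empty-vs-empty case defined as 0 so a featureless or
unparseable molecule never appears identical to anything.

Bulk similarity uses one sparse matrix product per query batch (counts are
small integers, exact in float32; the division is done in float64).
Exhaustive computation is deliberate — per-target sets are at most a few
thousand molecules, so approximate neighbor indexes would add error for no
useful speedup.

## Activity data

Activities are EC50 values in µM; smaller is more potent. A molecule is
active at cutoff *c* iff EC50 < *c* strictly, so a measurement exactly at the
cutoff is inactive. Three default cutoffs (1, 5, 10 µM) guard conclusions
against cutoff choice; the same thresholds define the four potency classes
(<1, [1,5), [5,10), ≥10 µM) used by the potency-sensitive votes. Repeated
(molecule, target) measurements are collapsed to the arithmetic mean EC50 in
µM (a log-scale mean is arguably more natural for concentrations and is
available as an option, but plain averaging is the default to match the
field's common practice). Targets with fewer than 10 molecules total are
discarded — too sparse to learn from and impossible to tenfold-validate; an
optional minimum-actives filter is also provided since the sparsity that
matters for learning is on the active side. Random-negative molecules carry
no EC50 and receive potency class 3, the only class available to non-binders.

## Neighbor substrate

All scorers consume the same neighbor structure: similarities sorted
descending, ties broken by ascending molecule id (determinism matters for
reproducible ranked lists; the ordering itself is arbitrary). Ranks are
1-based and raw (not normalized by k). Self-neighbors are excluded only in
leave-one-out contexts, flagged by the caller — cross-validation folds never
contain the query.

## The voter

Forward pass, for the k = 6 nearest training neighbors of a query:
relevance `R_i = tanh(w_y + w_s s_i + w_r r_i)`, vote `V_i` indexed by the
neighbor's binary class (standard, 2 weights) or potency class (potency
mode, 4 weights), influence `I_i = R_i V_i`, output
`z = sigmoid(w_z + sum I_i)`. The potency-mode training target remains the
binary label at the chosen cutoff; only the votes change. Because the output
layer is a logistic unit trained on cross-entropy, z estimates the
probability that the query is active, and the influences decompose each
prediction exactly: `sigmoid(w_z + sum I_i)` reconstructs z to machine
precision, which is what the explanation report checks.

Training minimizes the cross-entropy (equivalently, the Kullback–Leibler
divergence between target and predicted label distributions) by full-batch
gradient descent with analytically derived gradients shared across neighbors.
Numerical choices:

- **Initialization**: biases and feature weights uniform(−0.01, 0.01) from a
  seeded generator; votes nudged in the informative direction (+0.1 active /
  −0.1 inactive; potency mode +0.1, +0.05, +0.02, −0.1) to break the
  z ≡ 0.5 symmetry.
- **Step size**: learning rate 0.05 on the *mean* loss (so the step is
  dataset-size invariant), 500 epochs by default, early stop once the
  per-epoch improvement falls below 1e−8. If a step increases the loss, it is
  rejected and the rate halved, so the reported loss trace is non-increasing
  by construction.
- **Clipping**: probabilities are clipped to [1e−12, 1−1e−12] inside the loss
  so it stays finite at saturation; logits are capped at ±700 before
  exponentiation. The gradient uses the standard unclipped form z − t.
- **Regularization**: optional L2 on all weights, default 0.
- Neighbors during training come from the training fold only, with
  self-exclusion, so no molecule votes on itself.
- For the calibration analysis the voters are trained to convergence
  (5000-epoch budget): calibration is a property of the fitted optimum, and
  a half-converged model is systematically over-regularized toward 0.5.

Degenerate inputs: an empty training set or a single-class training fold is a
hard error, not a silent constant model.

## Generic learners

The tree ensemble is a random forest (200 trees, 3 tried attributes per
split) on a bespoke feature vector: the 10 largest Tanimoto similarities to
the training set, sorted descending (ties by id), each multiplied by +1/−1
according to the matched training molecule's activity, zero-padded when the
training set is smaller than 10. Its score is the fraction of tree votes.
The max-margin learner is an SVM on the precomputed Tanimoto kernel
(symmetric, unit diagonal, and PSD on every set we generate — checked by
eigenvalue in the tests); cost ∈ {0.1, 1, 10, 100} and optimizer tolerance ∈
{0.001, 0.01, 0.1} are picked by an internal stratified 3-fold grid search on
AUC. Margins are min-max rescaled to (0,1) using the training-margin range so
calibration analysis can bin them — rescaled margins are *not* probabilities,
which is exactly what the reliability analysis shows. Signed-similarity
features are also available for the margin learner as a config switch.

## Evaluation protocols

**Tenfold CV**: random partition into 10 folds (sizes differ by ≤1); each
fold scored by a model trained on the other nine; held-out scores pooled into
one ranked list per target. A plan in which any fold lacks a class is flagged
invalid and the target skipped. **Simulated screens**: the same per-fold
models additionally score a 9000-molecule random-negative test pool; each
negative's score from each fold model enters the pooled list (one entry per
fold, matching the pooling of fold outputs; a `negatives_once` switch instead
averages the ten fold scores per negative). **Training augmentation**: 1000
random-negative molecules are appended to each fold's training set as
inactives (potency class 3); test sets are never touched by augmentation, and
pool/dataset overlap is a hard error.

Metrics: AUC in the Mann–Whitney formulation (ties at midrank, computed via
the trapezoidal ROC, verified against all-pairs counting); enrichment is the
percentage of all true actives recovered in the top ⌈N%⌉ of the ranked list
(a recall reading; a precision variant is available). Reliability curves pool
predictions from targets with AUC > 0.90 into ten width-0.1 bins and report
the observed active fraction per bin. Method pairs are compared by two-sided
paired t-tests of per-target AUC; a zero-variance difference is reported as
"identical methods" rather than raised. Size-stratified summaries report mean
metrics over targets above molecule-count thresholds plus the fraction of
targets on which each method is best (ties split equally).

## Synthetic corpora

The generator emulates the *geometry* of curated bioactivity panels, not
chemistry: per target, two clusters of self-similar actives (random
perturbations of prototype bit sets, 512 bits, density 0.1, unequal 70/30
cluster occupancy), in-assay inactives that are strongly perturbed prototypes
with EC50 ≥ 10 µM, and a shared pool of independent random molecules used as
presumed-inactive negatives. Active EC50s are graded by similarity to the
nearest prototype through `g(sim) = 10^(g0 − g1·sim)` µM with multiplicative
lognormal noise (σ in log10 units). `g0 = 2, g1 = 4` maps the realistic
similarity range onto EC50s that the 1/5/10 µM cutoffs each split
non-trivially; the strictly decreasing form encodes the assumption that
proximity to the cluster chemotype implies potency.

Two named condition sets are frozen in `synthetic.py`:

- `clustered_corpus_config`: 10 targets × (50 actives + 50 inactives), fixed
  flip probability 0.05 — tight clusters, the benchmarking conditions.
- `potency_graded_config`: 4 targets × (60 actives + 40 inactives), per-active
  flip probability uniform in [0.02, 0.18] so actives span a graded
  similarity shell (hence all four potency classes), with inactives placed
  outside the shell (flip 0.25). Labels at 5 µM put potency classes on both
  sides of the label boundary, which is the regime in which potency-sensitive
  votes carry information the binary labels do not.

What passing tests on these corpora do **not** show: robustness to assay
noise heterogeneity, activity cliffs, scaffold-hopping actives, or realistic
substructure correlations — real fingerprints have strongly correlated bits,
synthetic ones are independent. Directional conclusions (MaxSim > MeanSim,
potency votes help when EC50 gradients are informative, random-negative
augmentation improves screens) transfer as qualitative mechanisms, not as
effect sizes.

## Design choices that were genuinely open

- **Vote-mode target**: the potency-sensitive voter keeps the binary label at
  the chosen cutoff as its training target; only the votes change. The
  alternative (an ordinal or graded target) changes the estimand.
- **Rank input**: raw 1-based rank, not rank/k, so the rank weight has the
  same meaning for every k.
- **kNN denominator**: min(k, |train|), so small training sets yield valid
  proportions instead of constants.
- **Enrichment**: recall-of-actives in the top N% by default.
- **Unknown substructures at prediction time** get fresh bit indices beyond
  the training universe: they cannot intersect any training fingerprint but
  still count toward the Tanimoto union, penalizing similarity exactly as
  novelty should.

## Known limitations

- Full-batch gradient descent is fine at these set sizes (≤ a few thousand
  molecules) but would need minibatching far beyond that.
- The max-margin grid search is a small fixed grid, not a full hyperparameter
  optimizer; it is a contract stand-in, and its selected cost/tolerance are
  recorded on the scorer.
- Probability calibration is demonstrated for the voter trained to
  convergence on within-distribution held-out data; distribution shift (e.g.
  external molecules unlike any training cluster) degrades both ranking and
  calibration, as similarity-based methods inherently must.
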