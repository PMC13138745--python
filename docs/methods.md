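# Methods

## The model

`caser` treats cER identification as positive/negative/unlabeled
classification over a gene × feature matrix. The fitted object is a
tri-training ensemble: three SVM base learners h₁, h₂, h₃, initialized on
bootstrap resamples of the labeled pool L and refined with pseudo-labels
drawn from the unlabeled pool U.

Each round, for each learner hᵢ, the error eᵢ of its two peers' joint
prediction is estimated on L (the fraction of labeled points the peers
agree on but mislabel; if they never agree, eᵢ = 0.5). When eᵢ improved
over the previously accepted e′ᵢ, the candidate set
Lᵢ = { x ∈ U : hⱼ(x) = hₖ(x) } is formed and accepted only if
eᵢ·|Lᵢ| < e′ᵢ·l′ᵢ, with the canonical initializations e′ᵢ = 0.5,
l′ᵢ = ⌊eᵢ/(e′ᵢ − eᵢ) + 1⌋ on first use, and the canonical subsampling of
Lᵢ to ⌈e′ᵢ l′ᵢ / eᵢ − 1⌉ points when it is too large. Accepted learners
are refit on the balanced L plus Lᵢ; the loop stops when no learner
updates or after `max_rounds` (default 10). Pseudo-labels are re-derived
from U every round, never carried over. With U empty, the fit reduces to a
bagged three-SVM ensemble.

Assumptions worth keeping in mind: the acceptance conditions control noise
only under the usual "classification noise rate < 1/2, learners not too
correlated" assumptions; bootstrap resampling plus three different kernels
(one RBF, two sigmoid by default) is what supplies the diversity.

## Class balancing

The labeled pool is typically imbalanced. Before bootstrap initialization
the minority class is oversampled to parity with borderline-SMOTE:
synthetic points are convex combinations x = a + u·(b − a), u ∈ [0, 1], of
a "danger" minority point a (between m/2 and m−1 of its m nearest
neighbors are majority; default m = 10) and one of its k nearest minority
neighbors b (default k = 5, automatically reduced when the minority class
is smaller than k + 1). Points whose entire m-neighborhood is majority are
treated as noise and never anchor synthesis. When the classes are so well
separated that no danger point exists, synthesis falls back to ordinary
SMOTE over the non-noise minority points — otherwise easy problems could
never be balanced at all. Balancing is applied to L only; pseudo-labeled
points are never balanced, since distorting their class mix would also
distort the permutation null. Retraining reuses the same balanced L.

## Scoring and calibration

The cER score is the mean of the three learners' calibrated positive-class
probabilities (configurable to the vote fraction). Each SVM is calibrated
with Platt-style sigmoid calibration on out-of-fold decision values (5
stratified folds, fewer when a class is tiny; a plain logistic squash of
the margin when calibration is infeasible). A probability of exactly 0.5
counts as a negative prediction — the conservative choice for a
prioritizer. Scores are row-independent, so gene order never matters.

## Significance

The null distribution is built by independently permuting every feature
column across genes (drawn in canonical sorted-gene order, so results are
invariant to input row order) and re-scoring each permuted table with the
fitted model; the default 100 iterations pool into one empirical null of
100 × n_genes scores. p(g) is the fraction of pooled null scores ≥ the
observed score — ties count, p = 0 is allowed (a +1/(N+1) correction is
available behind a flag). Column permutation preserves each feature's
marginal distribution exactly while destroying gene–feature association;
it does not preserve inter-feature correlation, which is the standard
trade-off of this null. BH q-values use
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, tied p receive identical q, and significance is
q < 0.1 over the family of all scored genes in the run. Novel genes are
significant genes outside the labeled (train + test) sets; dual-role genes
are significant in ≥ 2 subtype runs, with novelty judged against the
subtype training labels.

## Labels

Positives: ERGs in ≥ 2 of the four cancer-gene databases (CancerMine, CGC,
NCG, OncoKB) that carry a recognized epigenetic domain and survive the
LoF-burden filter. The filter excludes genes whose CDS-normalized LoF rate
falls below the (1 − 0.2) quantile of the all-protein-coding background;
because the prose rule this encodes is directionally ambiguous, both the
quantile level and the direction are arguments. Negatives: ERGs on the
neutral-gene list. Everything else labeled "unlabeled" forms U. The
stratified 8:2 train/test split rounds the per-class train count half-up
and is deterministic per seed.

## Derived features

All derived features follow explicit formulas: mutation-class ratios
(count_num + pc)/(count_den + pc) with pseudocount 1 (benign = silent +
LoFI missense; LoF = splice-site + nonsense + frameshift; inactivating
additionally includes start-loss/nonstop-style events); amplification
percentage = share of "gain" records, deletion = its complement; peaks
within 3 kb merged transitively, keeping max height and total span;
S50 = (i* + (0.5 − F₍ᵢ*₋₁₎)/f₍ᵢ*₎)/P on depth-normalized phase fractions —
a linear-interpolation reconstruction validated by its properties (0.5 on
uniform profiles, reversal antisymmetry, monotonicity in late mass) rather
than against the original implementation; super-enhancer percentage = the
fraction of cell lines with ≥ 1 overlapping interval under 0-based
half-open coordinates (touching intervals do not overlap); methylation
ratio = cancer/normal with missing on zero denominators. HiFI/LoFI
assignment of missense variants is an input column; a helper thresholds a
damage probability at 0.5.

## Preprocessing

Numeric features impute missing entries with the column median, count
features with zero; all-missing numeric columns are dropped with a warning
(a median is undefined and zero-filling would fabricate signal). Z-scoring
uses the population standard deviation and maps constant columns to zeros
to keep kernels finite. Both operations are idempotent. Z-scoring is fit
on all genes in the table by default.

## Synthetic data

The generator emulates the study conditions end to end: every gene draws a
latent class (30 % positive by default); features are unit-variance
Gaussians with block correlation through shared latent factors (loading
0.5, block size 5); the informative half of the 20 features is shifted by
1.5 sd in positives; labeled pools of 15 + 15 genes and an unlabeled pool
of 400 are drawn inside a 1,000-gene table, leaving ≈ 570 holdout genes
with known truth; missingness is completely at random. With one
informative feature of effect e the population AUROC is Φ(e/√2), which
anchors the difficulty scale. What it deliberately does not emulate:
heavy-tailed and discrete omics marginals, informative missingness,
batch/cancer-type structure, and the label noise of curated databases — so
green tests demonstrate correctness of the machinery and its statistical
calibration, not performance on real tumor data.

## Numerical and design choices

- All randomness flows from one seed through `numpy.random.SeedSequence`
  substreams (SMOTE, bootstraps, learner fits, null permutations), giving
  byte-identical ranked outputs per seed.
- Problem sizes in tests and the acceptance script (hundreds of genes, tens
  of features, 10–100 permutation iterations, 10–50 replicate seeds) are
  chosen so the statistical properties under test are measurable in
  seconds; they are desk-scale stand-ins for the full gene-by-671-feature
  analysis, which needs only the same calls on the larger table.
- The empirical-p pooled null is shared across genes (one null
  distribution), not per-gene.
- Supervised baselines reuse the identical SMOTE + fit path with the single
  spec replicated and no unlabeled pool, so semi-supervised gains are
  attributable to the unlabeled data alone.
- SMOTE inside each CV fold only, never before splitting (leakage).
- Holdout classification threshold is 0.5 on the ensemble score.

## Known limitations

The permutation null ignores feature-feature correlation, making it mildly
liberal when many features are strongly correlated. Platt calibration on
~30 labeled genes is coarse; scores are best read as rankings. The
tri-training guarantees are heuristic for SVMs (their error is not
classification noise in the formal sense). The S50 reconstruction and the
LoF-filter direction encode one reading of ambiguous prose, both exposed
as configuration.
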