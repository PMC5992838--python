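# Methods

`psnpipe` implements a network-based strategy for predicting binary clinical
endpoints from multi-omics cohorts. Instead of classifying patients on their
molecular profiles directly, the pipeline builds a Patient Similarity
Network (PSN) per data source — a complete weighted graph whose nodes are
patients — and turns each patient's *position in that network* into feature
vectors for standard classifiers. This note records the models, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Dimension reduction

Each omics matrix (patients x features) first drops every feature with at
least one missing value. Four optional reduction strategies follow:

* **Rank-sum selection** (per endpoint): a two-sample Wilcoxon rank-sum test
  per feature between the two label groups, keeping either all features with
  p < 0.05 or the 10% smallest p-values regardless of significance. The
  exact null distribution is used when both groups have at most 10 members
  and the pooled sample is tie-free; otherwise the normal approximation with
  tie correction. Features constant across all samples get p = 1.
* **Variance selection**: the 10% most-varying features, ties broken by
  feature id for determinism.
* **PCA**: centered principal components, keeping the smallest leading set
  whose cumulative explained variance ratio exceeds 0.90.
* **None**: the complete matrix.

Selection statistics default to being fitted on training patients only
(`fit_scope="train_only"`) and then applied to all patients; an
`all_samples` mode exists because some published workflows fit on the full
cohort. The leakage-free default is the package's own hygiene choice — with
transductive network features (below) the labels still never touch network
construction either way.

## Network inference

Pearson correlations `c_ab` between all patient-profile pairs are min-max
normalized over the set `C` of all off-diagonal coefficients and raised to a
soft-threshold power:

    w_ab = ((c_ab - min C) / (max C - min C)) ** beta

Negative correlations are handled by the min-max shift (no absolute value).
`beta` is selected as the smallest value in {2, 4, 6, 8, 10, 12} whose
*truncated scale-free fit index* reaches 0.90; `beta = 1` provides the
un-thresholded "correl" control. If no candidate qualifies, the best-fitting
one is returned with a structured warning — never silently.

The fit index is the R² of regressing the binned log10 node-frequency on
log10(mean connectivity) and mean connectivity jointly (a power law with
exponential truncation), with connectivity = weighted degree, 10 equal-width
bins, and empty bins dropped. Two properties of this convention are worth
knowing. First, because `log k` and `k` are nearly collinear over a narrow
connectivity range, the regression can reproduce any locally quadratic
log-frequency shape, so the index is liberal: even structureless networks
can score far above 0.5. Second, it is sensitive to the histogram's
monotonicity, so the index fluctuates meaningfully across cohort draws
(roughly 0.7-0.95 on the standard modular benchmark). The index is
therefore treated as a selection criterion, not as evidence of scale-free
topology.

PSNs stay complete — no pruning or sparsification before feature
extraction, since the soft threshold defines weights for every pair.

**Fusion.** Multiple PSNs over the same patients are merged by Similarity
Network Fusion: each network yields a full kernel (row mass halved, 1/2 on
the diagonal) and a K-nearest-neighbour local kernel; for T iterations each
full kernel is replaced by `S @ mean(other kernels) @ S.T`, symmetrized and
renormalized. Defaults K = 10 neighbours, T = 50 iterations. Fusion operates
on the already-rescaled similarity matrices (no re-kernelization from raw
data). The output is symmetrized, min-max rescaled to [0, 1], zero diagonal.

## Topological feature families

Four families are extracted per network; all are standardized column-wise
to zero mean and unit SD (constant columns become all-zero with a warning).

**Centrality (12 columns, fixed order).** weighted degree, closeness,
current-flow closeness, current-flow betweenness, eigenvector, Katz, HITS,
pagerank, load, weighted local clustering, and iterative variants of
weighted degree and local clustering. Conventions, chosen where the
literature admits several and all switchable:

* shortest-path metrics use distance = 1/weight (not 1 - weight);
* flow/spectral metrics use the weight as conductance/affinity;
* local clustering is the geometric-mean (Onnela) weighted variant,
  computed in closed matrix form (verified against networkx);
* eigenvector and HITS are the Perron eigenvector of the symmetric weight
  matrix via dense `eigh` — deterministic, unlike randomized iterative
  eigensolvers; on an undirected graph HITS hub and authority scores
  coincide with it (unit-sum normalized);
* Katz attenuation is 0.9/lambda_max per network; pagerank damping 0.85,
  tolerance 1e-8;
* iterative metrics repeatedly record the current maximum's value, remove
  that node, and recompute on the shrinking graph; ties break by ascending
  patient id; the final singleton keeps value 0.

**Modularity (sum of k_s columns).** Two partitioning families, every
near-optimal partition kept (criterion within 5% of the best — the margin
is a package choice, since "several optimal partitions" admits no unique
definition): spectral clustering with the number of modules chosen by the
normalized-Laplacian eigengap, and a weighted degree-corrected stochastic
block model fitted by spectral initialization plus greedy node moves, with
block count (including the single-block model) chosen by a description
length = negative profile log-likelihood + parameter and assignment coding
costs. Module labels are canonicalized by decreasing module size. Each
partition contributes a one-hot block; a node's row sums to the number of
partitions. SBM fit failures degrade to spectral-only with a warning.

**Embedding (2 x 128 columns).** Two biased second-order random-walk runs —
(p, q) = (1, 4), breadth-favouring, and (4, 1), depth-favouring — each
embedded by skip-gram with negative sampling and concatenated. Walk
defaults follow the node2vec reference tool: 10 walks per node, 80 nodes
per walk, window 10, one training pass, 5 negative samples, initial
learning rate 0.025 with linear decay. The trainer is a mini-batch numpy
implementation: batches are capped at 8 pairs per vocabulary node (larger
batches aggregate so many duplicate per-node updates that the effective
step size diverges), duplicates within a batch are summed exactly through
sparse one-hot products, and a single worker makes results bit-reproducible
from the seed. Walk sampling is direct categorical sampling per step, all
walks advancing in lock-step; alias tables are deliberately not precomputed
because on complete graphs the per-(previous, current) table is O(n³)
memory for no measurable speed gain at cohort scale.

**Diffusion (1,000 columns).** Each feature is one diffusion round: 10% of
the nodes (rounded, minimum 1, with a warning for tiny graphs) are drawn
without replacement and given signal 1, the rest 0; the signal is smoothed
by the regularized-Laplacian kernel `K = (I + L)^-1` with `L = D - W`, and
the post-diffusion value at every node is recorded. The kernel is computed
once per network and reused for all rounds. `K` is symmetric positive
definite and conserves total signal (each column of the feature matrix sums
to the seed count — a useful invariant check). A heat kernel `expm(-tL)` is
available; raw post-diffusion scores are used, not permutation-normalized
ones, and which smoother variant the broader literature family intends is
genuinely open — the regularized Laplacian is a documented default, not an
inference.

## Classification and integration

Endpoints are binary; evaluation uses a stratified half/half train-test
split (per-class train share = ceil(fraction x class size)). Three
algorithms: LDA (falling back to the lsqr solver with automatic shrinkage
on a singular within-class covariance), random forest (500 trees), and SVM
(linear or RBF). SVM cost and width are grid-searched over 2^(2p),
p in {-4, -2, -1, 0, 1, 2, 4}, by stratified 5-fold CV balanced accuracy on
the training side, ties resolving to the first grid point in scan order.
Features are re-standardized inside every fit using training rows only.
Continuous scores in [0, 1] come from class probabilities (LDA, RF) or a
logistic transform of the SVM decision value.

Performance is reported as ACC, bACC = (sensitivity + specificity)/2, and
MCC (0 when a confusion-table marginal is empty), plus the confusion
counts. A 10-times 5-fold cross-validation on the training patients (50
fits; SVM hyper-parameters resolved once on the full training set before
the folds) yields `cv_mean_bacc`, the leakage-free estimate used as the
voting weight — weighting by test performance would leak the evaluation
data into the ensemble.

**Weighted voting.** Member scores are combined with weights proportional
to their CV performance, normalized to sum to one; the consensus score is
thresholded at 0.5, ties counting as positive (a deterministic, documented
rule). Group comparisons of bACC samples use Welch t-tests for two groups
and one-way ANOVA with Tukey HSD for more, significance at p < 0.01,
reporting the accuracy gain Delta_bACC = mean(A) - mean(B).

Topological features are *transductive*: the PSN spans train and test
patients jointly (labels never enter network construction). This mirrors
the method's design; consequently a trained model applies only to patients
present in the network.

## Synthetic cohorts

The generator emulates the structure of a multi-source clinical cohort:
several feature matrices over a shared patient set, the last source
covering only a subset ("small cohort", optionally biased toward positive
patients), Bernoulli endpoint labels, and planted signal features whose
mean shifts by `effect_size` SD units in the positive class. Correlated
feature blocks (and, in `modular_profiles`, correlated patient blocks) use
the latent-factor construction `x = sqrt(rho) z + sqrt(1 - rho) eps`, which
gives pairwise correlation rho in expectation. Endpoints are independent of
each other by default so that power analyses stay interpretable.

What it does **not** emulate: copy-number segment structure, platform or
batch effects, heavy-tailed count noise, or correlated endpoints. Passing
the recovery benchmarks therefore shows that the pipeline's machinery is
sound — signal planted in profile space survives the network, feature, and
voting stages — not that comparable accuracy is attainable on any
particular clinical dataset.

## Benchmark scales and reproducibility

The standard benchmarks use 200 patients x 500 features (network-level
checks and signal recovery with effect size 2 and 50 signal features per
endpoint) and 4 patient blocks at rho = 0.7 for the soft-threshold
benchmark; oracle equivalences run on graphs of at most 7 nodes where
brute-force reimplementation is feasible. Every stage derives its RNG seed
from the master seed, the stage name, and the source tag (CRC32, below
2^31), so a rerun with the same configuration and master seed reproduces
the output tree bit-for-bit; the run manifest records the configuration
hash (output directory excluded) next to every artifact.

## Known limitations

* The truncated scale-free index is liberal and noisy (above); selected
  beta values should be read together with the attained fit.
* The SBM description length is a BIC-style approximation, not an exact
  microcanonical description length; it reliably separates planted from
  uniform structure but block counts near the decision boundary can differ
  from exact-MDL implementations.
* The skip-gram trainer is single-threaded by design; a parallel mode would
  be faster and non-deterministic.
* Weighted voting assumes member scores are comparable in [0, 1]; scores
  from different algorithm families are probability-like but not
  calibrated.
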