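# psnpipe

Network-based prediction of binary clinical endpoints from multi-omics
patient cohorts.

Clinical outcome prediction usually feeds molecular profiles straight into
a classifier. `psnpipe` implements the alternative: build a **Patient
Similarity Network** (PSN) per omics source — a complete weighted graph
whose nodes are patients and whose edge weights are soft-thresholded
correlations between their profiles — and classify each patient from their
*topological position* in that network. It is aimed at computational
biologists studying whether network structure carries predictive signal
beyond the raw features, and ships a synthetic-cohort generator so every
stage is testable without access to any clinical dataset.

## Method

For patients *a, b* with profile correlation *c₍ab₎*, edge weights follow
the WGCNA-style soft threshold over the set *C* of all pairwise
correlations:

    w_ab = ((c_ab − min C) / (max C − min C))^β

with β the smallest value in {2, 4, 6, 8, 10, 12} whose truncated
scale-free fit index R² reaches 0.90 (β = 1 is the un-thresholded
control). Networks from several sources can be merged by Similarity
Network Fusion (K = 10 neighbours, T = 50 iterations).

Each network yields four node-feature families:

| family     | columns  | content |
|------------|----------|---------|
| centrality | 12       | weighted degree, closeness, current-flow closeness/betweenness, eigenvector, Katz, HITS, pagerank, load, weighted clustering, iterative degree & clustering |
| modularity | Σ k_s    | one-hot memberships of every near-optimal spectral and stochastic-block-model partition |
| embedding  | 256      | two node2vec runs, (p,q) = (1,4) and (4,1), d = 128 each, concatenated |
| diffusion  | 1,000    | post-diffusion signal of random 10%-seed sets through the regularized-Laplacian kernel (I + L)⁻¹ |

Features are standardized and fed to LDA, random-forest or SVM classifiers
(SVM cost/width grid 2^(2p), p ∈ {−4, −2, −1, 0, 1, 2, 4}); performance is
reported as ACC, bACC and MCC on a held-out stratified split, with a
10×5-fold cross-validation on the training patients providing the weights
for a voting ensemble (weights ∝ CV bACC, normalized to sum to one,
consensus thresholded at 0.5). Group comparisons use Welch t-tests or
ANOVA + Tukey at p < 0.01, reporting Δ_bACC.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from psnpipe import (CohortSpec, DiffusionConfig, ModelConfig,
                     PipelineConfig, ReductionConfig, generate_cohort,
                     run_pipeline, write_cohort)

spec = CohortSpec(
    n_patients=120,
    sources=[("rnaseq", 400)],
    endpoints=[("relapse", 0.4)],      # prevalence 40%
    n_signal_features=40,              # planted informative features
    effect_size=1.5,                   # class shift, in SD units
    rng_seed=7,
)
write_cohort(generate_cohort(spec), "cohort/")

config = PipelineConfig(
    cohort_dir="cohort/", output_dir="run/", rng_seed=7,
    mode="topological",
    families=("centrality", "modularity", "diffusion"),
    reduction=ReductionConfig(strategy="variance_top"),
    diffusion=DiffusionConfig(n_diffusions=200),
    model=ModelConfig(algorithm="LDA"),
)
manifest = run_pipeline(config)

ep = manifest["results"]["relapse"]
for name, report in ep["models"].items():
    print(f"{name:22s} bACC={report['bacc']:.3f} MCC={report['mcc']:.3f} "
          f"(CV {report['cv_mean_bacc']:.3f})")
print(f"{'weighted vote':22s} bACC={ep['vote']['bacc']:.3f} "
      f"MCC={ep['vote']['mcc']:.3f}")
```

Output:

```
centrality_rnaseq      bACC=0.915 MCC=0.824 (CV 0.941)
modularity_rnaseq      bACC=0.972 MCC=0.932 (CV 0.973)
diffusion_rnaseq       bACC=0.675 MCC=0.342 (CV 0.556)
weighted vote          bACC=0.937 MCC=0.862
```

The planted 40-feature signal separates the classes in the similarity
network: the centrality and module-membership models recover it almost
perfectly on the held-out half, the diffusion model is weaker on this
cohort, and the CV-weighted vote tracks its strongest members. `run/`
contains the inferred network, every feature matrix, per-model reports and
the consensus scores, all reproducible bit-for-bit from `rng_seed`.

The same workflow is scriptable from the shell:

```bash
psnpipe simulate --n-patients 120 --sources rnaseq:400 \
        --endpoints relapse:0.4 --effect-size 1.5 --seed 7 --out cohort/
psnpipe infer --matrix cohort/rnaseq.tsv --out network.tsv
psnpipe features --network network.tsv --family centrality --out cent.tsv
psnpipe train --features cent.tsv --clinical cohort/clinical.tsv \
        --endpoint relapse --algorithm LDA --seed 7 --out model.yaml
```

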