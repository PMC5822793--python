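# netscore

Risk stratification from gene coexpression networks and a convolutional
Cox score, on survival-annotated expression cohorts.

Instead of ranking individual prognostic genes, this workflow treats the
transcriptome as a weighted coexpression network, finds its modules,
asks which modules' summary profiles predict overall survival, and
builds a compact neural scoring model from the hub genes of the modules
that validate in independent cohorts. It is aimed at computational
biologists who want a tested, seed-reproducible implementation of that
whole chain — network construction through Kaplan-Meier curves — plus a
synthetic multi-cohort benchmark with planted ground truth to measure it
on.

## The method

1. **Network.** Pearson correlation `r_ij` across samples; unsigned
   adjacency `a_ij = |r_ij|^β` (default β = 6, or chosen by scale-free
   topology fit); topological overlap
   `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
   `ℓ_ij = Σ_u a_iu a_uj`; average-linkage clustering on `1 − TOM`;
   modules by hybrid dynamic tree cut (height cutoff 0.99, deep split 2,
   minimum size 30; unassigned genes are "gray").
2. **Screening.** Each module is summarized by its eigengene (first
   principal component, unit variance, oriented with the module mean).
   A univariate Cox fit per eigengene flags survival-related modules at
   uncorrected p < 0.05; eigengenes are recomputed from each test
   cohort's own expression, and only modules significant everywhere
   advance.
3. **Selection.** Genes rank by module membership `kME_gm = cor(x_g, ME_m)`;
   the top 10 per advancing module form the model input (20 genes for
   two modules).
4. **Scoring.** A per-module 1-D convolutional layer (kernel = module
   block, so each filter summarizes one module), three fully connected
   rectified layers and a linear output produce the scalar risk score.
   Training minimizes the negative Cox log partial likelihood (Breslow
   ties) full-batch with Adam; hyperparameters come from seeded 5-fold
   cross-validation maximizing Harrell's C. A conventional multivariate
   Cox model on the same 20 genes is the comparison baseline.
5. **Analytics.** Continuous-score Cox, median dichotomization into
   high/low risk, Kaplan-Meier + log-rank, multivariate Cox against
   clinical covariates, and subgroup tables.

The survival engine (Newton-Raphson Cox with Breslow ties, product-limit
estimator, K-sample log-rank, Harrell's C with bootstrap SE) and the
network training are implemented in the package and audited against
brute-force oracles and `lifelines` in the test suite. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic benchmark (two cohorts, n = 300/200, six planted modules of
which the two largest carry a log-hazard effect of 1):

```sh
cd analysis
python 01_simulate_cohorts.py
python 02_build_network.py
python 03_screen_modules.py
python 04_select_genes.py
python 05_train_netscore.py
python 06_survival_analytics.py
```

which prints (seed 2026):

```
cohort0: 300 genes x 300 samples, 30% censored
modules: {'turquoise': 60, 'gray': 60, 'blue': 50, 'brown': 40, 'yellow': 30, 'green': 30, 'red': 30}
adjusted Rand index vs planted truth: 1.000
training screen: ['turquoise', 'blue'] significant of 6 modules
test-cohort validation: ['turquoise', 'blue']
advancing to model building: ['turquoise', 'blue']
selected 20 genes (turquoise: 10, blue: 10) as model input
5-fold CV chose filters=4, fc=(32, 16, 8), epochs=150 (mean fold C = 0.745)
cohort0: C-index 0.872 +/- 0.012
cohort1: C-index 0.768 +/- 0.021
test cohort: network C 0.709 vs linear Cox C 0.784 on the same 20 genes
cohort0: high- vs low-risk HR 12.00 (8.24-17.47), log-rank p = 8e-51
cohort1: high- vs low-risk HR 5.11 (3.48-7.51), log-rank p = 1.2e-19
```

Reading this: the tree cut recovers the six planted modules exactly
(ARI 1.0, noise genes gray); screening and independent validation keep
precisely the two modules that carry a planted hazard effect; their top
hub genes feed the scoring model, which separates the held-out cohort
into risk groups with a hazard ratio of ~5. On this *linear* planted
signal the 20-gene Cox baseline is competitive with the network — the
network's advantage appears when the hazard depends on a product of two
module factors, a case the linear model cannot represent (measured in
the acceptance suite). Derived tables land in `results/analysis/`;
regenerable cohort data goes to `scratch/`.

The same pipeline runs as one command on a simulated or on-disk cohort
set:

```sh
netscore run-all --seed 7 --outdir scratch/run7
```

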