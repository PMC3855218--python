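# Methods

## The model

The object of study is the *average* accuracy of genomic prediction,
`r = corr(GBV, TBV)`, for a randomly composed training set of size `N` from
one population — not the accuracy of any particular animal. GBVs are
predicted with GBLUP:

    y = 1·mu + g + e,   g ~ N(0, G·sigma2_g),   e ~ N(0, I·sigma2_e),

with `y` the quasi-phenotypes (EBVs), and `G` the VanRaden method-1 genomic
relationship matrix built from observed allele frequencies, `G = (X−2P)(X−2P)' / (2 Σ p_j(1−p_j))`.
Variance components are estimated once per marker panel on the complete
data by REML and reused in every cross-validation fold; re-estimating them
per fold changes fold accuracies only marginally and multiplies the cost by
the number of folds.

The deterministic accuracy equations (D1, G1, G2, D2, G3 and the density
law; see the README for the formulas) express `r` through the training size
`N`, the quasi-phenotype reliability `h²`, the number of independent
chromosome segments `Me`, and — in the D2/G3 family — the maximum
achievable accuracy `w`. `Me` is treated purely as a population parameter
to be estimated from data; no theoretical formula from effective population
size is used. `w²` is interpreted as the fraction of genetic variance
tagged by the marker panel, so `100·w²` is reported alongside every fit.

## Cross-validation engine

For each `k` in the scheme (production default k = 2…10, 15, 20), animals
are randomly assigned to balanced folds (sizes differ by at most one);
each fold is predicted from the remaining `k−1` folds, and

    r_hat = corr(GBV, EBV) / r(EBV, TBV)

is averaged over the `k` folds to give one replicate value. The divisor is
the mean EBV accuracy of the validation animals. The realised training size
recorded per scenario is `floor(n(k−1)/k)`. Replicate accuracies are kept
raw: no Fisher transform and no clipping at 1 (values slightly above 1 can
occur in small folds). A Shapiro–Wilk check per scenario (delegated to
`scipy.stats.shapiro`) is reported as QC but never gates the fit.

## Likelihood and optimisation

Replicate accuracy `r_ij` of scenario `i` is modelled as normal with mean
given by the chosen equation at `N_i` and variance equal to the scenario's
empirical replicate variance (denominator `n_reps − 1`). Scenarios and
replicates are treated as independent — an acknowledged simplification,
since folds of one replicate share animals.

- D1/G1/G2: bounded 1-D maximisation over `log Me ∈ [0, ln 10⁶]`
  (`scipy.optimize.minimize_scalar`).
- D2/G3 and the global (Me, z) density fit: a coarse grid over
  `(log Me, w)` (or `(log Me, z)`) seeds five L-BFGS-B polish runs; the
  likelihood surface is a curved ridge in `(Me, w)` and a single start can
  stall on it. Bounds: `Me ∈ [1, 10⁶]`, `w ∈ [0.01, 1]`, `z ∈ [0, 10]`.
  `w_hat = 1` is a legitimate boundary report, not an error.

Tests verify optimiser results against dense grid-search oracles (`Me`
step 1, `w` step 0.001) and against noiseless self-consistency tables.

The `w`-versus-density regression is ordinary least squares of the fitted
`w` on `x = 1/ln(M/L)` (statsmodels OLS). With plateau detection enabled,
the maximal high-density run of points whose successive `w` differ by less
than 0.005 is excluded from the line and its mean reported as the plateau
`w`; the 0.005 tolerance makes precise the visual "constant level"
criterion.

## Synthetic populations

The generator produces the statistical structure the equations assume, so
that every downstream stage has a testable ground truth:

- **Genotypes.** Biallelic SNPs in mutually independent LD blocks. Each
  block draws a single latent allele frequency, uniform on
  `[maf_floor, 1−maf_floor]` (default floor 0.05, mimicking the roughly
  uniform frequency profile of commercial chips); within a block, each
  haplotype's allele indicators share a Gaussian-copula latent factor with
  correlation `ld_correlation` (default 0.99). A block is therefore nearly
  rank-1 and behaves as *one* independently segregating chromosome segment
  — deliberately so: the accuracy equations count segments, and a
  homogeneous segment structure is the regime in which a single `Me`
  describes the learning curve. Default block length 10 markers.
- **Trait.** QTL effects i.i.d. normal. A fraction of QTL sit on panel
  markers (the typed part), the rest on hidden loci simulated independently
  and never exposed. The two parts are rescaled so the typed share of TBV
  variance is exactly `tagged_variance_fraction` (= `w²`, default 0.766),
  and TBV is standardised to unit sample variance.
- **Quasi-phenotype.** `y = r·TBV + sqrt(1−r²)·eps` with
  `r = ebv_accuracy` (default 0.945, the reliability 0.893 then playing the
  role of `h²`). This emulates progeny-test EBVs of high, homogeneous
  accuracy; the "accuracy > 0.84" regime of real bull data.

What the generator does **not** emulate: pedigree relationships and family
structure, selection, multiple chromosomes with genetic maps, allele
frequency–dependent QTL effects, and realistic decay of LD with distance.
Passing tests therefore demonstrate the correctness and internal
consistency of the machinery and the identifiability of `(Me, w)` under the
model's own assumptions — not that the equations describe any particular
real population.

## Numerical choices

- REML: eigendecomposition of `G` once, then 1-D search over `log lambda`
  (`lambda = sigma2_e/sigma2_g`) in `[−10, 10]`; diagonal jitter
  `1e−8·mean(diag G)` when eigenvalues below `−1e−8` occur (finite-sample
  `G` is routinely rank-deficient).
- GBLUP: Cholesky solve of `V = sigma2_g·G_TT + sigma2_e·I`; the overall
  mean by GLS; predictions `sigma2_g·G_PT V⁻¹(y−mu)` — equal to Henderson's
  mixed-model equations, which the tests check to 1e−8 on random small
  instances.
- Systematic marker thinning keeps the first marker (index 0, 2^x,
  2·2^x, …); the choice is arbitrary but fixed for reproducibility.
- Empirical variances use denominator `n_reps − 1`.
- Genome length default `L = 29` Morgan (autosomal cattle genome);
  configurable everywhere the density enters.

## Test problem sizes

The reference synthetic world for end-to-end checks is `n = 2000`
individuals × `M = 5000` markers with `w² = 0.75`: large enough that the
accuracy curve approaches its ceiling within the observed training-size
range (as in the motivating bull data sets), small enough for minute-scale
runtimes. Test runs use 3 CV replicates per scenario rather than the
production default of 50, and the extrapolation check fits on a
1000-individual subsample of a 1600-animal world and predicts the
10-fold-CV training size of the full world. The multi-seed stability check
spans 10 such worlds.

## Known limitations

- Independence of replicate accuracies is assumed in the likelihood; the
  effective information is overstated, so log-likelihood differences
  between families are comparable but not calibrated test statistics (no
  standard errors or confidence intervals are produced, by design).
- The fitted `w` carries a small downward finite-range bias (~0.01–0.02 at
  the reference world size) because the observed accuracies sit below the
  asymptote the parameter describes.
- `Me` from the goodness-of-fit approach is internally stable but need not
  match segment counts from population-genetic theory; it should be read
  as a curve-shape parameter.
- The solvers are dense (`O(n³)`); populations beyond ~20k individuals are
  out of intended scope.
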