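# Methods

## Statistical model

The package implements multivariable Mendelian randomization with Bayesian
model averaging (MR-BMA) on two-sample GWAS summary statistics. Inputs are
per-variant association estimates with *d* candidate risk factors (SD
units) and with a binary outcome (log odds ratios), plus standard errors.
Dividing each variant's row by its outcome standard error yields a
standardized design X (n × d) and response y on which ordinary least
squares without intercept equals the fixed-effect inverse-variance-weighted
(IVW) multivariable MR estimator. The key modelling assumptions inherited
from IVW MR are: instruments associate with the outcome only through the
modelled exposures (no unmodelled pleiotropy — violations are what the
diagnostics target), exposure associations are measured without error
relative to the outcome's, and effects combine linearly.

For a factor subset *s* the Bayesian model is

    y = X_s θ + ε,   ε ~ N(0, I),   θ_j ~ N(0, σ_j²) independently,

whose marginal likelihood is the closed form N(y | 0, X_s D X_sᵀ + I) with
D = diag(σ²). It is evaluated through the |s|-dimensional inner matrix
A = I + D^{1/2} X_sᵀ X_s D^{1/2} (matrix determinant lemma plus Woodbury),
so scoring a model costs one small solve against a cached d × d Gram
matrix; sizes 1 and 2 use hand-written scalar/2×2 forms because permutation
inference re-scores the model space thousands of times. Residual variance
is fixed at 1 after standardization (the fixed-effect convention);
reported causal-effect standard errors use the unscaled inverse Gram
matrix.

Model posterior probabilities combine the marginal likelihood with an
independent-inclusion prior p^{|s|}(1−p)^{d−|s|}, restricted to
1 ≤ |s| ≤ `max_model_size` and normalized over the scored space. The empty
model is excluded from normalization (only non-empty risk-factor sets are
ranked) but its score is recorded for reference. A factor's marginal
inclusion probability (MIP) is Σ_{s∋j} P(s|y); its model-averaged causal
effect (MACE) is Σ_{s∋j} P(s|y)·θ̂_j(s) — a sum over containing models, not
an average conditional on inclusion, so MACE ≈ MIP × conditional effect.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `inclusion_prob` | 0.1 | prior probability a factor is causal (≈3 expected causal factors among 30) |
| `effect_sd` | 0.5 | prior SD of causal effects, log odds per SD; scalar or per-factor vector |
| `max_model_size` | 12 | subset-size cap for scoring |
| `gwas_sig_threshold` | 5×10⁻⁸ | instrument significance and strong-instrument factor rule |
| `ld_r2_threshold` / `min_distance` | 0.05 / 1 Mb | LD and distance pruning of instruments |
| `max_abs_correlation` | 0.99 | factor-collinearity bound on genetic-association correlations |
| `model_prob_floor` | 0.02 | minimum posterior probability for a model to be diagnosed |
| `cooks_threshold_rule` | 0.5 | F(k, n−k) quantile flagging influential variants |
| `q_alpha` | 0.05 | outlier cutoff: χ²(1) quantile at 1 − α/n (Bonferroni-style) |
| `n_perm` | 1000 | permutations for empirical p-values |

The prior constants are deliberately configuration, and results should be
read jointly with the priors used: with `inclusion_prob = 0.1` the prior
odds already penalize larger models, so posterior concentration on a small
model reflects data, not only prior. `effect_sd = 0.5` is weakly
informative on the log-odds-per-SD scale, where plausible lipid effects on
coronary disease are a few tenths. Because the prior is independent per
coefficient, a per-factor `effect_sd` vector makes the scoring exactly
equivariant to rescaling individual exposure columns (rescale a column by
c, its prior SD by 1/c: posteriors are invariant, effects scale by 1/c);
the test suite asserts this exact form.

## Workflow

1. **Read + harmonize.** Variants are matched by identifier (not position,
   avoiding genome-build ambiguity; positions are used only for distance
   pruning). Where the outcome's effect allele equals the exposure's other
   allele the outcome beta's sign is flipped; irreconcilable allele pairs
   and variants missing any value are dropped, each with a provenance
   record. Palindromic (A/T, C/G) variants are kept with a warning by
   default and droppable by flag — strand cannot be resolved from alleles
   alone, so the choice is surfaced rather than silently made.
2. **Instrument selection.** Greedy in ascending p-value (ties broken by
   identifier, making the result order-invariant): keep a candidate iff
   genome-wide significant, r² < 0.05 with every kept variant, and ≥ 1 Mb
   from every kept same-chromosome variant. Cross-chromosome pairs are
   implicitly r² = 0. This mirrors standard clumping practice.
3. **Factor pruning.** Pearson correlations of the per-factor
   genetic-association columns are computed; after drop-list and
   strong-instrument removals (a factor needs ≥1 instrument at p < 5×10⁻⁸
   when exposure p-values are available), the worst pair above the
   threshold loses its member with the larger mean |r| to the rest, until
   no pair remains at or above the bound. Keep/drop lists let a curated
   (biological) resolution of collinear groups be expressed as
   configuration. Order of the three steps (drop-list → strong-instrument →
   correlation loop) is fixed for determinism.
4. **Scoring.** Exhaustive enumeration up to `max_model_size`, or shotgun
   stochastic search: from a random admissible subset, score all one-factor
   additions/deletions/swaps, move to a neighbour with probability
   proportional to its posterior weight, iterate for `budget` steps, and
   normalize over the deduplicated union of visited models. Rank-deficient
   subsets receive zero posterior and are logged. Reported rankings break
   posterior ties by smaller model, then lexicographic labels.
5. **Diagnostics.** For every model above `model_prob_floor`: Cook's
   distance D_i (closed form via leverages, validated against literal
   leave-one-out refits) flags influential variants above the median of
   F(k, n−k); the squared standardized residual q_i (the variant's
   heterogeneity-Q contribution) flags outliers above the
   1 − 0.05/n χ²(1) quantile. The union of flags across diagnosed models is
   removed — producing a single cleaned dataset rather than per-model
   variants — the search is rerun, and the loop repeats until no flags or
   `max_rounds` (5). Removal is permanent; if a removal would leave
   n ≤ max_model_size + 2 the workflow stops with an "exhausted" warning.
6. **Inference.** The permutation null permutes the standardized response
   across variants, preserving the exposure correlation structure the null
   must respect, and reruns the full search per permutation. Empirical
   p-values use the add-one estimator (1+k)/(1+N), whose smallest
   attainable value is 1/(N+1). BH-FDR adjustment takes the family size m
   as the number of analyzed factors, not the number of rows displayed; m
   may exceed the supplied vector (partial family), in which case
   unsupplied p-values are treated as larger than all supplied ones.

## Synthetic data: what it emulates, and what it does not

The generator draws per-variant exposure effects from a zero-mean
multivariate normal with a block correlation structure (default six blocks
of five factors, within-block r = 0.9, between-block r = 0.2 — the
subfraction-panel pattern where measures of one lipoprotein class move
together), scaled by an instrument-strength SD of 0.1. Outcome betas are
β_X·θ plus optional direct (pleiotropic) effects on designated outlier
variants plus noise with the reported standard error. Default magnitudes —
exposure SE 0.01, outcome SE 0.02 — correspond to a ~25 000-sample
metabolomics GWAS and a case-control outcome GWAS with on the order of 10⁵
cases. Defaults use 148 variants and 30 factors. Alleles are synthesized
non-palindromic so generated data pass harmonization unchanged.

Because the outcome noise uses exactly the standard errors the outcome
panel reports, the weighted regression's assumed model is the true
generative model; parameter recovery is therefore a sharp test of the
machinery, not of robustness. What the generator does **not** emulate — and
what passing tests therefore do not demonstrate — includes: overdispersion
(real outcome associations are noisier than their SEs suggest), weak or
winner's-curse-biased instruments, measurement error in exposure betas,
sample overlap between exposure and outcome GWAS, LD between instruments,
and allele-frequency structure. Results on real data depend on those
violations; the diagnostics stage addresses only the pleiotropy-like ones.

The scenario library fixes five named conditions with frozen seeds: `null`
(θ = 0, type-I calibration), `single-causal` (θ₁ = 0.4 inside a
0.9-correlated block, recovery), `two-causal`, `causal-plus-outliers`
(three +10-standardized-unit direct effects, diagnostics recovery) and
`near-collinear` (a 0.995-correlated pair, factor pruning).

## Numerical choices and problem sizes

- The inner matrix I + D^{1/2}GD^{1/2} is always positive definite, so the
  marginal likelihood is finite even for collinear subsets; rank deficiency
  is detected separately at the effect-estimation step (Cholesky failure or
  correlation-matrix rank check) and such models are scored zero.
- Normalization uses log-sum-exp; posterior sums are asserted to 1 ± 1e-10.
- Leverages ≥ 1 − 1e-12 yield infinite Cook's distance (the fit is wholly
  determined by that point).
- Tie-breaks are deterministic everywhere (identifier order for instrument
  p-ties, mean-|r|-then-label for factor pruning, model-size-then-labels
  for rankings), making reruns byte-identical; stochastic search and
  permutations are reproducible bit-for-bit given their seeds.
- Statistical test runs use deliberately compact sizes chosen to keep the
  suite quick while leaving clear margins: recovery uses 50 replicates with
  exhaustive search to model size 3; calibration uses 20 replicates × 200
  permutations at model size 2; diagnostics recovery uses 20 replicates at
  model size 2. The acceptance script uses the same conditions at 10–20
  replicates.

## Known limitations

- No intercept, no MR-Egger variant, no heteroscedasticity-robust errors;
  the optional overdispersion scale mentioned in some MR-BMA treatments is
  not implemented — residual variance is fixed at 1.
- LD pruning consumes a supplied pairwise r² table; the package never
  estimates LD from genotypes and has no proxy-variant lookup.
- Empirical p-values are bounded below by 1/(n_perm+1); factors whose
  signal exceeds that resolution are reported at the boundary.
- The permutation null severs all variant–outcome linkage, so it tests the
  global null per factor rather than a conditional null given other
  factors' effects; under strong signal in one factor, correlated factors'
  p-values should be read with that in mind.
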