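# Methods

This note documents the statistical procedures implemented in asvnet,
the defaults they ship with, the synthetic data they are validated on,
and the numerical conventions and known limitations a user should be
aware of.

## Pipeline model

The pipeline treats an amplicon experiment as a triple (counts,
taxonomy, phenotypes): a non-negative integer ASV × sample matrix,
Greengenes-style ranked lineages per ASV, and three continuous
per-animal phenotypes (EFF, CH4Y, ACET:PROP). The analysis chain is
prevalence filter → CSS-log2 → correlation network over ASVs plus
phenotypes → PCIT pruning → per-phenotype predictor sets → family
enrichment → best-subsets selection → baseline/CV evaluation. Each
stage is a pure function of its inputs and a stage seed, so whole runs
are reproducible bit for bit.

## Normalisation

**Prevalence filter.** Features with a nonzero count in fewer than
`min_samples` (default 20) samples are removed. The boundary is
inclusive. Rationale: correlations estimated from a handful of nonzero
observations are leverage-dominated; the filter also sets the
background for enrichment and baselines.

**CSS-log2.** For sample *j* and quantile level *l* (default 0.5), the
scale factor is s_j = Σ{x_ij : x_ij ≤ q_j(l)}, where q_j(l) is the
linear-interpolation quantile of the sample's *positive* counts —
computing the quantile over all counts would collapse it to zero in
sparse tables. Values are x_ij / s_j × 1000, then log2(x+1), so zero
counts map exactly to zero and columns that are scalar multiples of
each other normalise identically. The scaling constant 1000 is a
conventional choice that keeps values count-like; it and the quantile
level are recorded in the transform metadata. An `adaptive` mode picks
the smallest grid level at which the median scale factor becomes
unstable (relative change > 0.1 between adjacent grid points),
mimicking data-driven quantile selection; the fixed median is the
default because it is explicit and stable on the table sizes used
here.

**CLR.** Natural log of (count + 1) minus the per-sample mean log.
The pseudocount of 1 mirrors the CSS-log2 step so the two transforms
are comparable. Sample columns sum to zero by construction.

**RV coefficient.** Escoufier's matrix correlation
tr(XXᵀYYᵀ)/√(tr((XXᵀ)²)·tr((YYᵀ)²)) on column-centred matrices. It is
reported in the pipeline as a check that the CSS-log2 and CLR sample
geometries agree (values > 0.95 on the default synthetic data); when
they do, downstream Pearson-correlation analysis is insensitive to the
choice.

## Diversity

Chao1 uses the bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)).
Bray–Curtis distances are computed on raw counts (normalisation is a
modelling choice deliberately kept out of the dissimilarity); family
aggregation is available via `aggregate_by_rank`. PCoA
eigendecomposes the Gower-centred −½JD²J matrix; negative eigenvalues
are reported but truncated (no Cailliez correction — the simplest
defensible convention, flagged in the result), and explained fractions
are relative to the positive-eigenvalue sum. PERMANOVA uses the
pseudo-F from total and within-group sums of squared distances and the
(1 + #{F_perm ≥ F_obs})/(1 + n_perm) p-value, which can never be zero;
permutations shuffle whole label vectors under a mandatory seed.

## PCIT

The Pearson matrix spans ASVs and phenotypes jointly (phenotype columns
are treated exactly like ASV columns; Pearson's scale invariance makes
standardisation immaterial). Complete-case samples are used rather
than pairwise-complete ones, since inconsistent pairwise estimates can
break the |r| ≤ 1 coherence the partial-correlation formulas rely on.

For every unordered trio, the three first-order partials and the
tolerance ε (mean ratio of partial to direct correlation, signed) are
computed; the comparison |r_xy| < |ε·r_xz| ∧ |r_xy| < |ε·r_yz| is on
magnitudes. An edge is retained only if no trio flags it. The
implementation vectorises over the conditioning node (O(n³) work in
O(n) array passes) and is tested to agree exactly with a literal
triple-loop reference on random matrices up to 12 nodes; the result is
independent of node ordering.

Degenerate trios — any ratio denominator (a direct correlation or a
√(1−r²) term) below 1e−12, e.g. duplicated features — are skipped
entirely and counted in the network object. No significance or
magnitude cutoff is applied beyond PCIT itself.

A geometric consequence worth knowing: ε is bounded near ⅔, so a
mediated pair can only be pruned when its mediator correlations are
below ≈ 0.58 (hence the pair's marginal correlation below ≈ ⅓).
Strongly mediated trios with very strong mediator links are retained
by construction. The `mediated_trio` fixture is sized accordingly
(r_xz ≈ r_yz ≈ 0.44, r_xy ≈ 0.22, partial ≈ 0.03). Removing nodes
from a network and re-running PCIT does not in general preserve the
retained status of the remaining edges, because the removed nodes may
have participated in flagging trios.

## Enrichment

For each family, the hypergeometric upper tail P(X ≥ x) of observing x
selected members given family size K, selection size n and background
N; reported score = −log10(p), so higher means more enriched, and only
families with x ≥ 2 are reported. ASVs without a family assignment
are excluded from both selection and background — pooling them into a
pseudo-family would manufacture enrichment out of classification
failure. No multiple-testing correction is applied to the scores; a
Benjamini–Hochberg column is emitted alongside as auxiliary output.

## Subset selection

Best-subsets OLS (intercept always included, predictors not
standardised — R² is invariant). The default engine is a
branch-and-bound search exploiting monotonicity of R² under predictor
inclusion: a branch is pruned when the R² of its full completion
cannot beat the incumbent at any reachable size. DFS visits subsets in
lexicographic order and incumbents are replaced only on strict
improvement, so ties resolve to the lexicographically smallest subset,
and the search provably reproduces exhaustive enumeration (tested on
50 random problems up to p = 12). Beyond `p_exhaustive_max` (default
20) a forward-greedy mode is used and flagged in the output; with
n ≈ 56 samples the R² path is near-saturated in that regime and the
greedy path is an explicit approximation, not a silent one.

The retention rule selects the smallest k with R²_k ≥ threshold ×
R²_full, threshold defaulting to 0.95; retention and reduction are
computed from unrounded values.

## Evaluation

Random baselines draw m ASVs without replacement from the full
prevalence-filtered pool (selected ASVs are *not* excluded by default;
exclusion is a flag) and refit OLS, ten draws by default.
Cross-validation uses a single seeded shuffle with round-robin fold
assignment (fold sizes differ by at most one); per fold, CV-R² is the
squared Pearson correlation between observed and predicted values in
the held-out fold — deliberately not 1 − SSE/SST, which differs out of
sample; a test enforces the distinction. A fold whose observed or
predicted values are constant yields an undefined CV-R², recorded as
missing and excluded from the mean with a warning.

The summary layer derives, per trait × dataset row: improvement of the
full and selected models over the random-baseline mean, retention
(100·R²_sel/R²_full) and reduction (100·(1 − N_sel/N_full)), plus
min/mean/max aggregates. Derived columns are recomputable from the
base columns to 10 decimals.

## Synthetic data

The generator emulates the target study design. Defaults: 56 samples,
350 ASVs, 25 families with Zipf-distributed membership (~5%
unclassified at family rank), Dirichlet(0.3) compositional base,
log-normal depths (median ≈ 20k reads), multinomial count sampling,
55% zero cells, three phenotypes rescaled to dairy-herd-like means and
SDs with a planted CH4Y–ACET:PROP correlation of 0.5, eight direct
ASVs per phenotype at a target |r| of 0.3 (the moderate range typical
of ASV–phenotype associations) and six mediated ASVs.

Key constructions:

* The spread of base log-abundances is solved by bisection so the
  expected multinomial zero fraction matches `sparsity_target` under
  the drawn depths, making sparsity a first-class dial.
* Effects are injected on the latent log-abundance scale *before*
  count sampling, so they survive the CSS-log2 transform. The latent
  effect is inflated by a fixed attenuation constant (0.86, measured
  once at n = 500 and frozen) that accounts for correlation loss
  through multinomial sampling and transformation; realised |r| at
  large n lands on the configured target.
* Direct ASVs are drawn from the prevalent, family-classified half of
  the table (effects planted on near-absent taxa would be unmeasurable
  at n = 56), with half of each phenotype's direct set taken from one
  designated family so enrichment recovery has ground truth.
* Mediated ASVs are noisy copies of a direct ASV's latent deviations
  (target latent correlation 0.65) with no independent phenotype term.

What the generator does **not** model: read-level artefacts (chimeras,
taxonomic mis-assignment), overdispersion beyond the log-normal latent
noise, phylogenetic correlation among ASVs, covariate structure (diet,
breed, week) and non-linear microbe–phenotype relationships. Passing
recovery tests therefore demonstrate the machinery is correct and well
calibrated under the stated generative model, not that real rumen data
will yield the same recall.

## Problem sizes and determinism

The validation suite runs the full design (56 × 350, a ~7 × 10⁶-trio
PCIT scan) in seconds per run; oracle comparisons use 50 random
instances up to 12 nodes/predictors, calibration checks use 200 null
PERMANOVA simulations, and recovery statistics average 10 generator
seeds — sizes chosen so the complete suite re-runs comfortably on one
CPU. All randomness flows from explicit seeds; pipeline stages derive
their seeds as a hash of the master seed and the stage name, so adding
a stage never perturbs earlier stages' draws, and identical configs
reproduce identical artifacts byte for byte.

## Limitations

* PCIT retains edges without any significance assessment; with n ≈ 56
  the retained 0.2–0.5 correlations include noise edges, which is why
  the random-baseline and CV layers exist.
* The retention rule optimises in-sample R²; the selected panel's
  honest performance is the CV-R², which is noisy at ~11-sample folds.
* CSS quantile level and scaling constant are conventions, not
  estimates; both are recorded in the transform metadata.
* Forward-greedy selection beyond 20 predictors is a heuristic and is
  flagged as such in the subset path output.
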