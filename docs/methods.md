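# Methods

This note records the statistical model, the numerical choices, what the
synthetic generator does and does not emulate, and the known limitations.
It states no number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Design and model

The data are a samples × lipid-features intensity matrix from an untargeted
LC-HRMS experiment over a balanced two-factor design: cell-line origin
(4 levels) × FOLFOXIRI-resistance status (2 levels: naïve, resistant), with
pooled-QC and blank injections interleaved. Both factors are fixed; the aim
is explanation of effect-linked variation, not classification of new
samples.

**ANOVA decomposition.** After unit-variance scaling, the centered matrix is
split into pure effect matrices by group means:
rows of `X_origin` hold (origin mean − grand mean), `X_resistance`
analogously, `X_interaction` holds (cell mean − origin mean − resistance
mean + grand mean), and `E` the within-cell residual. In a balanced design
these four blocks are exactly pairwise orthogonal, reconstruction is exact,
and the sum-of-squares shares (over the grand-mean-centered total) sum to 1;
`tests/test_anova.py` asserts all three properties against a brute-force
loop oracle. Balance is required by default; an opt-in `unbalanced='weighted'`
mode averages cell means with equal level weights (Type-III-like), an
extension beyond the balanced study design.

**Multiblock kernel-OPLS.** The four blocks (three effects + residual) each
contribute a kernel K_b = X_b X_bᵀ normalized by its Frobenius norm — so no
block dominates by scale — and the consensus kernel is their unweighted
mean; λ is a diagnostic, not a fitting weight. The residual is a block of
its own so that the orthogonal component can be read against it. With Y the
column-centered concatenation of level indicators (4 + 2 + 8 columns,
rank 7):

* *predictive components* are the dominant eigenvectors of K P_Y K, the
  consensus kernel projected through the design space. The default number
  equals rank(Y) = 7. Components are labeled tp1, tp2, … in decreasing order
  of explained data variance and attributed to the effect with the largest
  block contribution λ.
* *orthogonal components* maximize design-uncorrelated kernel variance,
  i.e. dominant eigenvectors of (I−P_Y) K (I−P_Y); each is deflated from
  the kernel before the predictive components are re-estimated.
* λ_{b,c} = t_cᵀ K_b t_c / Σ_b t_cᵀ K_b t_c (rows sum to 1 exactly; kernels
  are PSD so entries are non-negative).
* comp_var_c = ‖X_cᵀ t_c‖² / ‖X_c‖²_F, the component's share of the total
  centered (scaled) data variance; R²Y = ‖T_pᵀY‖²/‖Y‖² with orthonormal
  predictive scores.

A structural note on R²Y: because every effect kernel maps col(Y) into
itself and the residual kernel annihilates it, col(Y) is invariant under the
consensus kernel, and with the full 7 predictive components R²Y equals 1
identically; it is informative only when fewer components are requested.
The perfect-signal limit (noise-free single-factor data) yields R²Y = 1 and
λ = 1 on the matching block, which the tests assert.

**Eigen-extraction.** Components are extracted by power iteration with a
deterministic start (the first kernel column, or the largest-norm column if
that one is numerically zero), explicit re-orthogonalization against
previously extracted components, tolerance 1e-10 and at most 10⁴
iterations. Convergence is declared on the iterate *or* on the Rayleigh
quotient — the latter handles (near-)degenerate eigenvalues, where any
vector of the leading eigenspace is a valid component. If neither criterion
is met within the budget (this arises in a small fraction of permutation
refits with almost-tied eigenvalues), the component is taken from a dense
symmetric eigensolver instead of aborting the run; the result is still
deterministic. Component signs follow the convention that the
largest-|loading| feature loads positively (ties broken by lowest feature
index).

## Preprocessing

Order of operations: quality filters on the raw table, then PQN, then
imputation, then unit-variance scaling — the intensity/CV thresholds are
defined against raw QC intensities. Details:

* Missingness (rule a) is computed across biological samples only (QCs are
  pooled copies, blanks are solvent); a cell counts as missing when absent
  or ≤ 5 × the feature's mean blank signal. Features with no blank signal
  fall back to absolute missingness. This choice is recorded in the filter
  report.
* QC CV uses sd/mean with the n−1 denominator; non-detected QC cells enter
  as 0. IQR uses linear-interpolation quartiles over biological samples.
* Removal is by union of rules (a)–(d); the report attributes each removed
  feature to its first failing rule in that order.
* PQN reference = per-feature median over QC injections; a row needs ≥ 10
  evaluable quotients (positive reference, value present) or it is an
  error. All rows, including QCs and blanks, are corrected.
* Residual missingness is imputed with half the feature's minimum observed
  biological intensity — appropriate for detection-limit (left-censored)
  missingness, which is also what the generator produces. `method='none'`
  is available for complete data.

## Permutation validation

* **Effect significance.** The test statistic for an effect is its
  λ-weighted explained variance summed over the predictive components
  attributed to it — the same quantities through which the model is
  interpreted. The statistic choice is recorded in the output so
  alternatives (e.g. per-effect R²Y) can be swapped. Main-effect nulls
  permute that factor's labels *within strata of the other factor*, which
  preserves the tested null and keeps the design balanced; the interaction
  null permutes the joint cell-assignment vector. p = (1 + #{null ≥
  observed})/(1 + n_perm); with the default 10³ permutations the smallest
  attainable p is ≈ 10⁻³, and that empirical floor is what is reported.
  When the permutation space is no larger than n_perm, all distinct
  arrangements are enumerated exactly. Per-effect RNG streams are derived
  from the top-level seed and the effect name, so adding one effect never
  perturbs another's null.
* **Number of orthogonal components.** Component k is retained iff its
  captured share of data variance exceeds the 95th percentile of the same
  quantity after the residual matrix has been permuted independently within
  each feature column (then re-projected onto the within-cell complement
  with per-feature SS restored, so only inter-sample residual *structure*
  is destroyed, not residual magnitude). This dimensionality-style null
  leaves the effect blocks untouched; permuting design labels instead would
  leave a structured residual source in place under the null and could
  never detect it. Calibration on i.i.d. residuals (selection returns 0)
  and power on a planted source (returns 1) are both tested.

## Synthetic generator

The generator emulates: a balanced 4 × 2 design (default 6 replicates per
cell — the replicate count is a generator choice, not a claim about any
particular experiment), ~750 lipid features named by shorthand across the
study's sub-class vocabulary (carbons 30–60, double bonds 0–8, sphingolipid
;2O/;3O suffixes, ether O- prefixes), log-normal intensities (base level
e^N(ln 5e6, 1)), additive log-scale effects, per-sample log-normal dilution
(sd 0.2), five pooled QCs (5 % CV around the grand-mean profile), three
blanks at 10⁻³ of signal level, detection-limit censoring of 2 % of cells,
and a configurable subset of features whose blank level is high enough that
the 5×-blank rule removes them (default 3, reported in the truth object).

Ground-truth exactness: per feature, each component (origin, resistance,
interaction offsets; structured orthogonal trend; i.i.d. noise) is scaled to
its exact requested share of the sum of squares, so the planted fractions
are exact on the log scale. Three deliberate choices keep the truth
*recoverable and honest*:

* Effects live on the log scale and the table is exponentiated (MS
  intensities are multiplicative); with the default signal spread of 0.25
  log-units (≈ 25 % CV, a typical biological variation for cell-pellet
  lipidomics) the exp → PQN → UV-scale path is near-linear and shares are
  recovered within ~1–2 percentage points. Larger spreads degrade this
  transport and are the user's responsibility.
* Noise is fully isotropic in sample space (only the planted orthogonal
  trend is projected out of it, keeping that source's share exact). It
  therefore leaks the usual (levels−1)/(n−1) finite-sample bias into
  estimated group means; an earlier design that orthogonalized noise
  against all cell means made permutation nulls degenerate and was
  rejected.
* Censoring applies to the dilution-free intensity, so missingness does not
  itself inject dilution-correlated structure; the planted components
  remain the only structure present, which is what "known ground truth"
  must mean.

Origin-level offsets are drawn with anisotropic weights over three
orthonormal contrasts (default 0.68/0.255/0.065; axis 1 separates
{SW620, LS174T} from {DLD1, HCT116}), emulating a lipidome in which the
first two origin components dominate. The defaults plant effect fractions
of 58.4/7.8/18.1/15.7 % (origin/resistance/interaction/residual) and one
structured orthogonal source at 30 % of the residual — a regime in which
cell origin dominates, resistance is a small common shift, and exactly one
orthogonal component is supported.

What the generator does **not** emulate: chromatographic drift and
run-order effects, isotope/adduct structure, correlated lipid co-regulation
within pathways, heteroscedastic technical noise, and batch structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real acquisitions.

## Problem sizes used in the checks

The test suite and acceptance script size their simulations for a
single-CPU run: parameter-recovery at 200–750 features × 48 samples;
permutation calibration at 16 samples × 30 features over 50–200 seeds with
49–99 permutations; the end-to-end emulation and the acceptance script at
the full default 750 features × 48 samples with 10³ permutations per
effect. The parameter-recovery experiments use complete data
(missing_rate 0) so they isolate the estimator from imputation error; the
missing-data path is exercised separately by the default-condition runs.

## Known limitations

* The method is linear; nonlinear lipidome responses are summarized only
  through their linear projections.
* Balanced designs are assumed throughout the primary path; the weighted
  unbalanced mode is a pragmatic extension without the exact orthogonality
  guarantees.
* The interaction permutation null (joint cell relabeling) also disturbs
  main effects; with strong main effects it is approximate, as is standard
  for interaction permutation tests.
* Half-minimum imputation is appropriate for left-censored missingness
  only; data missing for other reasons will bias variance decompositions.
* With 10³ permutations, reported p-values cannot go below ≈ 10⁻³; claims
  of smaller p-values are outside what the machinery can support.
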