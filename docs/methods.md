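# Methods

`ginicca` implements a multivariate association analysis for cohorts of
binary clinical indicators, of the kind used to relate a set of
exposure/demographic risk-factor variables **X** (p variables) to a set of
symptom/clinical/diagnostic variables **Y** (q variables) in human
encephalitis: Gini-index covariance matrices for 0/1 data, canonical
correlation analysis (CCA), and permutation-based significance.

## Data model and dichotomization

A cohort is an n × (p+q) table over {0, 1, missing}; 1 codes presence of an
attribute (exposed, symptom present, test abnormal). Continuous variables
are dichotomized with explicit inclusive-threshold rules before analysis;
the conventions bundled with the package are age ≤ 10 years (young
children), duration of illness ≤ 100 days and hospital stay ≤ 50 days, each
coding the "short/young" side as 1. Descriptive summaries report
present/absent/missing percents against the full cohort size n (so the
three percents of a variable sum to 100), plus the presence rate among
subjects with an available measurement, because both conventions are common
in descriptive tables for cohorts with substantial diagnostic missingness.

## Gini covariance for binary variables

For categorical variables the variance/covariance is defined through
pairwise dissimilarities over all ordered subject pairs,

    Q_ij = 1/(2 m²) · Σ_a Σ_b (x_ia − x_ib) L (x_ja − x_jb),

with an orthogonal transformation L that reduces to the identity for binary
data (the only case supported; a non-identity `L` argument is rejected).
Expanding the double sum gives the closed form `(1/m) Σ x y − x̄ ȳ`: the
mean-centered product-moment covariance with **divisor m**, forced by the
1/(2m²) normalization. The diagonal is Gini's "likeability" variance,
p(1−p) for prevalence p. The implementation uses the closed form
(vectorized with presence masks); the explicit double sum is kept in the
test-suite as an independent oracle. Correlations follow as
R_ij = V_ij / √(V_ii V_jj).

**Missing data.** Each matrix entry is computed over the subjects complete
for that *pair* of variables (pairwise-available-case analysis), with the
pair's own complete-case count and means used in all terms of both V_ij and
R_ij — an internal-consistency choice the pairwise-deletion literature
leaves open; the per-pair complete counts are recorded alongside the
matrices. Pairs with fewer than 2 complete cases are an error. Pairwise
deletion can make the assembled matrix indefinite; repair is deferred to
the CCA step (below) so the association estimates themselves stay faithful
to the observed pairs. Zero-variance (constant) variables are flagged,
their correlation entries zeroed, and they are dropped from CCA with a
logged warning rather than failing the run.

## Canonical correlation analysis

With blocks S_xx, S_yy, S_xy, CCA maximizes
a'S_xy b / √(a'S_xx a · b'S_yy b) and is solved via the two eigenvalue
problems

    (S_xx⁻¹ S_xy S_yy⁻¹ S_yx − λI) a = 0,
    (S_yy⁻¹ S_yx S_xx⁻¹ S_xy − λI) b = 0,

whose shared eigenvalues λ_k = ρ_k² are the squared canonical correlations;
min(p, q) variate pairs are returned in descending order. Both problems are
solved and required to agree (tolerance 1e-8 internally; the test-suite
checks 1e-10 against a whitened-SVD oracle). Numerical choices:

- **PSD repair.** Each within-set block is symmetrized and its eigenvalues
  clipped to a floor of `1e-8 · trace/dim` before inversion; an optional
  ridge γ (default 0) can be added to the diagonals. Every adjustment is
  appended to a repair log that propagates into the run manifest.
  Eigenvalues are clipped into [0, 1] (logged when the excursion exceeds
  1e-8), since indefinite cross-blocks can push λ̂ marginally above 1.
- **Normalization.** Weights satisfy a'S_xx a = b'S_yy b = 1 (unit-variance
  variates).
- **Sign convention.** Each variate's sign is fixed so the X-side variable
  with the largest |loading| loads positively — a determinism choice, since
  CCA signs are otherwise arbitrary.
- **Tie-breaking.** Equal eigenvalues keep a stable order (descending λ,
  then original eigenvector order).

Derived quantities: loadings (structural coefficients) are correlations
between each variable and its own set's variate, computed as
(S_xx a)_i / √V_ii; cross-loadings use the opposite variate and obey
cross = ρ_k · loading exactly; "percent of variation contributed" is the
squared loading × 100, reported unrounded in CSV output and rounded to the
nearest integer by the convenience helper; redundancy of Y given X on
variate k is (mean squared Y-loading on k) · λ_k, bounded by λ_k. Subject
scores are U = X_c A, V = Y_c B on prevalence-centered data; a subject
missing any variable of a side gets a missing score on that side.

## Permutation inference

Binary data violate the multivariate normality behind parametric CCA tests,
so significance is nonparametric: whole Y-set rows (their missingness
pattern included) are permuted against the X rows — the standard
exchangeability-respecting scheme, which breaks between-set association
while preserving each set's internal dependence — and the pipeline is
re-run per permutation. Variates are tested with the sequential Wilks-type
statistic Λ_k = Π_{j≥k} (1 − λ_j), so variate k is judged jointly with all
later ones, and p-values use the add-one rule
(#{Λ_k^perm ≤ Λ_k^obs} + 1)/(n_perm + 1) — never exactly zero, and exact in
level for a valid permutation scheme. The default is 10,000 permutations;
tests use reduced counts. Replicates whose solve fails are dropped and
counted; more than 5% failures abort.

An exact optimization: S_xx, S_yy and all pairwise counts are invariant
under row permutation of one block (the same rows are present, only
re-paired), so only S_xy is recomputed per permutation against
once-factored within-set inverses. A test asserts equality with a full
from-scratch re-run, permutation by permutation.

Standard errors of ρ_k default to a subject bootstrap (resample subjects
with replacement, re-run the pipeline, SD across resamples), because the
spread of a null permutation distribution does not estimate an estimator's
sampling variability; that spread is nevertheless available via
`method="permutation"` for comparability with analyses that report it.
Degenerate resamples are re-drawn up to 10 times.

## Synthetic cohorts

No patient-level data ship with the package, so a latent-threshold
(Gaussian-copula) generator provides cohorts with the statistical structure
the analysis assumes. Each subject's latent vector is multivariate normal
with unit variances; variable i is coded 1 when its coordinate exceeds
Φ⁻¹(1 − prevalence_i), making marginal prevalences exact in expectation.
Within-set dependence is exchangeable with latent correlation
`within_noise` (default 0.1, a mild level consistent with the mostly weak
within-set correlations seen in such cohorts); between-set dependence is a
rank-one coupling `rho_latent · (S_xx^{1/2} u)(S_yy^{1/2} v)'` along unit
directions u, v (default uniform), which makes the *latent-scale* first
canonical correlation exactly `rho_latent`. Non-realizable structures fail
at spec construction via a Cholesky check. Missingness is applied MCAR per
variable.

Thresholding attenuates dependence (phi < latent correlation), so the
binary-scale first canonical correlation of generated data is well below
`rho_latent`; all calibration comparisons are therefore made on the binary
scale against a matched, independently-implemented estimation route, never
against `rho_latent` itself.

The `table2_preset` transcribes the marginal structure of a published
208-patient encephalitis cohort: 15 exposure/demographic and 24
symptom/clinical/diagnostic variables with prevalence = present-count/208
and missing rate = missing-count/208, following that table's
percent-of-cohort convention. Two consequences are documented rather than
hidden: (a) for high-missingness diagnostics (EEG missing 42.3%), the
preset's conditional-on-observed presence rate equals the percent-of-cohort
figure, whereas in the real study missingness was informative (tests were
ordered when likely abnormal), so the observed-only rate there was much
higher — the generator is MCAR by design and does not emulate that
mechanism; (b) the preset does not attempt to match the study's specific
within-set correlation pairs (e.g. the strong stay–duration correlation),
only an exchangeable level. The default `rho_latent = 0.8` yields a strong
binary-scale first canonical correlation at n = 208, comparable in
magnitude to the published headline association; it is a demonstration
default, not a claim of equality.

## What passing tests do and do not show

The acceptance suite verifies (a) printed-arithmetic conventions (squared
loadings as percent contributions, the ρ·loading cross-loading identity,
percent-of-cohort summaries), (b) exact oracle equivalences (Gini vs
centered product-moment covariance at 1e-12 on 100 random tables; CCA vs
whitened SVD at 1e-10 on 200 random configurations), and (c) operating
characteristics on synthetic cohorts: type-I error of the permutation test
within its binomial band (500 replicates × 200 permutations at n = 100,
p = q = 3), and monotone recovery of injected association at the preset's
margins with n = 10,000 and 6 replicates per route per grid point — sizes
chosen to give Monte-Carlo standard errors well below the effects being
checked. Because the generator is MCAR, exchangeable-within-set and
rank-one between sets, these results certify the pipeline's statistical
machinery, not the clinical conclusions of any particular cohort; with real
data, informative missingness and richer dependence can move estimates in
ways the synthetic checks do not probe.

## Known limitations

- Binary variables only; no multi-category Gini transformation (the
  general max-over-L optimization), no tetrachoric/polychoric option, and
  no imputation — pairwise deletion is the only missing-data mechanism.
- The first sample canonical correlation is an upward-biased
  max-singular-value statistic; at n ≈ 200 with 39 variables the bias is
  substantial. The permutation test accounts for this under the null, but
  reported ρ̂₁ values are not bias-corrected.
- No asymptotic (Bartlett/Rao) tests and no regularized/sparse or kernel
  CCA variants.
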