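# Methods

## Problem and data

Apparent solubility (S_app) in intestinal fluid combines ionization,
aggregation and solubilization by mixed taurocholate/lecithin aggregates.
The package works with log10 molar S_app in three media — blank phosphate
buffer pH 6.5 (PhB), FaSSIF and aspirated human intestinal fluid (HIF) —
for 86 lipophilic drugs (calculated logP > 2). FaSSIF is measured for all
86 compounds, PhB for 63 and HIF for 48; missingness is explicit and never
imputed at the dataset layer. The curation of the bundled table, including
the per-row assignment of ambiguous solubility columns, is documented in
`table1_curation.md`.

## Preprocessing

Descriptor matrices are processed in a fixed order: signed cube root,
normality screen, autoscale. The cube root (sign(x)|x|^(1/3)) compresses
heavy-tailed count- and volume-like descriptors while staying defined for
negative values. The normality screen is moment-based by default — a
column is dropped when |skewness| > 2 or |excess kurtosis| > 7 — because
moment screens are deterministic, scale-free and do not sharpen with n the
way formal tests do; a D'Agostino-Pearson test mode (alpha = 0.05) is
available. The screen is applied to the cube-rooted values: whether the
original workflow screened before or after transforming is not knowable,
and screening after is the choice that lets the transform do its job
before a column is condemned. Autoscaling uses the sample (n−1) standard
deviation, the chemometrics convention; columns with variance below 1e−12
are treated as constant and dropped. Descriptor names can be blinded
(bijective aliases) so that selection cannot be steered by recognizable
names.

## Latent engines

PLS1 is fitted by NIPALS with deflation of both blocks; for a single
response the inner loop is stationary after one pass, but the iteration
(tolerance 1e−12, cap 500) is retained so the fit is well defined in
general. Predictions use the closed-form coefficients
B = W(P'W)⁻¹q, and the package asserts (in tests) that the NIPALS path and
the coefficient path agree to 1e−10, with scikit-learn's PLS as an
independent cross-check. PCA is computed by SVD of the centered matrix.
Both engines make the largest-magnitude loading entry of each component
positive, so reports are reproducible across platforms; all engines are
deterministic functions of their input order.

Cross-validation: "7 groups" is read as 7-fold CV with round-robin
(venetian-blind) fold assignment by observation index, configurable to
contiguous blocks. Q²(a) = 1 − PRESS(a)/SS with SS about the full-data
mean; every observation is predicted exactly once by a model fitted
without its group. Components are accepted while the incremental Q² gain
exceeds 0.01 (configurable); this threshold rule is a declared stand-in
for the original software's undocumented autofit.

VIP uses SSY_a = q_a² t_a't_a as the response variance captured by
component a; the normalization Σ VIP² = p holds by construction and is
asserted on every fitted model.

Outlier diagnostics: Hotelling T² in score space with the
A(n²−1)/(n(n−A)) F(A, n−A) limit, and DModX as the observation residual
standard deviation over the pooled training residual standard deviation,
with degrees of freedom p−A per observation and (n−A−1)(p−A) pooled, so
that DModX² is approximately F-distributed and the 95% limit is
sqrt(F_0.95(p−A, (n−A−1)(p−A))). The DModX literature admits several
variants; this one is fixed and documented.

## Model-building protocol

- **Split.** Compounds are sorted by response, most soluble first (ties
  broken by name), and 1-based positions divisible by 3 go to the test
  set: 86 compounds give 28 test / 58 training before relocation. The
  anchor at position 3 (rather than 1) is what makes the 86-compound
  counts consistent with the published final 56/30 split after two
  relocations.
- **Relocation.** A PCA (2 components by default) is fitted on the
  training descriptors; training compounds above the 95% T² or DModX limit
  move to the test set, iterating at most 5 passes because the model
  changes after each move. Test compounds are never touched; every move is
  logged.
- **Truncation.** A preliminary PLS on all descriptors ranks them by VIP;
  only the top 100 are kept (boundary ties broken by name).
- **Greedy elimination.** Within each pass candidates are visited in
  ascending VIP order, recomputed once per pass; a candidate is
  permanently removed iff the model re-fitted without it — with the
  component count re-chosen — has a Q² at least as high as the current one
  (equality within 1e−6 to avoid float churn). Passes repeat until a full
  pass removes nothing. The deterministic VIP ordering replaces the
  human-in-the-loop of the original workflow, and components are re-chosen
  per trial, both declared choices.
- **Augmentation.** Measured PhB solubility, melting point and/or logD are
  appended as autoscaled extra descriptors. Compounds missing a requested
  value are excluded from that variant's training (mean-imputation exists
  but is off by default), mirroring the differing n of the published model
  variants. The augmentation is retained only if Q² improves, the same
  rule as elimination; a column nearly collinear with the response
  (|r| > 0.999) raises a leak flag.
- **Test-set R².** External-validation convention: residual sum of squares
  over the spread about the *training* mean, so a constant predictor at
  the training mean scores exactly 0.

## Correlation and consensus analyses

Inter-medium agreement is the squared Pearson correlation over complete
cases. Lipophilicity strata on predicted logD(pH 6.5) are half-open:
[−inf, 3), [3, 4), [4, inf); compounds exactly at a break belong to the
upper stratum. Strata with fewer than 3 pairs are reported as undefined
rather than raising. The consensus model is the unweighted arithmetic mean
of two predictors; by convexity RMSE_c ≤ sqrt((RMSE_A² + RMSE_B²)/2),
which the tests verify numerically on every evaluation. Residual reports
list compounds mis-predicted by ≥ 1 log10 unit, signed (positive =
over-predicted solubility), sorted by magnitude.

## Synthetic data

The generator emulates the *statistical* structure of the study — n ≈ 86
compounds, hundreds of collinear descriptors, a response spanning a few
log units, a discovery-like block shifted to lower solubility — not any
solubilization physics. X = T P' + E with k latent factors and unit
descriptor noise; y = T q + f with configurable noise (default 0.3 log10
units, a realistic inter-laboratory error for solubility data). Only
`n_informative` descriptors (default 5 of 300) carry loadings; their rows
have norm 1.2 and point along the response direction in latent space with
a random orthogonal tilt of 0.4. The alignment is a deliberate
identifiability choice: it makes the informative descriptors exchangeable
noisy views of the predictive signal, so that removing any one of them
measurably degrades Q² and support recovery is well posed. With generic
random rank-k loadings any k of the planted descriptors span the signal
and a Q²-monitored elimination correctly prunes the rest — recovery of the
full support would then be undefined rather than hard.

Skewed descriptors are exponentiated normals (to exercise the cube-root
transform and the normality screen); outliers are planted orthogonally to
the latent plane at a chosen multiple of the pooled residual standard
deviation so they are DModX-visible but score-invisible. The table-like
generator draws three media from a shared latent solubility with noise set
so adjacent media correlate at a configurable r² (default 0.7), clips to
the bundled dataset's range, and reproduces its per-medium missingness
rates. All randomness flows through `numpy.random.default_rng` (PCG64);
identical spec + seed gives identical data within this implementation —
cross-language reproducibility is not promised.

What passing synthetic tests do **not** show: that real descriptor sets
contain a low-dimensional, response-aligned signal, that real solubility
noise is homoscedastic Gaussian, or that the specific descriptors reported
for the published models would be re-selected — the published model
statistics depend on a proprietary descriptor matrix and are out of reach
(see limitations).

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery study at n = 80
compounds, p = 300 descriptors, 20 seeded replicates, chosen to match the
study's scale while keeping a full run in tens of seconds on one CPU.
NIPALS convergence 1e−12; constant-column tolerance 1e−12; Q² equality
tolerance 1e−6; all fold assignments and candidate orders deterministic.
Degenerate inputs (zero-variance response, all-constant matrices,
over-large component counts, empty media, fold counts exceeding n) raise
typed errors rather than propagating NaNs.

## Known limitations

- The published model summary statistics (R²/Q²/RMSE of the FaSSIF and
  HIF models) are not reproducible here: they require the proprietary
  descriptor values and a human-guided selection. The package reproduces
  the protocol, not those numbers, and asserts engine-level guarantees
  instead.
- The inter-medium correlation figures printed in the source publication
  are not recovered exactly from the printed 86-compound table under any
  reading of the ambiguous rows (details in `table1_curation.md`); the
  package reports the values the curated table actually yields.
- The greedy elimination keeps descriptors whose chance correlation with
  the response predicts held-out folds; at n ≈ 80, p ≈ 100 the final
  models typically retain 25–55 descriptors, more than a human analyst
  reading loading plots would keep.
- No OPLS, kernel PLS, or missing-value-tolerant NIPALS; consensus
  partners must be supplied as prediction files (the commercial neural
  network model is out of scope).
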