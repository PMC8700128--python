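# Methods

## Purpose and design

`connbench` measures how well common connectivity estimators distinguish
*contemporaneous* (same-time) association from *lagged* (causal, in the
Granger sense) influence when neither the dependence structure nor the noise
is Gaussian-friendly. Because the ground truth of real systems is unknown,
the benchmark is built on three synthetic five-variate systems whose
structure is known by construction, and every measure is scored by the
percentage of realizations in which it declares each link significant.

## The three systems

All systems are five-variate with mutually independent noise streams; one
realization is `n` points (default 2000) after burn-in.

**S1 — contemporaneous only.** Each time point is an independent draw:

    x1 = e1                e1 ~ Exponential(rate 2)
    x2 = e2                e2 ~ chi-square(1)
    x3 = 0.8 x2 + e3
    x4 = 0.7 x1 (x1^2 - 1) exp(-x1^2/2) + e4
    x5 = 0.3 x2 + 0.05 x2^2 + e5        e3,e4,e5 ~ N(0,1)

Truth: undirected pairs X2–X3 (linear), X1–X4 and X2–X5 (nonlinear); no
lagged edges. Any "causal" detection here is a false positive.

**S2 — lagged only.** A nonlinear VAR of order 3:

    x1_t = 0.7 x1_{t-1} + e1
    x2_t = 0.3 x1_{t-2}^2 + e2
    x3_t = 0.4 x1_{t-3} - 0.3 x3_{t-2} + e3
    x4_t = 0.7 x4_{t-1} - 0.3 x5_{t-1} exp(-x5_{t-1}^2/2) + e4
    x5_t = 0.5 x4_{t-1} + 0.2 x5_{t-2} + e5

with e1, e5 standard normal, e2 ~ Exponential(rate 2), e3 ~ Beta(1,2),
e4 ~ Beta(2,1). Truth: X1→X2 (nonlinear), X1→X3, X4→X5 (linear), X5→X4
(nonlinear); no contemporaneous pairs. Any correlation detection reflects
lagged coupling leaking into same-time association.

**S3 — both.** Lag and zero-lag dependence together:

    x1_t = 0.6 x1_{t-2} + e1
    x2_t = x1_t + 0.3 x2_{t-1} + e2
    x3_t = 0.3 x3_{t-1} + sin(x2_{t-3}) + e3
    x4_t = 0.4 x3_{t-2} + e4
    x5_t = -3.2 + 0.5 x3_{t-1}^2 + e5

with e1, e4 standard normal, e2, e3 ~ Beta(1,2), e5 ~ Gamma(shape 16,
scale 0.25). Truth: contemporaneous X1–X2; lagged X2→X3, X3→X4, X3→X5.
Substituting the x1 equation into x2 also implies a lagged X1→X2 relation
at lag 2, which the truth network flags separately as *equation-implied*:
a directed measure reporting X1→X2 is not wrong.

### Noise conventions

* The exponential parameter is a **rate**: rate 2 means mean 0.5.
* The gamma second parameter is treated as a **scale** (mean
  16·0.25 = 4, variance 1). Read as a rate it would give variance 256,
  which would bury the 0.5·x3² signal driving X5 and make the X3→X5 link
  undetectable — inconsistent with the intended design of S3. A
  `gamma_b_is_rate` switch restores the rate reading, and the convention in
  force is recorded in each panel's metadata.
* Burn-in: 1000 points for S2/S3 (transients decay far faster; the largest
  lag is 3). S1 is i.i.d. over time and needs none. Lagged values are
  zero-initialized before burn-in.
* Seeding: realization r uses seed `base_seed + r`; the five noise streams
  are independent `SeedSequence` substreams, so panels are bit-reproducible.

## Measures and their settings

Defaults follow one fixed configuration applied to all systems: alpha 0.05,
k = 10 neighbors for every KNN estimator, 100 permutations/surrogates,
Lmax = tau_max = 4, 256 frequencies, VAR order P = 1 for S1 and 3 for
S2/S3.

**Symmetric (correlation) measures** — each unordered pair, conditioning on
the three remaining variables (MI is bivariate):

* *PPCor* — partial Pearson correlation, computed as the correlation of OLS
  residuals after regressing each member on the conditioning set (for one
  conditioner this is algebraically the textbook formula). Student-t test
  with n−2 degrees of freedom; a `strict_df` switch subtracts the
  conditioning dimension too (immaterial at n = 2000).
* *PSpCor* — the same on columns replaced by average ranks.
* *pdCor* — partial distance correlation on U-centered (bias-corrected)
  distance matrices, projecting the matrices of Xi and Xj onto the
  orthogonal complement of the conditioning matrix in the inner-product
  space of U-centered matrices; multivariate conditioning stacks the
  columns with Euclidean distances. Plain double centering is available
  behind a flag for cross-checks. Significance by one-sided permutation;
  because centering commutes with relabeling the sample, permutations
  re-index one precomputed centered matrix rather than recomputing it.
* *MI* — Kraskov-type k-nearest-neighbor estimator (type 1, max norm) in
  nats. Ties are broken with a deterministic jitter of amplitude 1e-10
  times each column's standard deviation, seeded from the panel. One-sided
  permutation test, whole-series i.i.d. shuffles of one series, add-one
  p-value (1 + #{null ≥ obs})/(1 + B).

The i.i.d. permutation null deliberately destroys autocorrelation; under
lagged dependence this inflates correlation detections, which is one of the
effects the benchmark quantifies.

**Directed (causality) measures** — every ordered pair:

* *CGCI* — conditional Granger causality index ln(S_R²/S_U²), the
  log-ratio of restricted (driver's lags omitted) to unrestricted residual
  variances of per-equation OLS VAR fits with intercepts, both fits aligned
  on the same rows; nested F test with P restrictions.
* *RCGCI* — CGCI on a sparse term set: greedy stepwise BIC selection over
  all (variable, lag ≤ Lmax) candidates per target, ties broken toward the
  more recent lag, stopping when no candidate lowers the BIC; the F test
  then has as many restrictions as selected driver terms. A driver with no
  selected terms scores exactly 0, not significant. (A stricter
  "unlock lag ℓ+1 only after selecting lag ℓ" discipline was tried and
  rejected: it cannot select a lag-2 term whose lag-1 counterpart is
  uninformative, as happens for S3's X1, whose autocorrelation vanishes at
  odd lags.)
* *PDC* — partial directed coherence from the same VAR:
  PDC_{j→i}(f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²) with
  Ā(f) = I − Σ_r A_r e^{−i2πfr}, evaluated at 256 frequencies in [0, 0.5];
  the squared values in each source column sum to 1 at every frequency.
  A no-square-root denominator variant exists behind a flag. Point-wise
  significance compares |Ā_ij(f)|² with the asymptotic chi-squared(1)
  threshold scaled by the target equation's residual variance and the
  inverse covariance of the stacked lagged regressors; the reported scalar
  per ordered pair is the fraction of significant (frequency, realization)
  pairs. The threshold's variance factor was validated against the
  empirical sampling spread of the VAR coefficients. An unstable fitted
  VAR triggers a warning but values are still returned.
* *PTENUE* — partial transfer entropy on a non-uniform embedding (below),
  lagged candidates only, termination level 0.01; the statistic is the raw
  CMI of the driver's selected terms given the rest of the embedding.

**Instantaneous measures** — contemporaneous and lagged output per pair:

* *PMIME0* — the mixed-embedding measure with zero-lag candidate terms
  (termination level 0.05). Per ordered pair it reports two normalized
  ratios: the driver's lagged contribution
  I(x_{t+1}; w_j^{lag} | w \ w_j^{lag}) / I(x_{t+1}; w) and the analogous
  contribution of the driver's zero-lag term. A ratio is exactly zero when
  no corresponding term was selected; positive means significant (the
  surrogate test is built into selection). If I(x_{t+1}; w) is nonpositive
  for a nonempty embedding, both ratios are reported 0 with a warning.
* *PCMCI+* — two-phase constraint-based discovery (see below).

### Mixed-embedding construction

For a target Xi, candidates are all (variable, lag) terms with lag 1..Lmax
(plus zero-lag terms of the other variables in PMIME0 mode, "zero lag"
meaning simultaneous with the predicted sample; a config switch moves it
one step earlier). Greedily, the candidate with maximal CMI given the
already-selected terms (Kraskov-type conditional estimator, k = 10) is
accepted iff its CMI exceeds the 95th (99th for PTENUE) percentile of CMIs
recomputed with the candidate column replaced by 100 random circular
time-shifts (minimum shift 20 — shifts preserve the candidate's marginal
and autocorrelation while breaking its alignment with the target);
selection stops at the first rejection. The embedding is built once per
target and shared across drivers.

Because each step tests the *maximum* over ~20 candidate CMIs against a
single-candidate null, the stopping rule admits spurious terms well above
the nominal level. This inflation is an intrinsic property of the published
selection scheme, and it is visible in the benchmark output as PMIME0
lagged false-positive percentages above 5% on S1 — reproducing, not
masking, that behavior is intended.

### PCMCI+ procedure

Phase 1 prunes, per target, all lagged candidates (lag 1..tau_max) by
iterated conditional-independence tests given the q strongest surviving
candidates, q increasing until stable (level `pc_alpha`, default = alpha).
Phase 2 re-tests every surviving lagged link conditioning on the discovered
parents of both endpoints, and tests every variable pair at lag zero given
both endpoints' lagged parents. Contemporaneous edges are oriented by
collider detection over unshielded triples with the majority rule across
conditioning subsets of common neighbors; conflicted or undecidable links
stay unoriented and are *scored in both directions* when the harness fills
percentage tables. Two CI tests are provided: `parcorr` (partial
correlation, t test) and `cmi-knn` (KNN CMI with a local-permutation null:
the tested variable is shuffled only among each point's k_perm = 5 nearest
neighbors in the conditioning space, 100 permutations). This is a
re-implementation from the procedure's published description; the exact
published algorithm has additional refinements (e.g. sepset bookkeeping
across phases) that are out of scope here.

Exact-graph recovery is a family-wise property: with m absent links each
tested at level a, the probability of recovering the oracle graph exactly
is at most (1−a)^m even for a perfectly calibrated test. The consistency
check on 3-node linear-Gaussian systems therefore runs at a strict
per-link level (0.001) where recovery is essentially exact at n = 2000,
while per-link calibration at the nominal 0.05 is verified separately.
The benchmark sweeps themselves always use the nominal level.

## Harness

`run_benchmark` generates R realizations per system (seed base+r), feeds
the *same* panels to every measure, and aggregates percentages of
significant links: upper-triangular matrices for symmetric measures, full
off-diagonal matrices for directed ones (rows drive the columns), and a
contemporaneous/causal pair for the instantaneous ones. PDC cells average
the significant-frequency fraction, so they aggregate over (frequency,
realization) pairs. Per-realization results can be cached as JSON, making
sweeps resumable and byte-stable; a measure failing on one realization is
logged, recorded as missing, and the affected cells use the reduced
denominator. `score` compares a table against the truth network at a
percentage threshold (sensitivity and false-positive rate, contemporaneous
and lagged separately, equation-implied edges counting as true).

## Numerical choices

* OLS via `numpy.linalg.lstsq`; rank deficiency raises with the offending
  columns named rather than silently pseudo-inverting.
* Nested fits share sample rows (alignment on the largest lag involved) so
  restricted SSE ≥ unrestricted SSE holds exactly; tiny negative
  differences from rounding are clipped at zero before the F statistic.
* KSG counting uses strict inequality at the k-th neighbor radius
  (`nextafter` down); the deterministic jitter makes exact ties
  measure-zero.
* Average ranks on ties for Spearman.
* Permutation p-values use the add-one rule, so p ∈ (0, 1] and a test with
  B resamples can never report p below 1/(B+1).
* Saturated correlations (|r| = 1) report p = 0 with an explicit flag.

## Test-suite study sizes

The fast measures (PPCor, PSpCor, CGCI, RCGCI, PDC, MI on a single pair)
are verified at the full study size: 100 realizations of n = 2000. The
KNN-embedding measures cost minutes per realization (each greedy step
evaluates ~120 conditional MI estimates on n ≈ 2000 points), so their
checks run as reduced sweeps over the saturated (100%) and empty cells:
R = 5 realizations with targets restricted to the equations involved, and
R = 3 for the S3 contemporaneous check. PCMCI+ with the cmi-knn test is
likewise verified on reduced panels (n = 500, 50 local permutations) next
to full-size runs with the parcorr test. These reduced checks establish
that the implementations reproduce the saturated and empty cells of the
benchmark; the intermediate percentages of the KNN-heavy measures are only
pinned down by the full sweeps via `run_benchmark`.

## What the generator does and does not emulate

The synthetic systems provide known truth, heavy-tailed and skewed noise,
nonlinearity, and feedback loops — the failure modes the measures are
meant to be tested against. They do not emulate long memory, volatility
clustering, measurement noise, missing data, nonstationarity, or latent
confounders; a measure passing this benchmark can still fail on real data
exhibiting those features.

## Known limitations

* The exact parametric PDC significance procedure used in comparable
  published tables is not standardized; the chi-squared point-wise test
  implemented here is calibrated (validated on S1 and against the
  empirical coefficient sampling distribution) but other thresholds in
  circulation can behave very differently on collinear, small-variance
  regressor columns such as S2's X4, yielding much higher spurious-link
  percentages for that source column.
* Detection percentages for weak nonlinear links (S1's X1–X4, S2's X1→X2)
  are extremely sensitive to the noise-distribution conventions
  (rate-vs-scale/mean parameterizations, standardization); the conventions
  used here are stated above and recorded in panel metadata.
* PMIME0's stopping rule is implemented as a per-step surrogate
  significance test; implementations using a ratio-threshold termination
  will select systematically different embedding sizes.
* PCMCI+ is a faithful-in-structure but simplified re-implementation; see
  above.
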