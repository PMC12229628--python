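# Methods

This note documents the statistical model behind `idionet`, the conventions
and defaults it adopts where the underlying methodology leaves choices open,
what the synthetic-data generator does and does not emulate, and the
numerical decisions that affect results.

## Model and estimand

Each participant's diary is a day × item table of ordinal scores. Treating
days as exchangeable draws, the analysis models the items as a Gaussian
graphical model (GGM): the estimand for participant *p* is the matrix of
partial correlations

w_ij = −Ω_ij / √(Ω_ii Ω_jj),  Ω = R⁻¹,

where R is the Pearson correlation matrix of the participant's
(reverse-coded) scores. No shrinkage or sparsity penalty is applied: the
estimate is the plain inverse of R ("non-regularized"), so every edge keeps
its estimated weight and sampling noise shows up as many small edges rather
than a sparsified graph. A singular R is an error, never a silent
regularization; an explicit `ridge` parameter (default 0) is available and
recorded in provenance when used.

Assumptions worth stating plainly: days are treated as independent and
identically distributed within participant (no time-series structure is
modelled); the ordinal 1–7 scores are correlated as if interval-scaled
(Pearson by default, Spearman available; polychoric out of scope); and
within-participant stationarity over the whole observation period.

## Preprocessing conventions

- **Reverse-coding.** Positively valenced items (*cheerful*, *relaxed*, *in
  control* in the default 14-item schema) are reflected,
  s ↦ scale_min + scale_max − s, so high always means severe. The map is an
  involution and preserves missingness and marginal variance.
- **Exclusion.** Participants with fewer than 100 diary days (strict: 100
  exactly is retained) or with fewer than 2 distinct observed values on
  *every* item are dropped, with a per-participant reasons report. The
  variation rule operationalises what is, in practice, a manual judgement
  about stereotyped responding; a manual override list exists for exactly
  that reason.
- **Redundancy.** On pooled reverse-coded data across retained participants,
  each item pair with |r| ≥ 0.50 is tested: for every third item C, the
  dependent overlapping correlations r(A,C) vs r(B,C) are compared with the
  back-transformed-z test (Fisher-z difference standardised by the
  Dunn–Clark covariance evaluated at the back-transformed mean z). If fewer
  than 25% of those comparisons are significant at p < 0.05 the pair is
  flagged as redundant and the lower-variance member is removed (ties keep
  the lexicographically first item; per-pair overrides available). The
  0.50 / 0.05 / 0.25 defaults follow the convention published with this
  procedure in the network-psychometrics literature; they are conventions,
  not estimates, and are all exposed in config. Pooling (rather than
  per-participant testing) matches the single global item-removal decision
  the pipeline makes.
- **Missing data.** Missing days are absent rows; missing single items are
  explicit NaNs. Correlation uses listwise deletion by default (drops any
  day with a missing item), which keeps R positive semi-definite; pairwise
  deletion is available but can require a ridge.

## Graph metrics

Edge lengths are ℓ_ij = 1/|w_ij| (absent edge ⇒ no direct connection), so
stronger conditional associations mean shorter paths. Absolute values are
used both here and in strength because the verbal definitions of these
indices do not address negative partial correlations; the absolute-value
convention is standard for weighted psychological networks and is what the
code does wherever "sum of edge weights" would otherwise be ambiguous.

- Shortest paths: Dijkstra per source (scipy's csgraph implementation).
- Betweenness: Brandes accumulation, written in-package so that geodesic
  ties can be detected with *relative tolerance 1e-9* and credit split
  fractionally; exact-comparison implementations break such ties
  arbitrarily. (Ties are measure-zero for continuous weights but occur for
  hand-built and degenerate networks.) Equality with both a brute-force
  path-enumeration oracle and networkx's implementation is enforced in the
  test suite.
- Disconnection conventions, all logged as warnings: closeness is 0 for a
  node with any unreachable partner; ASPL averages finite pairs only, with
  the reachable-pair fraction reported alongside; global efficiency counts
  unreachable pairs as 0 (1/∞). A network with no finite pair has ASPL NaN
  and efficiency 0.
- Closeness is reported raw; any ×10² rescaling for display is a
  presentation choice, not applied in outputs.

## Variability and dispersion

Per item: sample SD (denominator n−1) and RMSSD, the root mean square of
successive differences taken only over calendar-adjacent day pairs with both
days observed — a gap of any length breaks the run and contributes no pair,
because a "successive difference" spanning an unobserved week is not
day-to-day variability. An item with no adjacent pair gets a missing marker,
not 0. Both are computed on reverse-coded scores, so they are invariant to
item valence. Inter-individual dispersion is the sample SD (n−1) of each
centrality index per item across participants; it requires all profiles to
share one item set, i.e. it must be computed after the global redundancy
removal.

## Group comparison

Every item × index × {raw, rank} combination, every item × {SD, RMSSD}, and
the two network-level density metrics are compared between relapse groups
with a Welch two-sample t-test (Student available by config — Welch is the
default because equal group variances are not plausible a priori) and a
Wilcoxon rank-sum test, both two-sided. The rank-sum p-value is exact by
enumeration when the combined sample is ≤ 20 without ties, otherwise the
tie- and continuity-corrected normal approximation. Rank indices rank items
within participant (1 = most central, average ranks for ties), isolating
relative from absolute centrality. Benjamini–Hochberg step-up adjustment is
applied at q = 0.10 within families; the default family structure is one
family per index × {raw, rank} block plus one for variability and one for
density (a single global family is available by flag, and the choice is
logged) — the family structure is a genuine analysis choice, so it is config,
never hard-coded. Both test types' p-values are adjusted within the same
families and reported side by side.

## Synthetic cohort generator

The generator is the package's substitute for a non-public clinical cohort
and defines the conditions under which the pipeline is validated:

- **Truth.** A shared sparse template of partial correlations: each of the
  m(m−1)/2 pairs is an edge with probability `base_edge_density` (default
  0.25), magnitudes uniform on [0.1, 0.35], negative with probability 0.1
  (symptom networks are predominantly positive after reverse-coding).
  Participant truths add N(0, heterogeneity) to each nonzero template edge
  (heterogeneity 0 ⇒ identical networks); relapsers' off-diagonals are then
  multiplied by the density factor δ (δ = 1 is the hysteresis null). The
  template is projected up front so that its δ-scaled version is already a
  valid (positive-definite) precision matrix — otherwise the per-participant
  repair could shrink relapse-group truths below the template and silently
  invert the configured density contrast. Per-participant positive-definite
  repair (uniform off-diagonal shrinkage in 0.95 steps, factor logged,
  failure below 0.5 is an error) remains as a safety net for heterogeneity
  draws; shrinkage rather than rejection sampling keeps generation a pure
  function of (config, seed).
- **Diaries.** Daily latent vectors from the truth's correlation matrix,
  optionally a stationary AR(1) with coefficient `ar_phi` (default 0, the
  estimator's exchangeability assumption; nonzero values exist to study its
  violation), discretised to 1–7 through an ordinal-probit threshold
  mechanism (default: equiprobable bins, the simplest model consistent with
  correlating ordinal scores). Whole days are dropped independently with
  `p_missing_day` (default 0.1). Day counts per participant are truncated
  Normal(265.3, 114.3) on [100, 365], mirroring a one-year observational
  cohort of 30 participants with 12 relapsers; `days_sd = 0` gives fixed
  counts for controlled experiments.
- **Planted duplicate.** Optionally appends a latent copy of the first item
  plus N(0, 0.1) noise for redundancy-detection validation.
- Generated items are all on the severity scale (no positively valenced
  items), so estimated networks compare against stored truths without a
  valence flip; reverse-coding is exercised by the real 14-item schema.

What the generator does **not** emulate: within-day sampling-time effects,
relapse-onset dynamics (labels are static over the whole period), item-level
(as opposed to day-level) missingness, floor/ceiling response styles, and
non-Gaussian latent dependence. Passing recovery tests therefore show the
pipeline is correct *under its own assumptions* — they do not certify those
assumptions for real diaries, where discretisation coarseness, drift, and
informative missingness can add bias the simulations do not represent.
Discretisation to 7 levels attenuates correlations mildly; the recovery
criteria (edge RMSE < 0.07 at T = 10,000, sign agreement ≥ 95% for edges
with |true partial| ≥ 0.15) deliberately allow for that attenuation.

## Numerical choices

- Condition-number guard at 1e12 before inverting R; the error names the
  most collinear item pair and suggests a ridge or item removal.
- Geodesic-tie tolerance: `math.isclose(…, rel_tol=1e-9)`.
- Degenerate two-sample input (zero variance in both groups, equal means)
  is t = 0, p = 1 by convention.
- NaN p-values (e.g. RMSSD undefined for a group) pass through BH
  unadjusted and uncounted.
- Edge-list CSVs store each unordered pair once (node_i < node_j
  lexicographically), omit zeros and the diagonal, and format weights with
  17 significant digits so read-back is bit-exact.
- All simulation entry points take a single integer seed; every random
  draw derives from `numpy.random.default_rng(seed)` in a fixed order, so
  outputs are bit-reproducible. Pipeline runs additionally record a config
  hash and per-file SHA-256 digests.

## Simulation sizes

The validation suite uses: 100 random graphs (≤ 6 nodes) for the metric
oracles; 1,000 random 3×3 matrices for the dual-oracle partial-correlation
check; 20 seeds × T ∈ {200; 1,000; 10,000} days for recovery; 20 seeds × a
3-point heterogeneity grid (0, 0.075, 0.15) with 10 participants × 1,000
days for dispersion; 50 seeds of the default 30-participant cohort for null
FDR calibration; 50 seeds × 30 participants × 2,000 days at δ = 1.5 for the
density-direction power check; and 20 seeds for planted-duplicate recovery.
These sizes give stable Monte-Carlo estimates while keeping the full suite
in the minutes range on a single CPU.

## Known limitations

- Pearson on 7-point ordinal data underestimates latent associations;
  Spearman is available, polychoric is not.
- Whole-period networks assume stationarity; acute relapse dynamics are
  averaged out by construction (a time-resolved or lag-1 VAR extension is
  explicitly out of scope).
- The exact-vs-approximate rank-sum switch (combined n ≤ 20, tie-free)
  means p-values for tied small samples use the normal approximation.
- With 13 items and ~200–300 complete days, per-participant networks carry
  substantial sampling error (edge SE ≈ 0.06); inter-individual dispersion
  estimates therefore include a sampling-noise floor, which is why the
  heterogeneity validation checks *ordering* against ground truth rather
  than absolute dispersion levels.
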