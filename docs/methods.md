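# Methods

## Scope and model

The package implements the computational side of PAMPA membrane
characterization: turning raw donor/acceptor concentration reads into
effective permeabilities, fitting the Abraham solvation parameter model
to neutral-compound permeability data, and quantifying similarity
between systems (artificial membranes and biological barriers) through
the D′ distance over their LFER coefficients.

The solvation parameter model, log SP = c + eE + sS + aA + bB + vV,
assumes the property is a free-energy-related quantity of the *neutral*
solute and that the five descriptors capture the relevant solute–phase
interactions linearly. Descriptors are inputs throughout; nothing here
estimates them from structure.

## Permeability inversion

Retention, lag time and the permeability equation are as documented in
`permeability.py`. Assumptions worth making explicit:

- **Porosity placement.** ε_a scales the membrane area (effective area
  A·ε_a, in the denominator with A), i.e. porosity reduces the area
  available for flux.
- **Lag-time model.** t_ss = ((5/4)·RM + 1)·60 s: a 60 s base lag
  extended linearly by retention (retained mass delays steady state).
  The slope is a parameter of `lag_time` so an alternative lag model can
  be substituted without touching the permeability equations.
- **Gradient-pH iteration.** P_e(A→D) comes from the iso-pH companion
  well (directional permeabilities coincide without a gradient). The
  gradient equation is then iterated: r_a starts at r_v, each pass
  computes P_e(D→A) at the current r_a and refreshes
  r_a = r_v·P_e(A→D)/P_e(D→A). Convergence is declared on the relative
  change of successive P_e(D→A) values (default tolerance 1e-3, cap 100
  iterations); the convergence variable is the permeability, not r_a,
  since the permeability is the reported quantity. On the tested
  asymmetry range (ratios 0.2–5) the fixed point is reached in under 20
  iterations.
- **Degenerate records.** A log argument ≤ 0 means the well is at or
  past its equilibrium plateau and P_e is not identifiable — rejected
  with a dedicated error, as is an incubation shorter than the lag time.
  Slightly negative retention (|RM| < 0.02) is clamped to 0 with a
  warning (measurement noise); anything more negative is a mass-balance
  violation and is rejected.
- **`forward_simulate`** is the exact algebraic inverse of the chain
  (C_D(t)/C_D(0) = (1−RM)(r + 10^(−k))/(1+r) with
  k = P_e·A·ε_a·(t−t_ss)·(1+r)/(2.303·V_D), acceptor concentration from
  the retention mass balance). It is the independent oracle for all
  inversion tests: the iso-pH round trip holds to 1e-10 relative over
  P_e ∈ [1e-8, 1e-4] cm/s and RM ∈ [0, 0.8].

Default geometry: V_D = 0.18 cm³, V_A = 0.20 cm³ (a stirring bar
occupies 20 µL of the nominal 200 µL donor), A = 0.3 cm², ε_a = 0.76;
default incubation 4 h. All permeabilities are cm/s, logs are log₁₀.

## LFER fitting

- **Neutrality filter.** Ionized fractions from Henderson–Hasselbalch
  (acid: 1/(1+10^(pKa−pH)); base: 1/(1+10^(pH−pKa))); multiprotic
  compounds take the worst (maximum) site, the conservative choice when
  the handling of multiple sites is not otherwise specified. Default
  exclusion threshold 0.02, configurable. Compounds without pKa data are
  retained as neutral but listed in the exclusion report so the
  assumption is auditable.
- **Regression.** Plain OLS on [1, E, S, A, B, V] — no weights, no
  standardization, no outlier handling (statsmodels OLS under the hood;
  tests cross-check coefficients and standard errors against a direct
  normal-equations solution). Residual df is N−6, so
  SD = √(RSS/(N−6)) is the residual standard error and
  F = (R²/5)/((1−R²)/(N−6)); this df convention is the only one that
  reproduces the published F values from their (R², N) pairs.
  Per-coefficient significance is a two-sided t-test at 95%. Rank
  deficiency is reported with the dependent column named; N < 7 is
  rejected outright.

## Similarity analytics

- **D′** is the Euclidean norm over (e, s, a, b, v); the intercept never
  enters (it is excluded structurally — the distance is computed from a
  vector that does not contain c). Distances are kept at full precision
  internally; reports round to 2 decimals, the precision at which
  reference tables are printed. Literature zero coefficients are exact
  zeros, not missing values.
- **Clustering** is scipy agglomerative linkage on the condensed D′
  matrix, UPGMA (average) by default — the reference merge order (skin
  pair first below 1, then the hexadecane/DOPC pair) is reproduced by
  UPGMA; single and complete linkage are available. scipy's tie-break
  (lowest-index pair) makes trees deterministic. Dendrograms export as
  Newick with branch lengths from merge-height differences.
- **PCA** is an eigendecomposition of the covariance matrix of the
  centered, *unscaled* coefficient rows. Covariance (not correlation)
  PCA is deliberate: the published loading pattern is unit-norm and
  dominated by the high-variance coefficients a, b, v, the signature of
  unstandardized PCA — and hydrogen bonding plus hydrophobicity are
  precisely what separates membranes chemically. Eigenvector signs are
  fixed deterministically (largest-magnitude loading positive); printed
  loading signs are convention-dependent, so comparisons use magnitudes.
- **Emulation screen.** Every (biological, PAMPA) pair is flagged when
  D′ ≤ 1.0 (configurable). The screen pulls its numbers from the same
  `dprime_matrix` code path as every other analysis, so the flags can
  never drift from the distance matrix.

## Synthetic data

The generator produces data with the *shape* of the study inputs and
exactly known truth:

- descriptors: independent uniform draws over drug-like Abraham ranges
  (E ∈ [0,2], S ∈ [0,2.5], A ∈ [0,1.5], B ∈ [0,2], V ∈ [0.5,2.5]);
- log P_e: LFER prediction from a ground-truth coefficient set (default:
  the certramide-membrane equation, a realistic well-determined system)
  plus Gaussian residuals (default SD 0.15, a typical regression SD for
  this assay class; 45 compounds by default);
- concentration records: `forward_simulate` under the plate geometry,
  retention drawn from [0, 0.5], optional multiplicative log-normal
  noise on concentrations (CV-parameterized, mimicking chromatographic
  quantification error; default off for exact round trips);
- optional pKa assignment to a configurable fraction of compounds, with
  sites placed from clearly ionized to clearly neutral, so the
  neutrality filter is exercised.

Everything is a pure function of (config, seed) via per-stage
`numpy.random.Generator` substreams keyed on a CRC of the stage name.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: descriptor correlations (real Abraham
descriptors are correlated; an optional Cholesky knob exists but the
default is independence, for test clarity), non-Gaussian residuals,
pH-dependent permeability of partially ionized solutes, membrane
degradation, or solubility/aggregation artifacts. Recovery results on
synthetic data are statements about the estimator under the model, not
about assay accuracy.

## Numerical choices and problem sizes

- Gradient-solver tolerance 1e-3 (relative, on P_e(D→A)); iteration cap
  100; round-trip tests run at tighter tolerances to confirm the fixed
  point is the true value.
- Parameter-recovery checks use 45-compound datasets, residual SD 0.15,
  200 seeded replicates; coverage is pooled per-coefficient (the joint
  all-coefficients event has nominal coverage ≈ 0.76 for correlated
  estimates and is not the quantity of interest).
- The residual-SD sanity band in tests comes from the chi-square
  sampling distribution σ·√(χ²_df/df) at extreme quantiles, not from a
  rule of thumb.
- The reference similarity analysis (14 systems) runs in milliseconds;
  the full test suite in a few seconds.

## Known limitations

- The intercepts of the literature systems (3–14) are not in the
  packaged table; D′, clustering, PCA and the emulation screen never
  need them, but `predict_log_sp` for those systems requires the
  original sources.
- No unstirred-water-layer correction and no modelling of P_e vs pH for
  ionizable compounds; gradient-pH handling resolves directional
  asymmetry only.
- The published solute-level datasets behind the two skin-membrane
  regressions live in the article appendix and are not redistributed
  here; the fitting chain is validated on synthetic stand-ins with
  matched size and residual scale instead.
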