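# Methods

## The model under audit

The package evaluates a Lyman-type probit NTCP model for memory impairment
after partial-brain radiotherapy.  The predictor is D40% — the EQD2 dose
received by 40% of the bilateral hippocampal volume — and the response is

NTCP(D) = Φ((D − TD50)/(m·TD50)),

with defaults TD50 = 14.88 EQD2 Gy and m = 0.54 (the published hippocampal
parameterization, shipped as `GONDI_2013` and overridable everywhere).  The
CDF is evaluated with `scipy.special.ndtr` (error-function form, absolute
error well below 1e-12); the closed-form inverse uses `ndtri`.  Raw
probabilities are never truncated inside the package.  The two-decimal
display rule, with values above 0.99 rendered ">0.99", is presentation
only; Brier scoring against a table printed that way is done by explicitly
capping forecasts at 0.99 (`brier_score(..., cap=0.99)`).

Parameters are fixed inputs being audited; `fit()` estimates only the
recalibration line (observed incidence regressed on predicted risk).  No
refitting of TD50/m is attempted: with essentially all patients in the
high-dose range there is no information to refit from, and no volume-effect
/ generalized-EUD reduction is implemented because the published model is
defined directly on D40%.

## DVH conventions

Cumulative DVHs store "fraction of structure volume receiving ≥ dose",
with a grid starting at 0 Gy (fraction 1.0) and strictly increasing doses;
absolute-volume exports are normalised on read, and duplicate grid doses
are rejected rather than silently deduplicated, since they usually flag a
malformed export.

* **Interpolation.** Both Dx% extraction and bilateral compositing
  interpolate the cumulative curve linearly between grid points and treat
  it as 0 beyond the last point — standard planning-system practice.
  Probing a volume fraction below the curve's final value returns the last
  grid dose: extrapolating beyond delivered dose is meaningless.
* **Terminal atoms.** A curve ending above zero carries an atom of volume
  at its last grid dose.  When compositing two structures on their union
  grid, an extra breakpoint is inserted 1e-9·max-dose past such a terminal
  dose so linear interpolation preserves the jump instead of smearing the
  atom toward the partner structure's longer grid.  (This fix was caught
  by the pooled-voxel oracle test, which inverts each cumulative curve
  into 1e5 pseudo-voxels, pools them by volume and recompares.)
* **EQD2.** Conversion is per bin with the bin's own dose per fraction
  d = D/n: EQD2 = D(d + α/β)/(2 + α/β), α/β = 2 Gy by default for late CNS
  effects.  The map is strictly increasing, equals the identity exactly at
  2 Gy/fraction, and reduces (raises) doses delivered below (above)
  2 Gy/fraction.  Cohort D40% values can exceed the 47.88 EQD2 Gy
  prescription equivalent only via hotspot bins — which is what the
  fixture cohort shows.
* **Mean dose** integrates the differential of the cumulative curve with
  bin-midpoint doses plus the terminal atom; it is exactly invariant under
  linear grid refinement.

## Reliable-change scoring

Observed AVLT-dr change O (retest minus baseline, integer word counts
0–15) is compared with the normative expectation
E = 1.025 − 0.035·(age − 62.5) and standardized by the normative residual
SD 2.362; an event is Z < −1.5, strictly.  Two documented interpretation
choices: O is the *change* score, not the raw retest score (the norms
describe expected change, and a change-minus-expected-change residual is
the only scale-consistent reading), and age is age at baseline testing.
The norms come from a healthy-ageing study with a ~3-year test-retest
interval and an older age range; they are applied unadjusted to 18-month
intervals, as the validation study itself did — a known transportability
caveat, not a package option.

## Performance metrics

* **Brier score**: mean of (f − o)²; the no-skill reference for a cohort
  with event rate p is p(1 − p).
* **Calibration**: records sorted by ascending predicted risk (stable sort,
  so ties break by input order) and split into n_bins contiguous groups
  with sizes as equal as possible, remainder to the lowest-risk bins
  (29 → 10+10+9).  Per-bin observed incidence gets a 95% Wilson interval.
  The recalibration line is an unweighted OLS over the (mean predicted,
  observed incidence) points; r² is reported as NaN when the observed
  incidences are constant.
* **Median split**: records exactly at the median dose go to the low
  group; the two-sided Fisher exact p uses the point-probability rule
  (sum of conditional table probabilities ≤ that of the observed table),
  pinned for reproducibility.
* **Spearman matrix**: mid-rank ties; binary variables enter as 0/1;
  constant variables yield NaN (undefined), never 0.  No multiplicity
  correction is applied across the matrix.

The printed per-bin regression coefficients and median-split incidences of
the original analysis are not reproducible from the printed cohort under
any binning convention tried; the package computes its own values under
the documented conventions and does not treat the printed ones as ground
truth.  (The median-split Fisher p does reproduce at 0.68.)

## Exact Fisher power

Power at equal group size n for true incidences (p_low, p_high) is
computed by full enumeration: weight every outcome pair (k1, k2) by
Binom(n, p_low)·Binom(n, p_high) and sum the weights of pairs rejected at
α.  The default design (0.111 vs 0.667, two-sided α = 0.05, target 80%)
reaches the target at **n = 13 per group** (power 0.810), under both the
point-probability and the doubled-one-sided two-sided rules and with the
proportions taken either as printed or as 1/9 and 2/3.  The historically
reported 15 per group for this design is consistent with a
continuity-corrected normal approximation (Casagrande–Pike–Smith gives
≈ 14.4 → 15) rather than exact enumeration; both rules are exposed
(`rule="point" | "doubled"`) so such calculations can be diagnosed.  Exact
power is not monotone in n at small n — the rejection region grows in
discrete jumps — so the minimal-n scan runs upward and tests assert the
sawtooth rather than pretend monotonicity.

## Synthetic cohorts

The generator reproduces the statistical structure of the study arm it
emulates: ages N(43, 10²) clipped to [18, 80] years; 28 × 1.8 Gy
fractionation; per-side hippocampal volumes U(2, 5) cc; left/right
cumulative DVHs as renormalised logistic sigmoids on a 0.1 Gy grid up to
1.15× prescription with midpoint U(5, 52) Gy and steepness U(1, 8) Gy;
events Bernoulli(NTCP(D40%)) under a configurable true dose-response
(defaults: the published parameters).  D40% is obtained by running the
*same* compositing/EQD2/extraction code the analysis uses, so the pipeline
is exercised end to end.

Score pairs are constructed backwards from the drawn event label: events
receive Z = −1.5 − |N(0, 0.7)|, non-events Z ~ N(0, 1) truncated to
≥ −1.5, and the observed change is round(E(age) + 2.362·Z) with scores
clipped to [0, 15] (baselines round(N(9, 2.5)) clipped to [2, 15]).  The
label and the scored Z agree exactly before rounding; integer rounding and
clipping perturb ~5% of labels at the extremes, which is why the
end-to-end recovery test (calibration slope within 1 ± 0.15 on a
5000-patient cohort) is looser than the pre-rounding self-consistency test
(incidence within 3 binomial SEs of mean NTCP per risk decile).  One
`numpy` Generator seeded once per cohort, with draws ordered per patient,
makes cohorts byte-reproducible.

What the generator does *not* emulate: anatomically realistic dose
distributions, correlated left/right dosimetry, tumor progression, drug or
education effects (covariate columns are exchangeable noise).  Passing
tests therefore demonstrate the pipeline's statistical correctness under
its own assumptions, not clinical validity of the model on real cohorts.

## Problem sizes and numerics

Default test/audit sizes are chosen to make sampling error negligible
relative to the asserted tolerances on a single CPU: 1e5 pseudo-voxels for
the compositing oracle, 1e4-point dense grids for Dx% scans, 1e5 subjects
for the null event-rate check (±0.5% absolute around Φ(−1.5) ≈ 6.68%),
5000 patients for end-to-end calibration recovery, 1e5 Monte-Carlo
replicates (3 binomial SEs) for the power cross-check.  Probabilities are
handled in double precision throughout; probit symmetry holds to 1e-12 and
the forward/inverse round trip to 1e-9.

## Known limitations

* No DICOM-RT ingestion; DVHs enter as CSV exports.
* The linear-quadratic conversion has no time factor or repopulation term.
* Only the AVLT delayed-recall endpoint is scored; other neurocognitive
  tests are out of scope.
* Unequal group sizes in the power module are not supported.
* The model's parameters are audited, never refitted; users wanting a
  recalibrated model should apply the reported intercept/slope externally.
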