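# Methods

This note documents the models implemented in `mirswitch`, their
assumptions, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter.

## Reporter calibration

The activity reporter expresses a detector transcript carrying a single
miRNA target site and a normalizer transcript from the same bidirectional
promoter. Assuming the miRNA represses the detector through simple
occupancy, the ratio `r` of detector to normalizer follows a Hill
repression curve

    r(M) = r0 / (1 + (M/K)^n),

where `M` is the miRNA level in arbitrary abundance units, `K` the binding
constant in the same units, `n` the Hill coefficient (≈ 1 for
non-cooperative binding) and `r0` the unrepressed ratio (1 after
normalization). How the abundance units are normalized is irrelevant to the
package: only internal consistency of `M` and `K` is required.

`fit_calibration` minimizes squared residuals on `log r` because reporter
noise is multiplicative (flow-cytometry intensity ratios are log-normal to
good approximation); standard errors come from the Jacobian-based
covariance of the nonlinear fit. `r0` is fixed at 1 by default and can be
freed when the data are not pre-normalized. The fit requires at least 4
points spanning a 4-fold miRNA range; below that the pair (K, n) is poorly
identified. Inversion uses the closed form `M = K (r0/r − 1)^{1/n}`, exact
on `0 < r < r0`.

## Two-state mixture and gating

Single-cell log reporter ratios are modeled as a two-component Gaussian
mixture (log-normal in ratio space). The component with the smaller
location is labeled the high-activity state (more repression, lower ratio).
EM is initialized from a median split of the log-ratios, with 4 additional
seeded random restarts, and stops when the log-likelihood gains less than
1e-8 per observation; the log-likelihood is asserted non-decreasing at
every iteration. When the fitted density has no dip between the two
component locations the result is flagged `effectively_unimodal` — the
two-component description adds nothing in that case.

Cells are gated by posterior membership. The reported threshold is the
ratio at which the two posteriors are equal, obtained in closed form from
the quadratic in `log r`; for equal weights and widths it reduces to the
geometric mean of the component medians. State fractions are reported as
the mean posterior (soft assignment) with a binomial standard error, which
is less threshold-sensitive than hard counting. How gates were drawn in the
original experiments is not recorded; the equal-posterior convention is
this package's choice.

`ratio_zscore` standardizes `log r` with the population (ddof = 0) standard
deviation — deterministic and appropriate for image-wide normalization.

## Dye-dilution division cycles

An amine-reactive dye halves with every division, so log dye intensity is a
Gaussian mixture whose component `d` has mean `mu0 − d·ln 2` (undivided
peak `mu0`, shared width σ — the observed cycles are equally wide and
evenly spaced, and pinning the spacing makes the deconvolution
identifiable). Constrained EM fits the weights, σ and, unless anchored,
`mu0`.

The absolute division count is only identifiable when `mu0` is known; in
practice it comes from the day-0 (undivided) measurement. With `mu0` free,
the fit is normalized so the brightest occupied cycle is division 0, i.e.
counts are relative. `divisions_per_day` fits consecutive daily samples
against one shared anchor and reports the least-squares slope of the mean
division count — for mESCs dividing every 12 h this recovers ≈ 2 divisions
per day.

## Interconversion kinetics

With `H` and `L` the high- and low-state cell counts, equal division rates
and first-order switching (`k_hl`: high→low, `k_lh`: low→high, both per
division),

    dH/dt = k H − k_hl H + k_lh L,
    dL/dt = k L + k_hl H − k_lh L,

the closed form is `H(t) = [f_eq T0 (1 − e^{−k_s t}) + H0 e^{−k_s t}] e^{kt}`
with `k_s = k_hl + k_lh`, `f_eq = k_lh/k_s` and `T0 = H0 + L0`. Because
proliferation is equal in both states, the high-state *fraction* relaxes
exponentially to `f_eq` with timescale `1/k_s`, independent of growth.
Time is measured in divisions internally; the stored `hours_per_division`
factor (default 12 h, the measured mESC cycle) converts at I/O. The growth
rate `k_div` defaults to `ln 2` per division (one doubling per division).

`fit_rates` maximizes a binomial likelihood — the observed `n_high` out of
`n_total` gated cells at each timepoint is a binomial draw around the
analytic fraction — rather than least squares, because the data are counts;
a least-squares mode is kept as a fallback flag. Several time courses
(e.g. sorted-high and sorted-low starts) can be fitted jointly with shared
rates and separate initial fractions. Standard errors are asymptotic
(inverse numerical Hessian, delta method on `log k`). Timescales are
reported both exactly and rounded to whole divisions: for the fitted rates
0.072 and 0.048 per division this gives one high→low switch per 14
divisions, one low→high per 21, and an 8-division relaxation time.

## Colony simulation

Colonies grow from one founder by synchronous binary divisions; at each
division each daughter independently switches state with the
state-appropriate per-division probability. Whether switching should apply
to the mother or to the daughters is ambiguous at the level of "once per
cell cycle"; per-daughter switching was chosen because sister lineages are
observed to de-correlate. During the first `n_survival_divisions` divisions
(default 2) each cell survives with a state-dependent probability —
`p_low` defaults to 1 so the single `survival_bias` parameter (default 8)
fixes `p_high = p_low/bias`; colony survival is then simply
any-descendant-alive. Only per-state counts are tracked (binomial
thinning), which is exact for this model and keeps a 170-colony,
14-division cohort in milliseconds.

Note the per-division switching probability makes the simulator a discrete
Markov chain whose expectation differs from the continuous-time exponential
by O(k²) — about 0.01 in switched fraction at `k_s = 0.08` over 14
divisions. Tests compare the cohort mean against the exact matrix-power
expectation, and against the continuous solution at the tolerance this
offset implies.

Cohort ECDFs of per-colony switched fractions use surviving colonies only
(experimental state distributions can only be read off colonies that grew);
envelopes are pointwise 2.5/97.5 percentiles over replicate cohorts
(default 100 replicates of 170 colonies). The predicted clonogenicity ratio
is the plain ratio of surviving-founder fractions, low over high, with a
percentile bootstrap CI over colonies. The experimentally quoted survival
bias of ≈ 7 with a wide confidence interval is not reproducible as a plain
ratio of the quoted clonogenicities (≈ 3.4); its computation is not
recorded, so the package reports the plain ratio only.

Two switching parameter sets circulate for this system: rates fitted from
population recovery (sum 0.12 per division, ratio 1.5) and the set used for
colony simulations (sum 0.08, ratio 1.5). Both are supported everywhere;
neither is hard-coded as the truth.

## Bistability model

See the README for the rescaled ODEs. The nullclines are derived from the
ODEs: `Y = γ/(1 + γ + (αX)^{n_1})` and `X = d/(1 + (βY)^{n_E})` — the
second printed elsewhere as `Y = (1/β)(1/X − 1)` is dimensionally
inconsistent with the `n_E = 2` dynamics and is treated as a typesetting
loss of the ½ exponent; the exact curve is `Y = (1/β)·sqrt(1/X − 1)`.
Hill exponents default to `n_E = 2` (ERK dimerizes) and `n_1 = 2`
(multiple cascade targets); both are kept as parameters, which makes the
cooperativity checks possible — with `n_E = n_1 = 1` no β yields
bistability. Degradation rates `k_d1 = k_d2 = 1` set the time unit; the
fixed-point structure depends only on (α, β, γ, dosage). The heterozygote
is modeled by the dosage multiplier `d = 0.5` on miRNA production while
keeping the wild-type rescaling of `X`, so stable `X` values compare
directly across genotypes.

Fixed points: substituting the X-nullcline into the Y-nullcline reduces the
problem to one scalar equation `F(Y) = Y(1 + γ + (αX(Y))^{n_1}) − γ = 0`,
sign-scanned on a fixed ~2900-point grid in `(0,1)` that is log-dense near
0 (high-miRNA fixed points sit at tiny active-ERK fractions when α is
large) and near 1, then refined by bisection to machine precision. Each
root is classified by the analytic Jacobian; every reported point satisfies
both ODE right-hand sides to < 1e-9. For these monotone rational nullclines
the intersection count is 1 or 3 with stable/saddle/stable ordering — an
invariant the tests assert over random parameter draws.

The phase diagram counts stable states per (α, γ) node at fixed β by the
same sign-scan, vectorized over the α grid. `critical_beta` ascends a β
grid and returns the first value with any bistable node; with the reference
grids (β step 0.05, α = 0 plus 200 log-spaced points to 100, γ 100
log-spaced points over [0.05, 50]) the scan reports 2.10. An independent
analytic check (non-monotonicity of `α² = (γ/Y − 1 − γ)(1 + β²Y²)²`)
places the true onset between 2.01 and 2.05, but near onset the bistable
α-window is ~1e-3 wide — far below the α-grid spacing — so 2.10 is the
honest grid answer, consistent with the analytic bound β > 2.

Saddle-node boundaries of the bistable window in α (for the reference
β = 10, γ = 1: α ≈ 5.203 and α ≈ 12.318) are located by bisection on the
stable-state-count indicator to 1e-4 and serve as regression fixtures.
`steady_state_curve` sweeps α and labels the contiguous regimes low →
bistable → high. Trajectories use adaptive RK45 at rtol 1e-10 and report
the basin by terminal proximity to a stable fixed point.

## Heterozygote distribution prediction

The wild-type mixture's component medians are mapped through the inverted
calibration to miRNA levels, scaled by the per-branch ratio of stable
fixed-point levels at dosage 0.5 vs 1 (high-activity component → high-miRNA
branch), and mapped back to ratio space. Medians are used rather than means
because the median commutes exactly with the monotone calibration;
component log-widths are carried over unchanged, a second-order
approximation that is excellent for a near-unit Hill coefficient. Whether
the original analysis rescaled the empirical distribution pointwise or
per component is not recorded; the component-wise convention is this
package's choice. Only the two component weights (state occupancies) are
fitted to the observed heterozygote sample, by bounded 1-D maximum
likelihood. Goodness is reported as per-observation log-likelihood plus a
one-sample Kolmogorov–Smirnov test against the predicted mixture CDF.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the estimators assume:
log-normal multiplicative reporter noise, binomial gating counts around the
analytic state fraction, ln 2-spaced Gaussian dye ladders, and two-state
branching colonies. They deliberately omit instrument effects
(autofluorescence, spectral spillover, FCS file structure), asynchronous
division times, cell-cycle reporter artifacts and any transcriptome-level
variation. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to those unmodeled
effects.

Every generator is a pure function of its parameters and a `RandomSpec`
(seed plus stream name, folded into the seed-sequence entropy via CRC-32),
so any dataset is reproducible bit-for-bit and distinct consumers get
independent streams from one seed.

## Problem sizes and numerical defaults

Defaults were chosen to mirror the reference analysis settings: 170
colonies × 14 divisions × 100 replicate cohorts; β = 10 phase diagrams;
α ∈ [0, 20] steady-state sweeps at γ = 1; rate fits on ~20 timepoints of
10⁴ gated cells. Monte-Carlo recovery suites in the tests use 60–200
seeded replicates, enough to resolve the stated coverage criteria (e.g.
≥ 90% of fits within ±15%) while keeping the suite under a minute. EM
tolerance is 1e-8 per observation; fixed-point residual tolerance 1e-9;
root refinement to machine precision; rate optimization by two-stage
Nelder-Mead on log-rates.

## Known limitations

* The analytic kinetics assume equal proliferation of the two states (as
  measured); unequal rates are supported only through the general ODE used
  as an integration oracle in tests.
* The mixture decomposition is fixed at two components; it will not detect
  a third state.
* The colony simulator's synchronous divisions ignore division-time
  variability, which broadens real colony-size distributions.
* `critical_beta` is grid-limited near onset (see above); refine the grids
  if the third decimal matters.
* The bistability region's growth with β is checked empirically on grids,
  not proven.
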