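# Methods

## Model family

All models concern K indicator phenotypes `y_1..y_K`, one latent factor `F`
and one external trait `T`, on the genetic (co)variance scale produced by
multivariate LDSC. The reduced form used throughout is

    y_k = a_k T + lambda_k u + e_k,      a_k = lambda_k b + d_k,
    F   = b T + u,

with `phi = var(T)`, `psi = var(u)` and `theta_k = var(e_k)`, giving

    cov(y_j, y_k) = a_j a_k phi + lambda_j lambda_k psi   (+ theta_k if j = k)
    cov(T, y_k)   = a_k phi
    var(T)        = phi.

The three topologies differ only in which of `b` and `d_k` are free:

- **common pathway** — all `d_k = 0`; the trait–indicator covariances are
  `b phi lambda_k`, proportional to the unstandardized loadings;
- **independent pathways** — `b = 0` (trait–factor covariance fixed at zero),
  all K direct effects `d_k` free, saturating the trait–indicator block.
  Fixing the trait–factor covariance is what makes the parameter-count
  difference against the common pathway model exactly K−1;
- **follow-up** — the common pathway model plus free `d_k` for at most K−1
  named indicators.

Identification is unit-loading (`lambda_1 = 1`, `psi` free). This convention
survives both the factor-on-trait regression and freed direct paths. A
unit-variance alternative (`var(F) = 1` enforced through the implicit
`psi = 1 − b²phi`) is implemented solely to assert that the standardized
solution does not depend on the convention; the test suite checks agreement
to 1e-5. Residual variances are left unbounded during optimization — bounding
them at zero would distort χ² differences at boundary solutions — and
negative estimates are flagged post fit as Heywood cases.

## Estimation

The fit function is diagonally weighted least squares,
`F_WLS = (s − σ(θ))' D⁻¹ (s − σ(θ))`, with `D = diag(V)` floored at 1e-14.
`s` and the V sub-block are extracted for the model's variables in model
order under a single half-vectorization convention (lower triangle,
column-major) used everywhere; V's rows/columns must follow the same
ordering, since a mismatch corrupts the weights silently.

Minimization is BFGS with the analytic Jacobian of the implied moments
(closed-form derivatives of the reduced form above). Start values are
deterministic: a triad estimate `S12·S13/S23` for the factor-variance proxy,
first-indicator scaling for loadings, observed variances for `phi`/`theta`,
and moment ratios for `b` or the `d_k`. On failure, up to 10 multiplicative
jittered restarts are drawn from a generator seeded by the run seed, so the
whole pipeline is a deterministic function of (data, config, seed). The
weight vector is internally rescaled by its median so the gradient tolerance
(1e-5 on the normalized scale) is invariant to the overall magnitude of the
standard errors; this matters for population-scale runs where SEs are driven
toward zero. The reported `F_WLS` minimum is on the original scale.

Parameter covariance is the sandwich
`(Δ'Γ⁻¹Δ)⁻¹ Δ'Γ⁻¹ V Γ⁻¹ Δ (Δ'Γ⁻¹Δ)⁻¹` with `Γ = D`; a rank-deficient
Jacobian raises a local-identification error. The standardized
correlate–factor coefficient is reported as an rG,
`b·sqrt(phi)/sqrt(b²phi + psi)`; its SE carries the unstandardized sandwich
SE through the standardization factor with the fitted variances treated as
fixed (a first-order approximation; the Monte-Carlo calibration below bounds
its quality in practice).

## Test statistics

The per-model exact-fit statistic is the residual-based quadratic form

    T = r' [V⁻¹ − V⁻¹Δ(Δ'V⁻¹Δ)⁻¹Δ'V⁻¹] r,     r = s − σ(θ̂),

with df = m − q, V eigenvalue-floored to invertibility. This statistic is
asymptotically χ²_df for any consistent estimator, independent of the
diagonal weights used in fitting, which makes nested differences
well-behaved. Q_Trait is the difference of these statistics between the
restricted (common pathway or follow-up) and the independent-pathways model;
its df is the parameter-count difference, K−1 minus the number of freed
paths. Marginally negative statistics or differences (floating-point noise
on near-equal fits) are clamped to zero with a warning. Calibration is not
assumed: the acceptance suite verifies the 5% rejection rate, the uniformity
of null p-values (Kolmogorov–Smirnov), and the sandwich SE ratio by
simulation.

## Heterogeneity decision rules

Residual genetic correlations subtract the model-implied correlation
(standardized with the model's own implied variances) from the observed one;
lSRMR is their root mean square over all K indicators, including freed ones,
whose residuals are ~0 — so the lSRMR-reduction percentage is computed on a
fixed denominator. Dual thresholds: an absolute cutoff (default 0.10,
following SRMR conventions) and a context cutoff (default 25% of the root
mean square *observed* correlate–indicator correlation). Both comparisons
use |residual| and strict inequality, so a residual exactly at 0.10 is not
flagged. The context threshold is computed once per correlate from observed
correlations and not recomputed across iterations (observed correlations do
not change when paths are freed). Heterogeneity requires the Q_Trait p-value
below `alpha_q` (default 0.05, unadjusted) *and* lSRMR above both
thresholds. Because the root mean square is bounded above by the maximum
absolute residual, a heterogeneous verdict always implies at least one
flaggable indicator, so the iterative step is total.

## Automated workflow

Per correlate: (1) fit the common pathway model and gate on the Wald p-value
of `b` against `alpha / n_correlates` (Bonferroni over the correlates
supplied); heterogeneity is evaluated only for gate-passing correlates.
(2) Fit independent pathways, assess heterogeneity; if absent, stop with
status `homogeneous` (or `corrected` if paths were already freed). (3) Free
a direct path to the most extreme outlier (largest |residual|, ties to the
lowest position); if freed paths now exceed `max_free_proportion · K`
(default 50%, strict), stop with `widespread_heterogeneity`. (4) Refit; if
the correlate–factor association no longer passes the gate threshold, stop
with `association_absorbed`; otherwise loop. The loop is bounded by K−1
freed paths. The exported summary mirrors the conventional results-table
layout, with dashes in follow-up columns for non-heterogeneous correlates
and the lSRMR reduction computed from unrounded values.

## Synthetic generator

The generator emulates stage-1 LDSC output, not SNP data. Given a scenario
(true loadings, `psi`, `b`, planted direct effects, residual variances,
`phi`), it draws `s ~ MVN(vech(Σ_true), V)` where V has diagonal
`(se_scale · sqrt(S_jj S_kk + S_jk²))²` — a normal-theory magnitude, not a
claim about LDSC's actual sampling behavior — and a single exchangeable
off-diagonal correlation `overlap_rho` (default 0.1) standing in for
sample-overlap-induced dependence. Defaults put correlate–indicator rg
standard errors near 0.03, typical of well-powered LDSC analyses.

Presets:

- `null_k5` — K=5, loadings (1, .9, .8, .7, .6), `b = 0.3`, no direct
  effects, all indicator variances 1. The calibration scenario.
- `ad_like` — K=3, `b = −0.3`, one direct effect +0.35 on indicator 3,
  sized so its observed population correlation flips sign (+0.11 vs −0.30 and
  −0.27) with population residual +0.23, while the compromise misfit spilled
  onto the clean indicators stays near −0.06, well below the 0.10 threshold
  at the default noise level. Correction strengthens the association.
- `g_like` — K=7, `b = 0.3`, two weakly loading indicators (0.35, 0.30)
  carrying direct effects +0.45/+0.42. Each planted outlier alone keeps the
  global lSRMR above both thresholds, so the workflow frees them one at a
  time; correction attenuates the association. A milder symmetric design
  stalls after one freed path because a single remaining outlier's
  contribution to the K=7 root mean square drops below the absolute
  threshold — an intended property of the dual-threshold rule worth knowing
  when choosing K and thresholds in real applications.

What the generator does **not** emulate: LDSC's actual (heavy-tailed,
LD-dependent) sampling distribution, block-jackknife V structure,
liability-scale issues, or multi-factor architectures. Passing tests
demonstrate internal statistical correctness of the estimator and decision
rules under a correctly specified multivariate normal sampling model — not
robustness to real LDSC output pathologies (beyond eigenvalue-smoothing of
indefinite S/V, which is handled).

## Numerical conventions and edge cases

- Symmetry tolerances: 1e-10 for S, 1e-8 for V (V is itself estimated and
  noisier). Indefinite S/V are eigenvalue-clipped to a floor with a logged
  warning rather than rejected, matching common practice for LDSC output;
  re-smoothing an already-floored matrix is a no-op within 1e-10.
- The smallest fit problem is K=3 (factor identification); K=3 independent
  pathways is just-identified (T = 0, df = 0, p = 1 by convention).
- Monte-Carlo study sizes: 500 replicates for null calibration, 200 for
  planted-outlier recovery, chosen to put the binomial Monte-Carlo error of
  a 5% rate near 1 percentage point; each replicate draws from an
  independent counter-based substream so any replicate is reproducible in
  isolation.
- Population-scale checks use `se_scale = 1e-8`: small enough that sampling
  noise is negligible at the 1e-6 level, large enough that V remains
  comfortably invertible in double precision.

## Scope

Stage-1 multivariate LDSC (estimating S and V from GWAS summary statistics),
liability-scale conversion, effective-sample-size computation, multi-factor
or correlated-residual measurement models, and maximum-likelihood or scaled
χ² variants are out of scope. Real-data results therefore cannot be
reproduced by this package alone; the synthetic scenarios mimic their
qualitative structure only.
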