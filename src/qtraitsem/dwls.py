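"""Diagonally weighted least squares fitting of factor models to (S, V).

The stage-2 estimator minimizes

    F_WLS(theta) = (s - sigma(theta))' D_S^{-1} (s - sigma(theta))

where s = vech(S) restricted to the model's variables, sigma(theta) is the
half-vectorized model-implied covariance and D_S is the diagonal of the
corresponding sub-block of V.  Parameter uncertainty comes from the sandwich

    V_theta = (D'G^{-1}D)^{-1} D'G^{-1} V G^{-1} D (D'G^{-1}D)^{-1}

with D the Jacobian of sigma at the estimate and G = D_S, which is robust to
the diagonal weights differing from the full sampling covariance V.

The per-model test statistic is the residual-based quadratic form

    T = r' [V^{-1} - V^{-1} D (D'V^{-1}D)^{-1} D'V^{-1}] r,   r = s - sigma(theta_hat)

which is asymptotically chi-square with m - q degrees of freedom for any
consistent estimator of theta, so nested differences of T behave as
chi-square with the difference in df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .covstruct import CovStruct, smooth_to_pd, vech
from .factor_models import ModelSpec, _unpack, implied_sigma, implied_sigma_jacobian

__all__ = ["FitOptions", "FitResult", "fit_dwls", "sandwich_vtheta", "model_chisq", "chisq_diff"]

_WEIGHT_FLOOR = 1e-14  # floor on diag(V) entries used as DWLS weights


@dataclass
class FitOptions:
    max_restarts: int = 10
    tolerance: float = 1e-10
    seed: int | None = None
    fixed: dict[str, float] | None = None  # pin named parameters (profiling/debugging)


@dataclass
class FitResult:
    spec: ModelSpec
    theta_hat: np.ndarray
    se: np.ndarray
    param_names: list[str]
    fwls_min: float
    chisq: float
    df: int
    p_value: float
    sigma_hat: np.ndarray
    std_solution: dict
    converged: bool
    heywood: list[str] = field(default_factory=list)
    n_restarts_used: int = 0
    vtheta: np.ndarray | None = None
    jacobian: np.ndarray | None = None
    weight_diag: np.ndarray | None = None
    s_observed: np.ndarray | None = None
    v_sub: np.ndarray | None = None

    def __getitem__(self, name: str) -> float:
        return float(self.theta_hat[self.param_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def wald_p(self, name: str) -> float:
        """Two-sided normal p-value for a single parameter."""
        se = self.se_of(name)
        if not np.isfinite(se) or se <= 0:
            return float("nan")
        z = self[name] / se
        return float(2.0 * stats.norm.sf(abs(z)))


def _start_values(spec: ModelSpec, S: np.ndarray) -> np.ndarray:
    """Deterministic start values from the observed sub-matrix.

    The factor-variance proxy is the triad estimate S12*S13/S23 from the first
    three indicators (guarded to stay positive); loadings follow from
    first-indicator scaling, variances from the S diagonal.
    """
    K = spec.K
    Syy = S[:K, :K]
    sty = S[K, :K]
    stt = S[K, K]
    denom = Syy[1, 2] if abs(Syy[1, 2]) > 1e-12 else 1e-12
    var_f = Syy[0, 1] * Syy[0, 2] / denom
    if not np.isfinite(var_f) or var_f <= 1e-8:
        var_f = max(0.5 * Syy[0, 0], 1e-4)
    var_f = min(var_f, 10.0 * Syy[0, 0] + 1e-4)
    lam = np.ones(K)
    lam[1:] = Syy[0, 1:] / var_f
    phi = max(stt, 1e-8)
    b0 = sty[0] / phi
    start: list[float] = []
    for par in spec.free_parameters:
        if par.kind == "loading":
            i = spec.indicator_names.index(par.name[7:-1])
            if spec.identification == "unit_variance":
                start.append(lam[i] * np.sqrt(var_f))
            else:
                start.append(lam[i])
        elif par.kind == "factor_residual_variance":
            psi0 = var_f - b0 * b0 * phi if spec.topology != "independent_pathways" else var_f
            start.append(max(psi0, 0.05 * var_f))
        elif par.kind == "factor_regression":
            if spec.identification == "unit_variance":
                start.append(b0 * np.sqrt(var_f) * 0.5)
            else:
                start.append(b0)
        elif par.kind == "direct_effect":
            if spec.topology == "independent_pathways":
                i = spec.indicator_names.index(par.name[2:-1])
                start.append(sty[i] / phi)
            else:
                start.append(0.0)
        elif par.kind == "indicator_residual_variance":
            i = spec.indicator_names.index(par.name[6:-1])
            start.append(max(Syy[i, i] - lam[i] ** 2 * var_f, 0.05 * Syy[i, i]))
        elif par.kind == "correlate_variance":
            start.append(phi)
    return np.asarray(start)


def _standardize(spec: ModelSpec, theta: np.ndarray, sigma: np.ndarray) -> dict:
    """Standardized solution derived from the fitted model's own implied variances."""
    lam, psi, b, d, resid, phi = _unpack(spec, theta)
    K = spec.K
    var_f = b * b * phi + psi
    sd_y = np.sqrt(np.maximum(np.diag(sigma)[:K], 1e-300))
    sd_f = np.sqrt(max(var_f, 1e-300))
    sd_t = np.sqrt(max(phi, 1e-300))
    out = {
        "loadings_std": lam * sd_f / sd_y,
        "rg_correlate_factor": b * sd_t / sd_f if spec.topology != "independent_pathways" else np.nan,
        "direct_effects_std": d * sd_t / sd_y,
        "var_factor": var_f,
    }
    return out


def fit_dwls(spec: ModelSpec, cs: CovStruct, options: FitOptions | None = None) -> FitResult:
    """Fit a model spec to a covariance structure by DWLS.

    The covariance structure is restricted to the spec's variables (indicators
    then correlate) with the V sub-block extracted in the matching vech order.
    Optimization is quasi-Newton (BFGS) with the analytic Jacobian of the
    implied moments, from deterministic start values, with up to
    ``max_restarts`` seeded multiplicative-jitter restarts on failure.
    """
    options = options or FitOptions()
    sub = cs.subset(spec.variable_names)
    s = vech(sub.S)
    V = sub.V
    w = np.maximum(np.diag(V).copy(), _WEIGHT_FLOOR)
    inv_w = 1.0 / w
    # optimize on a normalized weight scale so convergence tolerances are
    # invariant to the overall magnitude of the standard errors
    w_scale = float(np.median(inv_w))
    inv_w_opt = inv_w / w_scale

    fixed = options.fixed or {}
    fixed_idx = np.array([spec.param_index(n) for n in fixed], dtype=int)
    fixed_val = np.array([fixed[n] for n in fixed], dtype=float)
    free_mask = np.ones(spec.n_free, dtype=bool)
    free_mask[fixed_idx] = False

    def expand(x: np.ndarray) -> np.ndarray:
        theta = np.empty(spec.n_free)
        theta[free_mask] = x
        theta[fixed_idx] = fixed_val
        return theta

    def fun_and_grad(x: np.ndarray):
        theta = expand(x)
        r = s - vech(implied_sigma(spec, theta))
        wr = inv_w_opt * r
        f = float(r @ wr)
        J = implied_sigma_jacobian(spec, theta)[:, free_mask]
        g = -2.0 * (J.T @ wr)
        return f, g

    x0_base = _start_values(spec, sub.S)[free_mask]
    f0, _ = fun_and_grad(x0_base)
    if not np.isfinite(f0):
        raise ValueError("non-finite fit function at start values")

    rng = np.random.default_rng(options.seed if options.seed is not None else 0)
    best = None
    n_used = 0
    for attempt in range(options.max_restarts + 1):
        if attempt == 0:
            x0 = x0_base
        else:
            jitter = rng.normal(loc=1.0, scale=0.2, size=x0_base.shape)
            x0 = x0_base * jitter + rng.normal(scale=0.05, size=x0_base.shape)
        res = optimize.minimize(
            fun_and_grad,
            x0,
            jac=True,
            method="BFGS",
            options={"gtol": options.tolerance ** 0.5, "maxiter": 2000},
        )
        n_used = attempt
        grad_ok = np.linalg.norm(res.jac, np.inf) < 1e-5 * max(1.0, abs(res.fun)) + 1e-6
        if (res.success or grad_ok) and np.isfinite(res.fun):
            best = res
            break
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res

    converged = bool(
        best is not None
        and np.isfinite(best.fun)
        and (best.success or np.linalg.norm(best.jac, np.inf) < 1e-5 * max(1.0, abs(best.fun)) + 1e-6)
    )
    theta_hat = expand(best.x)
    fwls_min = max(float(best.fun) * w_scale, 0.0)
    sigma_hat = implied_sigma(spec, theta_hat)
    J = implied_sigma_jacobian(spec, theta_hat)

    # sandwich SEs over the free subset; fixed parameters get SE 0
    se = np.zeros(spec.n_free)
    vtheta_full = np.full((spec.n_free, spec.n_free), np.nan)
    try:
        vtheta = sandwich_vtheta(J[:, free_mask], w, V)
        se_free = np.sqrt(np.maximum(np.diag(vtheta), 0.0))
        se[free_mask] = se_free
        vtheta_full = np.zeros((spec.n_free, spec.n_free))
        vtheta_full[np.ix_(free_mask, free_mask)] = vtheta
    except np.linalg.LinAlgError:
        se[:] = np.nan
        converged = False

    lam, psi, b, d, resid, phi = _unpack(spec, theta_hat)
    heywood = [
        f"theta[{ind}]" for ind, v in zip(spec.indicator_names, resid) if v < 0
    ]
    if psi < 0:
        heywood.append("psi")

    fit = FitResult(
        spec=spec,
        theta_hat=theta_hat,
        se=se,
        param_names=[p.name for p in spec.free_parameters],
        fwls_min=fwls_min,
        chisq=np.nan,
        df=sub.m - int(free_mask.sum()),
        p_value=np.nan,
        sigma_hat=sigma_hat,
        std_solution=_standardize(spec, theta_hat, sigma_hat),
        converged=converged,
        heywood=heywood,
        n_restarts_used=n_used,
        vtheta=vtheta_full,
        jacobian=J[:, free_mask],
        weight_diag=w,
        s_observed=s,
        v_sub=V,
    )
    if converged:
        chisq, df, p = model_chisq(fit, cs)
        fit.chisq, fit.df, fit.p_value = chisq, df, p
    return fit


def sandwich_vtheta(jacobian: np.ndarray, gamma: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Sandwich parameter covariance for a DWLS fit.

    ``gamma`` may be the diagonal weight vector or the full diagonal matrix
    D_S used in fitting; ``V`` is the sampling covariance of the moments.
    Raises on a rank-deficient Jacobian (model not locally identified).
    """
    J = np.atleast_2d(np.asarray(jacobian, dtype=float))
    if J.shape[0] < J.shape[1]:
        raise np.linalg.LinAlgError("more parameters than moments")
    g = np.asarray(gamma, dtype=float)
    inv_g = 1.0 / (np.diag(g) if g.ndim == 2 else g)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    JtW = (J * inv_g[:, None]).T  # J' G^{-1}
    bread_inv = JtW @ J
    if np.linalg.matrix_rank(bread_inv) < J.shape[1]:
        raise np.linalg.LinAlgError("model not locally identified (rank-deficient Jacobian)")
    bread = np.linalg.inv(bread_inv)
    meat = JtW @ V @ JtW.T
    out = bread @ meat @ bread
    return (out + out.T) / 2.0


def model_chisq(fit: FitResult, cs: CovStruct) -> tuple[float, int, float]:
    """Residual-based test of exact fit for a single fitted model.

    T = r'[V^{-1} - V^{-1}D(D'V^{-1}D)^{-1}D'V^{-1}]r with df = m - q; the
    projection removes the directions absorbed by parameter estimation, so T
    is asymptotically chi-square regardless of the (diagonal) weights used to
    estimate theta.  V is eigenvalue-floored to be invertible.
    """
    if not fit.converged:
        raise ValueError("model_chisq requires a converged fit")
    r = fit.s_observed - vech(fit.sigma_hat)
    V = smooth_to_pd(fit.v_sub, 1e-12).matrix
    m = r.shape[0]
    q = fit.jacobian.shape[1]
    df = m - q
    if df <= 0:
        return 0.0, 0, 1.0
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular V after smoothing") from None
    D = fit.jacobian
    ViD = Vi @ D
    middle = Vi - ViD @ np.linalg.solve(D.T @ ViD, ViD.T)
    T = float(r @ middle @ r)
    if T < 0:
        if T < -1e-6:
            warnings.warn(f"model chi-square {T:.3g} negative beyond tolerance; clamped to 0")
        T = 0.0
    p = float(stats.chi2.sf(T, df))
    return T, df, p


def _is_nested(restricted: ModelSpec, unrestricted: ModelSpec) -> bool:
    if restricted.indicator_names != unrestricted.indicator_names:
        return False
    if restricted.correlate_name != unrestricted.correlate_name:
        return False
    rt, ut = restricted.topology, unrestricted.topology
    if ut == "independent_pathways":
        return rt in ("common_pathway", "followup")
    if ut == "followup":
        if rt == "common_pathway":
            return True
        if rt == "followup":
            return set(restricted.direct_paths) < set(unrestricted.direct_paths)
    return False


def chisq_diff(fit_unrestricted: FitResult, fit_restricted: FitResult) -> tuple[float, int, float]:
    """Chi-square difference between nested fits on the same covariance structure.

    For the common-pathway model against independent pathways this is the
    Q_Trait statistic with df = K - 1; for a follow-up model with F freed
    paths against independent pathways, df = K - 1 - F.
    """
    if not _is_nested(fit_restricted.spec, fit_unrestricted.spec):
        raise ValueError("models are not nested (restricted must nest inside unrestricted)")
    df = fit_restricted.df - fit_unrestricted.df
    if df <= 0:
        raise ValueError("restricted model must have more degrees of freedom")
    Q = fit_restricted.chisq - fit_unrestricted.chisq
    if Q < 0:
        if Q < -1e-6:
            warnings.warn(f"negative chi-square difference {Q:.3g}; clamped to 0")
        Q = 0.0
    p = float(stats.chi2.sf(Q, df))
    return float(Q), int(df), p
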