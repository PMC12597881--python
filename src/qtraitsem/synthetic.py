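"""Synthetic LDSC-style covariance structures with known generative truth.

The generator emulates stage-1 multivariate LDSC output without simulating
any SNP data: the half-vectorized genetic covariance estimate s is drawn from
a multivariate normal centered on the model-implied population matrix
Sigma_true, with a sampling covariance V built from normal-theory standard
error magnitudes

    se_jk = se_scale * sqrt(S_jj * S_kk + S_jk^2)

and an exchangeable correlation ``overlap_rho`` on the off-diagonal of V that
mimics dependence induced by participant sample overlap.  Three presets
mirror the study designs the statistics are meant for: a clean common-pathway
null (K=5), a small disease factor in which one proxy indicator carries a
sign-flipping direct effect (K=3, "ad_like"), and a larger cognitive factor
with two positively deviating indicators (K=7, "g_like").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .covstruct import CovStruct, unvech, vech
from .dwls import FitOptions, fit_dwls
from .factor_models import build_model, implied_sigma

__all__ = ["Scenario", "true_sigma", "simulate_covstruct", "preset", "calibration_study"]

PRESET_NAMES = ("null_k5", "ad_like", "g_like")


@dataclass
class Scenario:
    """Ground-truth parameterization of a single-factor model with a correlate."""

    K: int
    loadings: np.ndarray  # first entry 1.0 (unit-loading truth)
    psi: float  # factor residual variance
    b_true: float  # correlate -> factor effect
    direct_effects: np.ndarray  # mostly zeros; at most K-1 nonzero
    indicator_residuals: np.ndarray
    phi: float = 1.0  # correlate variance
    se_scale: float = 0.03
    overlap_rho: float = 0.1
    seed: int = 0
    indicator_names: list[str] = field(default_factory=list)
    correlate_name: str = "T"

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.direct_effects = np.asarray(self.direct_effects, dtype=float)
        self.indicator_residuals = np.asarray(self.indicator_residuals, dtype=float)
        if self.loadings.shape != (self.K,):
            raise ValueError("loadings must have length K")
        if self.direct_effects.shape != (self.K,):
            raise ValueError("direct_effects must have length K")
        if self.indicator_residuals.shape != (self.K,):
            raise ValueError("indicator_residuals must have length K")
        if self.psi <= 0 or self.phi <= 0 or np.any(self.indicator_residuals <= 0):
            raise ValueError("all variances must be positive")
        if np.count_nonzero(self.direct_effects) > self.K - 1:
            raise ValueError("at most K-1 direct effects may be nonzero")
        if not self.indicator_names:
            self.indicator_names = [f"y{k + 1}" for k in range(self.K)]

    @property
    def planted_paths(self) -> list[str]:
        return [
            self.indicator_names[k]
            for k in range(self.K)
            if self.direct_effects[k] != 0.0
        ]


def _scenario_spec_and_theta(sc: Scenario):
    """The follow-up (or common-pathway) spec holding the true parameters."""
    if sc.planted_paths:
        spec = build_model(sc.indicator_names, sc.correlate_name, "followup", sc.planted_paths)
    else:
        spec = build_model(sc.indicator_names, sc.correlate_name, "common_pathway")
    theta = []
    for par in spec.free_parameters:
        if par.kind == "loading":
            theta.append(sc.loadings[sc.indicator_names.index(par.name[7:-1])])
        elif par.kind == "factor_residual_variance":
            theta.append(sc.psi)
        elif par.kind == "factor_regression":
            theta.append(sc.b_true)
        elif par.kind == "direct_effect":
            theta.append(sc.direct_effects[sc.indicator_names.index(par.name[2:-1])])
        elif par.kind == "indicator_residual_variance":
            theta.append(sc.indicator_residuals[sc.indicator_names.index(par.name[6:-1])])
        elif par.kind == "correlate_variance":
            theta.append(sc.phi)
    return spec, np.asarray(theta)


def true_sigma(sc: Scenario) -> tuple[np.ndarray, pd.DataFrame]:
    """Population covariance and the population-level residual-rg table.

    The residuals are computed against the best-fitting common-pathway model
    at population level, obtained by an identity-weight (ULS) fit to
    Sigma_true: this is the misfit the pipeline is asked to detect, before
    any sampling noise.
    """
    spec, theta = _scenario_spec_and_theta(sc)
    sigma = implied_sigma(spec, theta)
    eigmin = np.linalg.eigvalsh(sigma).min()
    if eigmin <= 0:
        raise ValueError(f"Sigma_true is not positive definite (min eigenvalue {eigmin:.3g})")

    m = (sc.K + 1) * (sc.K + 2) // 2
    pop_cs = CovStruct(
        sc.indicator_names + [sc.correlate_name], sigma, np.eye(m), {"population": True}
    )
    cp = build_model(sc.indicator_names, sc.correlate_name, "common_pathway")
    fit = fit_dwls(cp, pop_cs, FitOptions(seed=0))
    from .heterogeneity import residual_rg

    rg_obs, rg_imp, rg_res = residual_rg(pop_cs, fit, sc.correlate_name, sc.indicator_names)
    table = pd.DataFrame(
        {
            "indicator": sc.indicator_names,
            "rg_observed": rg_obs,
            "rg_implied": rg_imp,
            "rg_residual": rg_res,
        }
    )
    return sigma, table


def _se_magnitudes(sigma: np.ndarray) -> np.ndarray:
    """Normal-theory magnitudes sqrt(S_jj*S_kk + S_jk^2) for each vech element."""
    p = sigma.shape[0]
    out = []
    for c in range(p):
        for r in range(c, p):
            out.append(np.sqrt(sigma[r, r] * sigma[c, c] + sigma[r, c] ** 2))
    return np.asarray(out)


def build_v(sc: Scenario, sigma: np.ndarray) -> np.ndarray:
    """Sampling covariance V = D^{1/2} R D^{1/2} with exchangeable overlap."""
    se = sc.se_scale * _se_magnitudes(sigma)
    m = se.shape[0]
    R = np.full((m, m), sc.overlap_rho)
    np.fill_diagonal(R, 1.0)
    if sc.overlap_rho < 0 or sc.overlap_rho >= 1:
        raise ValueError("overlap_rho must be in [0, 1)")
    V = R * np.outer(se, se)
    eigmin = np.linalg.eigvalsh(V).min()
    if eigmin <= 0:
        raise ValueError(
            f"V is not positive definite for overlap_rho={sc.overlap_rho}; use a smaller rho"
        )
    return V


def simulate_covstruct(sc: Scenario, rng: np.random.Generator | None = None) -> CovStruct:
    """Draw one LDSC-style (S, V) realization: s ~ MVN(vech(Sigma_true), V)."""
    spec, theta = _scenario_spec_and_theta(sc)
    sigma = implied_sigma(spec, theta)
    V = build_v(sc, sigma)
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    L = np.linalg.cholesky(V)
    s = vech(sigma) + L @ rng.standard_normal(V.shape[0])
    S = unvech(s, sc.K + 1)
    return CovStruct(
        sc.indicator_names + [sc.correlate_name],
        S,
        V,
        {"generator": "qtraitsem.synthetic", "seed": int(sc.seed)},
    )


def preset(name: str) -> Scenario:
    """Named study scenarios.

    ``null_k5``  K=5 common-pathway truth (no direct effects): the
    calibration scenario for Q_Trait and the sandwich SEs.

    ``ad_like``  K=3 disease-style factor with a negative correlate-factor
    effect and one positive direct effect on indicator 3 large enough to flip
    the sign of its observed correlation with the correlate (the
    proxy-indicator motif).

    ``g_like``  K=7 cognitive-style factor with a positive correlate-factor
    effect and two positive direct effects on indicators 6-7.

    Default se_scale=0.03 puts the correlate-indicator rg standard errors
    near 0.03, typical of well-powered LDSC analyses.
    """
    if name == "null_k5":
        lam = np.array([1.0, 0.9, 0.8, 0.7, 0.6])
        var_f = 0.3 * 0.3 * 1.0 + 0.5  # b^2*phi + psi = 0.59
        return Scenario(
            K=5,
            loadings=lam,
            psi=0.5,
            b_true=0.3,
            direct_effects=np.zeros(5),
            indicator_residuals=1.0 - lam**2 * var_f,
            phi=1.0,
            se_scale=0.03,
            overlap_rho=0.1,
        )
    if name == "ad_like":
        # the direct effect is sized to flip the sign of indicator 3's
        # observed correlation while keeping the misfit spilled onto the
        # clean indicators (the common-pathway compromise) comfortably below
        # the 0.10 outlier threshold
        lam = np.array([1.0, 0.9, 0.8])
        var_f = (-0.3) ** 2 * 1.0 + 0.5
        return Scenario(
            K=3,
            loadings=lam,
            psi=0.5,
            b_true=-0.3,
            direct_effects=np.array([0.0, 0.0, 0.35]),
            indicator_residuals=1.0 - lam**2 * var_f,
            phi=1.0,
            se_scale=0.03,
            overlap_rho=0.1,
        )
    if name == "g_like":
        # two weakly loading indicators carry large positive direct effects,
        # large enough that each alone sustains the lSRMR above its thresholds
        # (so the workflow frees them one at a time)
        lam = np.array([1.0, 0.95, 0.9, 0.85, 0.8, 0.35, 0.30])
        var_f = 0.3 * 0.3 * 1.0 + 0.5
        resid = 1.0 - lam**2 * var_f
        return Scenario(
            K=7,
            loadings=lam,
            psi=0.5,
            b_true=0.3,
            direct_effects=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.45, 0.42]),
            indicator_residuals=resid,
            phi=1.0,
            se_scale=0.03,
            overlap_rho=0.1,
        )
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate of a study."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def calibration_study(
    sc: Scenario,
    replicates: int,
    config=None,
    alphas: Sequence[float] = (0.01, 0.05),
) -> dict:
    """Monte-Carlo study of the full per-correlate pipeline under a scenario.

    Each replicate simulates a fresh covariance structure and runs the
    automated workflow; the summary collects Q_Trait rejection rates, the KS
    distance of Q p-values from uniform (meaningful under null scenarios),
    per-indicator flag rates, the mean/SD of the estimated correlate-factor
    rG, the mean reported sandwich SE of b, and the nonconvergence count.
    """
    from scipy import stats

    from .pipeline import QTraitConfig, run_correlate

    if replicates < 1:
        raise ValueError("need at least one replicate")
    config = config or QTraitConfig()

    q_ps, rgs, b_hats, b_ses = [], [], [], []
    flags = np.zeros(sc.K)
    statuses: dict[str, int] = {}
    nonconv = 0
    for rep in range(replicates):
        rng = replicate_rng(config.seed, rep)
        cs = simulate_covstruct(sc, rng=rng)
        rep_cfg = replace(config, seed=int(config.seed) + rep)
        report = run_correlate(cs, sc.indicator_names, sc.correlate_name, rep_cfg)
        statuses[report.final_status] = statuses.get(report.final_status, 0) + 1
        if report.final_status == "nonconvergent":
            nonconv += 1
            continue
        if report.initial is not None:
            a0 = report.initial.assessment
            q_ps.append(a0.q_p)
            for ind in a0.outliers:
                flags[sc.indicator_names.index(ind)] += 1
            fit0 = report.initial.fit
            b_hats.append(fit0["b"])
            b_ses.append(fit0.se_of("b"))
            rgs.append(report.gate["rg_cp"])

    q_ps_arr = np.asarray(q_ps)
    n_assessed = max(len(q_ps), 1)
    summary = {
        "scenario_K": sc.K,
        "replicates": replicates,
        "n_assessed": len(q_ps),
        "nonconvergent": nonconv,
        "statuses": statuses,
        "q_rejection": {
            str(a): float(np.mean(q_ps_arr < a)) if len(q_ps) else float("nan") for a in alphas
        },
        "ks_stat": float("nan"),
        "ks_p": float("nan"),
        "flag_rate": (flags / n_assessed).tolist(),
        "mean_rg": float(np.mean(rgs)) if rgs else float("nan"),
        "sd_rg": float(np.std(rgs, ddof=1)) if len(rgs) > 1 else float("nan"),
        "mean_b": float(np.mean(b_hats)) if b_hats else float("nan"),
        "sd_b": float(np.std(b_hats, ddof=1)) if len(b_hats) > 1 else float("nan"),
        "mean_se_b": float(np.mean(b_ses)) if b_ses else float("nan"),
    }
    if len(q_ps) > 1:
        ks = stats.kstest(q_ps_arr, "uniform")
        summary["ks_stat"] = float(ks.statistic)
        summary["ks_p"] = float(ks.pvalue)
    if summary["sd_b"] > 0 and summary["mean_se_b"] > 0:
        summary["se_ratio"] = summary["mean_se_b"] / summary["sd_b"]
    else:
        summary["se_ratio"] = float("nan")
    return summary
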