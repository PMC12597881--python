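"""Heterogeneity statistics: residual genetic correlations, lSRMR, outliers.

A fitted common-pathway (or follow-up) model implies genetic correlations
between the external correlate and each indicator.  The residual

    rg_residual_k = rg_observed_k - rg_implied_k

localizes misfit to indicator k; the local standardized root mean squared
residual

    lSRMR = sqrt( (1/K) * sum_k rg_residual_k^2 )

is its global effect-size companion to the Q_Trait significance test.
Meaningful heterogeneity requires the lSRMR to clear two thresholds at once:
an absolute cutoff (default 0.10, conventional for SRMR-type misfit) and a
context-specific cutoff set as a proportion (default 25%) of the root mean
square observed correlate-indicator correlation.  The same dual rule, applied
per indicator to |rg_residual_k|, flags outlying indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .covstruct import CovStruct, to_correlation
from .dwls import FitResult

__all__ = [
    "HeterogeneityAssessment",
    "residual_rg",
    "lsrmr",
    "context_threshold",
    "detect_outliers",
    "assess_heterogeneity",
]

DEFAULT_ABS_THRESHOLD = 0.10
DEFAULT_CONTEXT_PROPORTION = 0.25


@dataclass
class HeterogeneityAssessment:
    q_trait: float
    q_df: int
    q_p: float
    rg_observed: np.ndarray
    rg_implied: np.ndarray
    rg_residual: np.ndarray
    lsrmr: float
    abs_threshold: float
    context_threshold: float
    context_proportion: float
    outliers: list[str] = field(default_factory=list)
    most_extreme: str | None = None
    heterogeneous: bool = False


def residual_rg(
    cs: CovStruct,
    fit: FitResult,
    correlate: str,
    indicators: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed, implied and residual correlate-indicator genetic correlations.

    Observed values standardize the input S; implied values standardize the
    fitted model's implied covariance with its own implied variances, so a
    freed direct path drives that indicator's residual to ~0.
    """
    if not fit.converged:
        raise ValueError("residual_rg requires a converged fit")
    sub = cs.subset(list(indicators) + [correlate])
    R_obs = to_correlation(sub)
    K = len(indicators)
    rg_obs = R_obs[K, :K].copy()

    sigma = fit.sigma_hat
    d = np.diag(sigma)
    if np.any(d <= 0):
        bad = [
            fit.spec.variable_names[i] for i in np.flatnonzero(d <= 0)
        ]
        raise ValueError(
            f"non-positive implied variance for {bad} (Heywood solution); "
            "implied correlations are undefined"
        )
    inv_sd = 1.0 / np.sqrt(d)
    R_imp = sigma * np.outer(inv_sd, inv_sd)
    # map fit variable order onto the requested indicator order
    pos = [fit.spec.variable_names.index(n) for n in indicators]
    tpos = fit.spec.variable_names.index(correlate)
    rg_imp = R_imp[tpos, pos]
    return rg_obs, rg_imp, rg_obs - rg_imp


def lsrmr(rg_residual: Sequence[float]) -> float:
    """Root mean square of the residual genetic correlations."""
    r = np.asarray(rg_residual, dtype=float)
    if r.size == 0:
        raise ValueError("lsrmr requires at least one residual")
    return float(np.sqrt(np.mean(r**2)))


def context_threshold(
    rg_observed: Sequence[float], proportion: float = DEFAULT_CONTEXT_PROPORTION
) -> float:
    """proportion x root-mean-square observed correlate-indicator correlation."""
    r = np.asarray(rg_observed, dtype=float)
    if r.size == 0:
        raise ValueError("context_threshold requires at least one correlation")
    if not (0 < proportion <= 1):
        raise ValueError("proportion must be in (0, 1]")
    return float(proportion * np.sqrt(np.mean(r**2)))


def detect_outliers(
    rg_residual: Sequence[float],
    abs_threshold: float,
    ctx_threshold: float,
    indicator_names: Sequence[str] | None = None,
) -> tuple[list[str], str | None]:
    """Dual-threshold outlier rule on |residual| with strict inequalities.

    Indicator k is flagged iff |rg_residual_k| exceeds BOTH thresholds
    strictly; the most extreme outlier is the flagged indicator with the
    largest absolute residual (ties broken by lowest position).
    """
    r = np.abs(np.asarray(rg_residual, dtype=float))
    if indicator_names is None:
        indicator_names = [f"y{k + 1}" for k in range(r.size)]
    names = list(indicator_names)
    flagged = [k for k in range(r.size) if r[k] > abs_threshold and r[k] > ctx_threshold]
    if not flagged:
        return [], None
    most = max(flagged, key=lambda k: (r[k], -k))
    return [names[k] for k in flagged], names[most]


def assess_heterogeneity(
    q_trait: float,
    q_df: int,
    q_p: float,
    lsrmr_value: float,
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
    ctx_threshold: float = 0.0,
    alpha_q: float = 0.05,
) -> bool:
    """Combined decision: significant Q_Trait AND lSRMR above both thresholds."""
    if q_df <= 0:
        return False
    return bool(
        (q_p < alpha_q) and (lsrmr_value > abs_threshold) and (lsrmr_value > ctx_threshold)
    )


def assess(
    cs: CovStruct,
    fit_current: FitResult,
    fit_ip: FitResult,
    correlate: str,
    indicators: Sequence[str],
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
    context_proportion: float = DEFAULT_CONTEXT_PROPORTION,
    alpha_q: float = 0.05,
    ctx_threshold: float | None = None,
) -> HeterogeneityAssessment:
    """Full assessment of one fitted model against the independent-pathways fit."""
    from .dwls import chisq_diff

    if fit_current.df - fit_ip.df <= 0:
        # nothing left to test (all K-1 direct paths freed)
        q, q_df, q_p = 0.0, 0, 1.0
    else:
        q, q_df, q_p = chisq_diff(fit_ip, fit_current)
    rg_obs, rg_imp, rg_res = residual_rg(cs, fit_current, correlate, indicators)
    l = lsrmr(rg_res)
    if ctx_threshold is None:
        ctx_threshold = context_threshold(rg_obs, context_proportion)
    outliers, most = detect_outliers(rg_res, abs_threshold, ctx_threshold, indicators)
    het = assess_heterogeneity(q, q_df, q_p, l, abs_threshold, ctx_threshold, alpha_q)
    return HeterogeneityAssessment(
        q_trait=q,
        q_df=q_df,
        q_p=q_p,
        rg_observed=rg_obs,
        rg_implied=rg_imp,
        rg_residual=rg_res,
        lsrmr=l,
        abs_threshold=abs_threshold,
        context_threshold=ctx_threshold,
        context_proportion=context_proportion,
        outliers=outliers,
        most_extreme=most,
        heterogeneous=het,
    )
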