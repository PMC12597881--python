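"""Automated heterogeneity workflow per external correlate.

For each correlate the workflow (i) fits the common-pathway model and gates
on the Bonferroni-corrected significance of the correlate-factor regression;
(ii) fits the independent-pathways model and computes Q_Trait, residual
genetic correlations and the lSRMR with its dual thresholds; (iii) while
meaningful heterogeneity persists, frees an unconstrained direct path to the
most extreme outlying indicator and refits, stopping when heterogeneity
resolves, the correlate-factor association is absorbed, or the number of
freed paths exceeds a set proportion of the indicators (widespread
heterogeneity).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .covstruct import CovStruct, to_correlation
from .dwls import FitOptions, FitResult, fit_dwls
from .factor_models import build_model
from .heterogeneity import (
    DEFAULT_ABS_THRESHOLD,
    DEFAULT_CONTEXT_PROPORTION,
    HeterogeneityAssessment,
    assess,
    context_threshold,
)

__all__ = [
    "QTraitConfig",
    "CorrelateReport",
    "bonferroni_threshold",
    "run_correlate",
    "run_all",
    "export_report",
]


@dataclass
class QTraitConfig:
    alpha: float = 0.05
    alpha_q: float = 0.05
    abs_threshold: float = DEFAULT_ABS_THRESHOLD
    context_proportion: float = DEFAULT_CONTEXT_PROPORTION
    max_free_proportion: float = 0.5
    max_restarts: int = 10
    tolerance: float = 1e-10
    seed: int = 0
    n_correlates: int = 1  # used for the Bonferroni gate


@dataclass
class IterationRecord:
    freed_paths: list[str]
    fit: FitResult
    assessment: HeterogeneityAssessment


@dataclass
class CorrelateReport:
    correlate: str
    gate: dict
    iterations: list[IterationRecord] = field(default_factory=list)
    final_status: str = "nonconvergent"
    final_rg: float = float("nan")
    final_rg_se: float = float("nan")
    final_rg_p: float = float("nan")
    lsrmr_reduction_pct: float | None = None
    outlying_indicators: list[str] = field(default_factory=list)

    @property
    def initial(self) -> IterationRecord | None:
        return self.iterations[0] if self.iterations else None

    @property
    def final(self) -> IterationRecord | None:
        return self.iterations[-1] if self.iterations else None


def bonferroni_threshold(alpha: float, n_correlates: int) -> float:
    """Per-correlate significance threshold alpha / n_correlates."""
    if n_correlates < 1:
        raise ValueError("n_correlates must be >= 1")
    return alpha / n_correlates


def _rg_and_se(fit: FitResult) -> tuple[float, float, float]:
    """Standardized correlate-factor association (rG) with an SE and p-value.

    The SE carries over the unstandardized b's sandwich SE through the
    standardization factor, treating the fitted variances as fixed.
    """
    rg = float(fit.std_solution["rg_correlate_factor"])
    b = fit["b"]
    se_b = fit.se_of("b")
    scale = abs(rg / b) if b != 0 else float("nan")
    return rg, se_b * scale, fit.wald_p("b")


def run_correlate(
    cs: CovStruct,
    indicators: Sequence[str],
    correlate: str,
    config: QTraitConfig | None = None,
) -> CorrelateReport:
    """Run the full gate / Q_Trait / iterative path-freeing workflow."""
    config = config or QTraitConfig()
    indicators = list(indicators)
    K = len(indicators)
    gate_p_threshold = bonferroni_threshold(config.alpha, config.n_correlates)
    opts = FitOptions(
        max_restarts=config.max_restarts, tolerance=config.tolerance, seed=config.seed
    )

    report = CorrelateReport(correlate=correlate, gate={})

    cp_spec = build_model(indicators, correlate, "common_pathway")
    cp_fit = fit_dwls(cp_spec, cs, opts)
    if not cp_fit.converged:
        report.gate = {"passed": False, "bonferroni_threshold": gate_p_threshold}
        report.final_status = "nonconvergent"
        return report

    rg_cp, se_cp, p_cp = _rg_and_se(cp_fit)
    gate_passed = p_cp < gate_p_threshold
    report.gate = {
        "rg_cp": rg_cp,
        "se": se_cp,
        "p": p_cp,
        "passed": gate_passed,
        "bonferroni_threshold": gate_p_threshold,
    }
    report.final_rg, report.final_rg_se, report.final_rg_p = rg_cp, se_cp, p_cp
    if not gate_passed:
        report.final_status = "not_significant"
        return report

    ip_spec = build_model(indicators, correlate, "independent_pathways")
    ip_fit = fit_dwls(ip_spec, cs, opts)
    if not ip_fit.converged:
        report.final_status = "nonconvergent"
        return report

    # the context threshold uses OBSERVED correlations: fixed across iterations
    sub = cs.subset(indicators + [correlate])
    rg_obs_all = to_correlation(sub)[K, :K]
    ctx = context_threshold(rg_obs_all, config.context_proportion)

    freed: list[str] = []
    current_fit = cp_fit
    while True:
        try:
            assessment = assess(
                cs,
                current_fit,
                ip_fit,
                correlate,
                indicators,
                abs_threshold=config.abs_threshold,
                context_proportion=config.context_proportion,
                alpha_q=config.alpha_q,
                ctx_threshold=ctx,
            )
        except ValueError as exc:
            warnings.warn(f"assessment failed for {correlate}: {exc}")
            report.final_status = "nonconvergent"
            return report
        report.iterations.append(IterationRecord(list(freed), current_fit, assessment))

        if not assessment.heterogeneous:
            report.final_status = "corrected" if freed else "homogeneous"
            break

        nxt = assessment.most_extreme
        if nxt is None or nxt in freed or len(freed) >= K - 1:
            # cannot free further: treat as widespread misfit
            report.final_status = "widespread_heterogeneity"
            break
        freed = freed + [nxt]
        if len(freed) > config.max_free_proportion * K:
            report.final_status = "widespread_heterogeneity"
            report.outlying_indicators = freed
            break

        fu_spec = build_model(indicators, correlate, "followup", freed)
        fu_fit = fit_dwls(fu_spec, cs, opts)
        if not fu_fit.converged:
            report.final_status = "nonconvergent"
            break
        current_fit = fu_fit
        rg, se, p = _rg_and_se(fu_fit)
        report.final_rg, report.final_rg_se, report.final_rg_p = rg, se, p
        if p >= gate_p_threshold:
            report.final_status = "association_absorbed"
            report.outlying_indicators = freed
            # record the final model's assessment for completeness
            try:
                final_assess = assess(
                    cs, fu_fit, ip_fit, correlate, indicators,
                    abs_threshold=config.abs_threshold,
                    context_proportion=config.context_proportion,
                    alpha_q=config.alpha_q, ctx_threshold=ctx,
                )
                report.iterations.append(IterationRecord(list(freed), fu_fit, final_assess))
            except ValueError:
                pass
            break

    if not report.outlying_indicators:
        report.outlying_indicators = list(report.iterations[-1].freed_paths)
    if report.iterations and report.iterations[-1].freed_paths:
        l0 = report.iterations[0].assessment.lsrmr
        lf = report.iterations[-1].assessment.lsrmr
        if l0 > 0:
            report.lsrmr_reduction_pct = 100.0 * (l0 - lf) / l0
    return report


def run_all(
    cs: CovStruct,
    indicators: Sequence[str],
    correlates: Sequence[str],
    config: QTraitConfig | None = None,
) -> list[CorrelateReport]:
    """Run every correlate with a Bonferroni gate over the full correlate list."""
    correlates = list(correlates)
    if not correlates:
        raise ValueError("correlates list is empty")
    overlap = set(correlates) & set(indicators)
    if overlap:
        raise ValueError(f"correlates overlap indicators: {sorted(overlap)}")
    config = config or QTraitConfig()
    reports = []
    for corr in correlates:
        cfg = QTraitConfig(**{**asdict(config), "n_correlates": len(correlates)})
        reports.append(run_correlate(cs, indicators, corr, cfg))
    return reports


def _fmt(x, nd=6):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "-"
    return f"{x:.{nd}g}" if isinstance(x, float) else str(x)


def export_report(
    reports: Sequence[CorrelateReport],
    destination: str | Path,
    cs: CovStruct | None = None,
    config: QTraitConfig | None = None,
) -> dict[str, Path]:
    """Write the summary TSV, per-correlate detail TSVs and a JSON run log.

    The summary mirrors the standard results-table layout: gate rG (SE),
    Q_Trait (df, p) and lSRMR from the common-pathway comparison, then the
    final follow-up columns, lSRMR reduction (computed on unrounded values)
    and the freed outlying indicators.  Non-heterogeneous correlates get "-"
    placeholders in the follow-up columns.
    """
    if not reports:
        raise ValueError("no reports to export")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = []
    for rep in reports:
        a0 = rep.initial.assessment if rep.initial else None
        had_followup = rep.final is not None and bool(rep.final.freed_paths)
        af = rep.final.assessment if had_followup else None
        rows.append(
            {
                "correlate": rep.correlate,
                "rG_cp": _fmt(rep.gate.get("rg_cp")),
                "SE_cp": _fmt(rep.gate.get("se")),
                "p_cp": _fmt(rep.gate.get("p")),
                "Q_trait": _fmt(a0.q_trait if a0 else None),
                "df": _fmt(a0.q_df if a0 else None),
                "p": _fmt(a0.q_p if a0 else None),
                "lSRMR": _fmt(a0.lsrmr if a0 else None),
                "rG_followup": _fmt(rep.final_rg if had_followup else None),
                "SE_followup": _fmt(rep.final_rg_se if had_followup else None),
                "Q_followup": _fmt(af.q_trait if af else None),
                "df_followup": _fmt(af.q_df if af else None),
                "lSRMR_followup": _fmt(af.lsrmr if af else None),
                "reduction_pct": (
                    f"{rep.lsrmr_reduction_pct:.2f}" if rep.lsrmr_reduction_pct is not None else "-"
                ),
                "outlying_indicators": (
                    ",".join(rep.outlying_indicators) if rep.outlying_indicators else "-"
                ),
                "status": rep.final_status,
            }
        )
    summary = dest / "summary.tsv"
    pd.DataFrame(rows).to_csv(summary, sep="\t", index=False)
    written["summary"] = summary

    warn_log: list[str] = []
    for rep in reports:
        if not rep.iterations:
            continue
        indicators = rep.initial.fit.spec.indicator_names
        detail_rows = []
        for it_idx, rec in enumerate(rep.iterations):
            a = rec.assessment
            for k, ind in enumerate(indicators):
                detail_rows.append(
                    {
                        "iteration": it_idx,
                        "freed_paths": ",".join(rec.freed_paths) or "-",
                        "indicator": ind,
                        "rg_observed": f"{a.rg_observed[k]:.8g}",
                        "rg_implied": f"{a.rg_implied[k]:.8g}",
                        "rg_residual": f"{a.rg_residual[k]:.8g}",
                    }
                )
        f = dest / f"residuals_{rep.correlate}.tsv"
        pd.DataFrame(detail_rows).to_csv(f, sep="\t", index=False)
        written[f"residuals_{rep.correlate}"] = f

        if cs is not None:
            # observed per-indicator regression betas vs unstandardized loadings,
            # with inverse-variance weights from diag(V)
            sub = cs.subset(indicators + [rep.correlate])
            K = len(indicators)
            stt = sub.S[K, K]
            fit0 = rep.initial.fit
            lam_idx = {
                ind: fit0.param_names.index(f"lambda[{ind}]")
                for ind in indicators
                if f"lambda[{ind}]" in fit0.param_names
            }
            from .covstruct import vech_index

            beta_rows = []
            for k, ind in enumerate(indicators):
                cov_idx = vech_index(K, k, K + 1)  # element cov(T, y_k) in sub vech
                var_sty = sub.V[cov_idx, cov_idx]
                lam_k = 1.0 if ind == indicators[0] else float(fit0.theta_hat[lam_idx[ind]])
                beta_rows.append(
                    {
                        "indicator": ind,
                        "beta_observed": f"{sub.S[K, k] / stt:.8g}",
                        "loading_unstd": f"{lam_k:.8g}",
                        "inv_variance_weight": f"{(1.0 / var_sty if var_sty > 0 else np.inf):.8g}",
                    }
                )
            f = dest / f"betas_{rep.correlate}.tsv"
            pd.DataFrame(beta_rows).to_csv(f, sep="\t", index=False)
            written[f"betas_{rep.correlate}"] = f

    log = {
        "config": asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "versions": {"qtraitsem": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "warnings": warn_log,
        "correlates": [rep.correlate for rep in reports],
        "statuses": {rep.correlate: rep.final_status for rep in reports},
    }
    logf = dest / "run_log.json"
    with open(logf, "w") as fh:
        json.dump(log, fh, indent=1)
    written["run_log"] = logf
    return written
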