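"""Single-factor measurement models with an external correlate.

Three topologies over K indicator phenotypes y_1..y_K, one latent factor F
and one external trait T:

``common_pathway``
    y_k = lambda_k * F + e_k,  F = b * T + u.  All association between T and
    the indicators is mediated by the factor.

``independent_pathways``
    y_k = lambda_k * F + d_k * T + e_k, with cov(T, F) fixed at 0.  The
    T-indicator covariance block is saturated by the K direct effects d_k.

``followup``
    The common-pathway model augmented with unconstrained direct paths
    d_k * T for a proper subset of indicators (at most K-1, else the block
    saturates and the model collapses to independent pathways).

Identification is by unit loading (lambda_1 = 1, factor residual variance psi
free) by default; a unit-variance convention (all loadings free, var(F) = 1)
is available to check that standardized output does not depend on the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .covstruct import vech

__all__ = ["ModelSpec", "Parameter", "build_model", "implied_sigma", "implied_sigma_jacobian"]

Topology = Literal["common_pathway", "independent_pathways", "followup"]
Identification = Literal["unit_loading", "unit_variance"]


@dataclass(frozen=True)
class Parameter:
    name: str
    kind: str  # loading | factor_regression | direct_effect |
    #            factor_residual_variance | indicator_residual_variance | correlate_variance
    bounds: tuple[float | None, float | None] = (None, None)


@dataclass
class ModelSpec:
    indicator_names: list[str]
    correlate_name: str
    topology: Topology
    direct_paths: list[str] = field(default_factory=list)
    identification: Identification = "unit_loading"
    free_parameters: list[Parameter] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.indicator_names)

    @property
    def variable_names(self) -> list[str]:
        """Indicators first, correlate last — the order of implied_sigma."""
        return self.indicator_names + [self.correlate_name]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    def param_index(self, name: str) -> int:
        for i, par in enumerate(self.free_parameters):
            if par.name == name:
                return i
        raise KeyError(f"no free parameter named {name!r}")

    def describe(self) -> str:
        """Human-readable path list (debug dump)."""
        lines = [f"topology: {self.topology} ({self.identification})"]
        for k, ind in enumerate(self.indicator_names):
            lines.append(f"  F -> {ind}  (lambda_{k + 1}{' = 1' if k == 0 and self.identification == 'unit_loading' else ''})")
        if self.topology != "independent_pathways":
            lines.append(f"  {self.correlate_name} -> F  (b)")
        for ind in self.direct_paths:
            lines.append(f"  {self.correlate_name} -> {ind}  (direct)")
        return "\n".join(lines)


def build_model(
    indicators: Sequence[str],
    correlate: str,
    topology: Topology,
    direct_paths: Sequence[str] = (),
    identification: Identification = "unit_loading",
) -> ModelSpec:
    """Construct a validated ModelSpec with its ordered free-parameter list.

    Free-parameter counts (unit-loading identification): common pathway has
    2K+2 ((K-1) loadings, K indicator residuals, factor residual psi, factor
    regression b, correlate variance phi); a follow-up model adds one direct
    effect per freed path; independent pathways has 3K+1 ((K-1) loadings,
    psi, K direct effects, K residuals, phi).
    """
    indicators = list(indicators)
    direct_paths = list(direct_paths)
    K = len(indicators)
    if K < 3:
        raise ValueError(f"need at least 3 indicators to identify the factor, got {K}")
    if len(set(indicators)) != K:
        raise ValueError("indicator names must be unique")
    if correlate in indicators:
        raise ValueError(f"correlate {correlate!r} is also an indicator")
    unknown = set(direct_paths) - set(indicators)
    if unknown:
        raise ValueError(f"direct_paths not among indicators: {sorted(unknown)}")
    if topology in ("common_pathway", "independent_pathways") and direct_paths:
        raise ValueError(f"direct_paths must be empty for topology={topology}")
    if topology == "followup":
        if not direct_paths:
            raise ValueError("followup topology requires at least one freed direct path")
        if len(direct_paths) > K - 1:
            raise ValueError(
                f"{len(direct_paths)} direct paths with K={K} indicators is "
                "saturated; use independent_pathways"
            )
    # keep freed paths in indicator order for a deterministic parameter layout
    direct_paths = [ind for ind in indicators if ind in set(direct_paths)]

    params: list[Parameter] = []
    first_free_loading = 1 if identification == "unit_loading" else 0
    for ind in indicators[first_free_loading:]:
        params.append(Parameter(f"lambda[{ind}]", "loading"))
    if identification == "unit_loading":
        params.append(Parameter("psi", "factor_residual_variance"))
    if topology != "independent_pathways":
        params.append(Parameter("b", "factor_regression"))
    if topology == "independent_pathways":
        freed = indicators
    else:
        freed = direct_paths
    for ind in freed:
        params.append(Parameter(f"d[{ind}]", "direct_effect"))
    for ind in indicators:
        params.append(Parameter(f"theta[{ind}]", "indicator_residual_variance"))
    params.append(Parameter("phi", "correlate_variance"))

    names = [p.name for p in params]
    assert len(set(names)) == len(names)
    return ModelSpec(indicators, correlate, topology, direct_paths, identification, params)


def _unpack(spec: ModelSpec, theta: np.ndarray):
    """Map the free-parameter vector onto (lam, psi, b, d, resid, phi).

    Under unit-variance identification psi is the implicit value making
    var(F) = 1, i.e. psi = 1 - b^2 * phi.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise ValueError(f"theta must have length {spec.n_free}, got {theta.shape}")
    K = spec.K
    lam = np.empty(K)
    d = np.zeros(K)
    resid = np.empty(K)
    psi = np.nan
    b = 0.0
    phi = np.nan
    ind_pos = {ind: k for k, ind in enumerate(spec.indicator_names)}
    for value, par in zip(theta, spec.free_parameters):
        if par.kind == "loading":
            lam[ind_pos[par.name[7:-1]]] = value
        elif par.kind == "factor_residual_variance":
            psi = value
        elif par.kind == "factor_regression":
            b = value
        elif par.kind == "direct_effect":
            d[ind_pos[par.name[2:-1]]] = value
        elif par.kind == "indicator_residual_variance":
            resid[ind_pos[par.name[6:-1]]] = value
        elif par.kind == "correlate_variance":
            phi = value
    if spec.identification == "unit_loading":
        lam[0] = 1.0
    else:
        psi = 1.0 - b * b * phi
    return lam, psi, b, d, resid, phi


def implied_sigma(spec: ModelSpec, theta: Sequence[float]) -> np.ndarray:
    """Model-implied covariance over (y_1, ..., y_K, T).

    With a_k = lambda_k * b + d_k the reduced form is
    y_k = a_k * T + lambda_k * u + e_k, giving

        cov(y_j, y_k) = a_j a_k phi + lambda_j lambda_k psi  (+ theta_k if j=k)
        cov(T,  y_k)  = a_k phi = b phi lambda_k + d_k phi
        var(T)        = phi

    so the correlate-indicator covariances under the common pathway model are
    exactly proportional to the unstandardized loadings with constant b*phi.
    Negative psi/theta_k (Heywood solutions) are representable; flagging them
    is the fitting engine's job.
    """
    lam, psi, b, d, resid, phi = _unpack(spec, np.asarray(theta, dtype=float))
    K = spec.K
    a = lam * b + d
    sigma = np.empty((K + 1, K + 1))
    sigma[:K, :K] = np.outer(a, a) * phi + np.outer(lam, lam) * psi
    sigma[:K, :K][np.diag_indices(K)] += resid
    sigma[K, :K] = sigma[:K, K] = a * phi
    sigma[K, K] = phi
    return sigma


def implied_sigma_jacobian(spec: ModelSpec, theta: Sequence[float]) -> np.ndarray:
    """Analytic Jacobian d vech(sigma) / d theta, shape (m, q).

    Built from the closed-form derivatives of the reduced-form covariance;
    under unit-variance identification the implicit psi = 1 - b^2 phi
    contributes chain-rule terms to the b and phi columns.
    """
    theta = np.asarray(theta, dtype=float)
    lam, psi, b, d, resid, phi = _unpack(spec, theta)
    K = spec.K
    a = lam * b + d
    ind_pos = {ind: k for k, ind in enumerate(spec.indicator_names)}

    cols = []
    for par in spec.free_parameters:
        dS = np.zeros((K + 1, K + 1))
        if par.kind == "loading":
            i = ind_pos[par.name[7:-1]]
            da = np.zeros(K)
            da[i] = b
            dlam = np.zeros(K)
            dlam[i] = 1.0
            blk = (np.outer(da, a) + np.outer(a, da)) * phi + (
                np.outer(dlam, lam) + np.outer(lam, dlam)
            ) * psi
            dS[:K, :K] = blk
            dS[K, :K] = dS[:K, K] = da * phi
        elif par.kind == "factor_residual_variance":
            dS[:K, :K] = np.outer(lam, lam)
        elif par.kind == "factor_regression":
            da = lam
            dS[:K, :K] = (np.outer(da, a) + np.outer(a, da)) * phi
            dS[K, :K] = dS[:K, K] = da * phi
            if spec.identification == "unit_variance":
                dS[:K, :K] += np.outer(lam, lam) * (-2.0 * b * phi)
        elif par.kind == "direct_effect":
            i = ind_pos[par.name[2:-1]]
            da = np.zeros(K)
            da[i] = 1.0
            dS[:K, :K] = (np.outer(da, a) + np.outer(a, da)) * phi
            dS[K, :K] = dS[:K, K] = da * phi
        elif par.kind == "indicator_residual_variance":
            i = ind_pos[par.name[6:-1]]
            dS[i, i] = 1.0
        elif par.kind == "correlate_variance":
            dS[:K, :K] = np.outer(a, a)
            dS[K, :K] = dS[:K, K] = a
            dS[K, K] = 1.0
            if spec.identification == "unit_variance":
                dS[:K, :K] += np.outer(lam, lam) * (-b * b)
        cols.append(vech(dS))
    return np.column_stack(cols)
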