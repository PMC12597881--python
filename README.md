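# qtraitsem

Heterogeneity diagnostics for genomic structural equation models.

Genomic SEM represents the shared genetic architecture of a set of GWAS
phenotypes with a common factor fit to an LDSC-derived genetic covariance
matrix **S** (heritabilities on the diagonal, coheritabilities off it) and its
sampling covariance **V**. When that factor is regressed on the genetic
component of an external trait, the model assumes every association between
the external trait and the individual indicator phenotypes is mediated by the
factor — the *common pathway* assumption. `qtraitsem` tests that assumption,
quantifies how badly it fails, locates the indicators responsible, and
automates the corrective re-specification. It is aimed at statistical
geneticists who work with multivariate GWAS summary statistics.

## The statistics

Models are fit to **S** by diagonally weighted least squares,

$$F_{\mathrm{WLS}}(\theta) = (s - \sigma(\theta))' D_S^{-1} (s - \sigma(\theta)),$$

where $s$ and $\sigma(\theta)$ are the half-vectorized observed and
model-implied covariances and $D_S$ is the diagonal of **V**. Parameter
uncertainty uses the sandwich estimator
$V_\theta = (\Delta' \Gamma^{-1}\Delta)^{-1} \Delta'\Gamma^{-1} V \Gamma^{-1}
\Delta (\Delta'\Gamma^{-1}\Delta)^{-1}$ with $\Gamma = D_S$, which stays
valid although the weights are only the diagonal of **V**.

Under the common pathway model the external trait's covariance with indicator
$k$ is $b_{T,F}\,\phi\,\lambda_k$ — exactly proportional to the unstandardized
loading. **Q_Trait** is the χ² difference between this model and an
*independent pathways* model that saturates the trait–indicator covariances
with K direct effects; it has K−1 degrees of freedom. Its effect-size
companion is the local standardized root mean squared residual,

$$\mathrm{lSRMR} = \sqrt{\tfrac{1}{K}\sum_k \mathrm{rg}_{\mathrm{residual},k}^2},
\qquad
\mathrm{rg}_{\mathrm{residual},k} = \mathrm{rg}_{\mathrm{observed},k} - \mathrm{rg}_{\mathrm{implied},k}.$$

Heterogeneity is declared only when Q_Trait is significant **and** the lSRMR
exceeds both an absolute threshold (default 0.10) and a context-specific one
(default 25% of the root mean square observed correlation). The same dual
rule applied per indicator flags outliers; the workflow then frees an
unconstrained direct path to the most extreme outlier and refits, iterating
until heterogeneity resolves, the factor association is absorbed, or freed
paths exceed half the indicators (widespread heterogeneity).

Because real applications require multivariate LDSC on external GWAS summary
statistics, the package ships a synthetic generator that emulates LDSC output
— `s ~ MVN(vech(Σ_true), V)` with normal-theory SE magnitudes and
sample-overlap-style correlation in **V** — so the whole pipeline is testable
against known ground truth.

## Worked example

A K=3 disease-style factor whose third indicator (think: a proxy-phenotype
GWAX of family history) carries a planted direct effect that flips the sign
of its observed correlation with the external trait:

```python
import numpy as np
from qtraitsem import preset, simulate_covstruct, run_correlate, QTraitConfig

sc = preset("ad_like")          # K=3 factor, one sign-flipped proxy indicator
sc.seed = 42
cs = simulate_covstruct(sc)     # one LDSC-style (S, V) draw
report = run_correlate(cs, sc.indicator_names, "T", QTraitConfig(seed=1))

a0 = report.iterations[0].assessment
print(f"gate rG = {report.gate['rg_cp']:.3f} (SE {report.gate['se']:.3f}, p = {report.gate['p']:.2e})")
print(f"Q_Trait({a0.q_df}) = {a0.q_trait:.2f}, p = {a0.q_p:.2e}; lSRMR = {a0.lsrmr:.3f} "
      f"(abs 0.10, context {a0.context_threshold:.3f})")
print(f"residual rg: {np.round(a0.rg_residual, 3)}")
print(f"outliers: {a0.outliers}; freed: {report.outlying_indicators}")
print(f"status = {report.final_status}; final rG = {report.final_rg:.3f} "
      f"(SE {report.final_rg_se:.3f}); lSRMR reduction = {report.lsrmr_reduction_pct:.1f}%")
```

prints

```
gate rG = -0.278 (SE 0.037, p = 4.90e-14)
Q_Trait(2) = 74.82, p = 5.66e-17; lSRMR = 0.144 (abs 0.10, context 0.060)
residual rg: [-0.038 -0.101  0.224]
outliers: ['y2', 'y3']; freed: ['y3']
status = corrected; final rG = -0.388 (SE 0.042); lSRMR reduction = 85.6%
```

Reading this: the common-pathway fit passes the significance gate
(rG = −0.28), but Q_Trait rejects factor mediation and the lSRMR (0.144)
clears both thresholds, driven by indicator 3's +0.22 residual correlation.
The workflow frees a direct path to `y3` and refits; heterogeneity resolves
("corrected"), and the correlate–factor association *strengthens* to −0.39 —
the sign-discordant proxy indicator had been diluting it. In the K=7
`g_like` preset the same correction attenuates the association instead: the
procedure is direction-agnostic.

The same run is available from the shell:

```bash
qtrait simulate --preset ad_like --seed 42 --out sim/
qtrait run --covstruct sim/covstruct.json --indicators y1,y2,y3 \
           --correlates T --seed 1 --out results/
qtrait calibrate --preset null_k5 --replicates 500 --seed 1 --out cal/
```

`qtrait run` writes a summary table (gate rG/SE, Q_Trait, lSRMR, follow-up
columns, lSRMR reduction, outlying indicators), per-correlate tables of
observed/implied/residual correlations and of observed betas vs
unstandardized loadings, and a JSON run log with the resolved configuration.

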