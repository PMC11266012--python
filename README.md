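# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, allele harmonization, the standard five-estimator
panel, sensitivity analyses, multivariable MR, and two-step mediation with
product-of-coefficients effect decomposition — plus a seeded synthetic-GWAS
generator with known causal truth for calibration and recovery testing.

It is aimed at epidemiologists running summary-level causal analyses of the
"many exposures, one disease outcome" kind — the motivating design is a
screen of obesity and lipid-metabolism traits against non-suppurative
(secretory) otitis media (NSOM), with HDL cholesterol and apolipoprotein A1
as candidate mediators — but every component is trait-agnostic.

## The statistics

Genetic variants are used as instrumental variables. For instrument *j* with
exposure association $\hat\gamma_j$ (SE $\sigma_{X_j}$) and outcome
association $\hat\Gamma_j$ (SE $\sigma_{Y_j}$), the per-SNP Wald ratio is
$\hat\beta_j = \hat\Gamma_j/\hat\gamma_j$. The panel:

* **IVW** (main method): $\hat\beta = \sum_j w_j\hat\gamma_j\hat\Gamma_j /
  \sum_j w_j\hat\gamma_j^2$ with $w_j = \sigma_{Y_j}^{-2}$ — weighted
  regression through the origin. Multiplicative random effects by default:
  the SE is inflated by $\max(1, \sqrt{Q/(k-1)})$, with $Q$ Cochran's
  heterogeneity statistic.
* **MR-Egger**: the same regression with a free intercept; the intercept
  estimates directional pleiotropy (tested with $t_{k-2}$), the slope is
  the InSIDE-robust causal estimate.
* **Weighted median**: the weight-0.5 quantile of the sorted Wald ratios,
  valid when ≥ 50% of the weight comes from valid instruments.
* **Simple / weighted mode**: the argmax of a Gaussian-kernel density of the
  ratios, valid when the modal ratio cluster is valid. Bootstrap SEs.

A binary outcome puts all betas on the log-odds scale, so results carry
OR = exp(β) with 95% CI; IVW p < 0.05 with OR > 1 is read as a risk factor,
OR < 1 as protective, and an IVW p between 0.04 and 0.05 triggers a
leave-one-out analysis. Multivariable MR regresses outcome betas jointly on
several exposures' betas (no intercept, IVW weights) to estimate each
exposure's direct effect conditional on the others.

Two-step mediation for a chain X → M → Y estimates the total effect
`beta_all` (X→Y), the step effects `beta1` (X→M) and `beta2` (M→Y, with
step-1 instruments deleted from step 2), and decomposes:

```
beta12  = beta1 * beta2        # mediated (indirect) effect
beta_dir = beta_all - beta12   # direct effect
beta_per = beta12 / beta_all   # proportion mediated
```

declared only when both step IVW p-values are below 0.05.

## Worked example

Simulate a mediation chain with known truth (β1 = −0.2, β2 = −0.25, direct
effect 0.1, so the true total effect is 0.15 and the true proportion
mediated is 1/3), then run the full two-step analysis:

```python
from mrkit import SimulationConfig, simulate_mediation_chain, run_mediation
from mrkit.mediation import mediation_to_frame

cfg_xm = SimulationConfig(k=50, true_beta=-0.2, seed=11)   # X -> M
cfg_my = SimulationConfig(k=50, true_beta=-0.25, seed=12)  # M -> Y
tx, tm, ty, truth = simulate_mediation_chain(cfg_xm, cfg_my,
                                             direct_effect=0.1, seed=13, overlap=10)
run = run_mediation(tx, tm, ty)
print(mediation_to_frame([run.result]).to_string(index=False))
```

prints

```
exposure mediator outcome  beta_all  beta1  beta2  beta12  beta_dir  beta_per
exposure mediator outcome     0.152 -0.197 -0.248   0.049     0.103     0.321
```

— the estimated total effect 0.152 sits next to the generative 0.15, the
step estimates recover −0.2 and −0.25, and the proportion mediated 0.321 is
close to the true 1/3. Both step p-values are far below 0.05, so the
mediation gate passes.

The same decomposition can be re-derived from any table of step estimates:

```sh
mrkit rederive-table2 --inputs examples/table2_step_estimates.tsv
```

```
       exposure          mediator outcome  beta_all  beta1  beta2  beta12  beta_dir  beta_per
        obesity   hdl_cholesterol    nsom     0.162 -0.074 -0.216   0.016     0.146     0.099
        obesity apolipoprotein_a1    nsom     0.162 -0.045 -0.226   0.010     0.152     0.063
body_mass_index   hdl_cholesterol    nsom     0.317 -0.233 -0.214   0.050     0.267     0.157
body_mass_index apolipoprotein_a1    nsom     0.317 -0.184 -0.224   0.041     0.276     0.130
```

Both negative step effects compose into a positive mediated contribution:
an adiposity exposure that lowers a protective lipid fraction thereby
raises disease risk through it.

Batch studies (forward/reverse screens, MVMR groups, mediation chains) are
driven by a YAML config — see `examples/study_config.yaml` and the `mrkit
screen` / `mrkit full-study` subcommands.

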