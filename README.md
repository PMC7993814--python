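# hopitx

Hierarchical ordered probit (HOPIT) models for anchoring-vignette
surveys, including an extended variant that is robust to
**heteroskedastic vignette perceptions**.

## The problem

Self-assessed measures ("how much difficulty do you have seeing across
the road?") are not comparable across people who use different response
scales. Anchoring vignettes — short descriptions of hypothetical
persons that everyone rates on the same scale — identify those scale
differences. The HOPIT model formalises this: a latent condition
*y\* = β′x + ε* is classified through respondent-specific cut-points
*τᵢᵏ* driven by covariates (*τᵢ¹ = γ₁′zᵢ + σᵤuᵢ*, increments
*exp(γₖ′zᵢ)*), and vignette ratings of known-common scenarios pin the
cut-points down.

Standard HOPIT assumes every respondent perceives a vignette equally
precisely (*V\*ᵢⱼ = θⱼ + σᵥvᵢⱼ*). That is doubtful: a respondent whose
own condition resembles the vignette understands it concretely; one far
from it only abstractly. The extended model makes the perception noise
grow with that distance,

    V*_ij = θ_j + σ_v · exp(α (y*_i − θ_j)²) · v_ij ,

so each respondent-vignette pair is effectively down-weighted by its
distance. α = 0 recovers the standard model, giving a χ²(1)
likelihood-ratio test of vignette equivalence. Estimation is by
simulated maximum likelihood: a 2-D Halton quasi-Monte Carlo rule
integrates the two latent disturbances, with importance sampling of ε
on the self-report's truncation interval.

## Worked example

```python
import numpy as np
from hopitx import ExtendedHopit, StandardHopit, SimConfig, simulate_dataset
from hopitx.estimators import lr_test_estimators

# a dataset from the package's generating process: N=1000 respondents,
# J=5 severity vignettes, true heteroskedasticity alpha=0.05
sim = simulate_dataset(SimConfig(N=1000, J=5, alpha=0.05, seed=7))
d = sim.dataset

std = StandardHopit(R=48).fit(d.X, d.y, vignettes=d.V, Z=d.Z)
ext = ExtendedHopit(R=48).fit(d.X, d.y, vignettes=d.V, Z=d.Z,
                              start=std.result_.params)

print(f"alpha_hat = {ext.alpha_:.3f}")
print(f"sigma_v:  standard {std.sigma_v_:.2f}  extended {ext.sigma_v_:.2f}")
print(f"AIC:      standard {std.aic_:.0f}  extended {ext.aic_:.0f}")
lr = lr_test_estimators(ext, std)
print(f"LR test of vignette equivalence: chi2(1) = {lr.statistic:.1f}, "
      f"p = {lr.p_value:.2e}")
rho = np.corrcoef(ext.predict_latent(d.X), sim.ystar)[0, 1]
print(f"corr(fitted index, simulated latent outcome) = {rho:.3f}")
```

Output from this exact script:

```
alpha_hat = 0.040
sigma_v:  standard 3.01  extended 1.03
AIC:      standard 7506  extended 6600
LR test of vignette equivalence: chi2(1) = 908.2, p = 1.64e-199
corr(fitted index, simulated latent outcome) = 0.795
```

Reading it: the extended fit recovers the true α = 0.05 and the true
perception sd σᵥ = 0.9 to within sampling error, while the misspecified
standard model absorbs the distance-driven noise into a ~3× inflated
σ̂ᵥ — discounting the vignette signal and distorting its coefficient
estimates. The LR test rejects vignette equivalence decisively, and the
fitted latent index correlates with the simulated truth at its
theoretical ceiling (√0.625 ≈ 0.79 under this design).

A command-line interface mirrors the library
(`hopitx fit|simulate|replicate|het-error`); every run writes a
manifest with seeds and draw settings for bit-for-bit reproduction.

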