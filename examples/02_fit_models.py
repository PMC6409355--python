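"""Fit the four temporal-interaction models and compare their fits.

Expression is generated from the 0.5^t distance law (Model 4) with noise
SD 0.5, so Model 4 should recover beta = (0.5, -0.3, 1.2) and a residual
SD near 0.5, while Models 1-3 absorb the misspecified distance term into a
larger residual.  The F test checks overall significance, the t tests the
individual coefficients.
"""

from oct4expr import (GenerativeConfig, ModelSpec, fit_model,
                      generate_timecourse, inference_report)

dataset = generate_timecourse(
    GenerativeConfig(n_genes=12, noise_sd=0.5, seed=21))

print(f"{'model':>5} {'f(t)':>7} {'beta1':>8} {'beta2':>9} {'beta3':>7} "
      f"{'resid_sd':>9} {'adjR2':>12} {'p2 (t test)':>12}")
for model_id in (1, 2, 3, 4):
    spec = ModelSpec(model_id)
    fit = fit_model(dataset.records, spec)
    rep = inference_report(fit)
    f_t = spec.terms[1].removeprefix("D*")
    print(f"{model_id:>5} {f_t:>7} {fit.beta[0]:>8.4f} {fit.beta[1]:>9.4f} "
          f"{fit.beta[2]:>7.4f} {fit.residual_sd:>9.3f} "
          f"{1 - rep.adj_r_squared:>12.3e} {rep.t_pvalues[1]:>12.3e}")

# The adjusted R-squared column is shown as 1 - adjR2: every model looks
# near-perfect on that scale because the exponential height term dominates
# the total variance, but the residual SD exposes the misspecified distance
# laws (Models 1-3), while Model 4 lands on the generative noise level 0.5
# and its distance coefficient is significant (small p2).
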