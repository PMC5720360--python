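"""Confidence intervals for the variance components.

Shows the two interval constructions: the Q-profile interval for the
heterogeneity variance under the consistency assumption (inverting the
chi-square pivot) and profile-restricted-likelihood intervals for both
components under the full model.
"""

import warnings

import nmari as nm

layout = nm.synthetic_layout(n_treatments=6, design_mix={2: 18, 3: 4}, seed=3)
truth = (0.4, 0.2)
config = nm.SimulationConfig(layout=layout, grid=(truth,), reps=1, seed=3)
net = layout.with_outcomes(nm.simulate_dataset(config, truth, 0).Y)

qp = nm.q_profile_ci_consistency(net, level=0.95)
pm = nm.estimate_pm_consistency(net)
print("consistency model (tau_omega_sq = 0):")
print(f"  PM point estimate tau_beta_sq = {pm.vc.tau_beta_sq:.3f}")
print(f"  Q-profile 95% CI              = ({qp.lower:.3f}, {qp.upper:.3f})")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    reml = nm.estimate_reml(net, "full")
    ci_b = nm.profile_likelihood_ci(net, "tau_beta_sq", reml_fit=reml)
    ci_w = nm.profile_likelihood_ci(net, "tau_omega_sq", reml_fit=reml)
print("\nfull model (REML + profile likelihood):")
print(f"  tau_beta_sq  = {reml.vc.tau_beta_sq:.3f}, "
      f"95% CI ({ci_b.lower:.3f}, {ci_b.upper:.3f})")
print(f"  tau_omega_sq = {reml.vc.tau_omega_sq:.3f}, "
      f"95% CI ({ci_w.lower:.3f}, {ci_w.upper:.3f})")
print("\nA tau_omega_sq interval containing 0 means the data cannot rule out")
print("consistency (all designs estimating the same effects).")
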