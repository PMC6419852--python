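"""Estimate causal coefficients when a hidden confounder is present.

A hidden variable H drives both regulators and target, so plain regression
is biased.  The moment-difference estimator uses only the between-
environment shift of second moments, in which the (invariant) confounder
contribution cancels, and recovers gamma* from noise-intervened data.
"""

import numpy as np

import invarmir as iv

study = iv.simulate_sem(
    p=3, t=1, parents_per_target=1, env_sizes=(2000, 2000),
    gamma_scale=1.0, gamma_jitter=0.0, gamma_sign=1,
    intervention_scale=2.0, intervened_regulators="all",
    hidden_dim=1, hidden_strength=1.5, seed=4,
)
target = study.targets.feature_ids[0]
X = study.regulators.values.T
Y = study.targets.values[0]
gamma_true = study.gamma_vector(target)

res = iv.hidden_icp_coefficients(
    X, Y, study.env, study.regulators.sample_ids, n_boot=100, seed=0,
)
# naive pooled OLS for contrast: biased by the confounder
D = np.column_stack([np.ones(len(Y)), X])
ols = np.linalg.lstsq(D, Y, rcond=None)[0][1:]

print(f"{'regulator':<10} {'true':>7} {'hiddenICP':>10} {'95% CI':>18} {'OLS':>7}")
for j, rid in enumerate(study.regulators.feature_ids):
    lo, hi = res.conf_intervals[j]
    flag = "*" if res.significant[j] else " "
    print(f"{rid:<10} {gamma_true[j]:>7.3f} {res.coefficients[j]:>10.3f}"
          f"  [{lo:+.3f}, {hi:+.3f}]{flag} {ols[j]:>7.3f}")
print("\n* = bootstrap interval excludes 0.  The moment-difference estimate")
print("tracks the true coefficients while pooled OLS absorbs confounder bias.")
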