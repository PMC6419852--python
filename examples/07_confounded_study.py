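"""Stress test: hidden confounders break correlation, not the causal scorer.

Hidden variables driving both miRNAs and mRNAs create spurious
correlations.  Pearson ranks those spurious pairs highly; the moment-
difference causal estimator cancels the invariant confounder contribution
and keeps its precision.  This is the regime the causal method is built
for -- on clean unconfounded linear data a well-tuned regression is
already near-optimal and ensembling adds little.
"""

import invarmir as iv

K_SHOW = 3
for hidden_dim, label in ((0, "no confounding"), (4, "4 hidden confounders")):
    precisions = {}
    for seed in range(K_SHOW):
        study = iv.simulate_sem(p=15, t=60, parents_per_target=2,
                                env_sizes=(80, 80, 80),
                                intervened_regulators="all",
                                hidden_dim=hidden_dim, hidden_strength=1.5,
                                seed=100 + seed)
        truth = study.true_pairs
        K = len(truth)
        for name, sm in (
            ("pearson", iv.pearson_scores(study.regulators, study.targets)),
            ("hidden_icp", iv.score_all_pairs(study.regulators, study.targets,
                                              study.env, method="hidden_icp")),
        ):
            rk = iv.rank_interactions(sm)
            hits = len(set(iv.top_k_overall(rk, K)) & truth)
            precisions.setdefault(name, []).append(hits / K)
    print(f"{label}:")
    for name, vals in precisions.items():
        mean = sum(vals) / len(vals)
        print(f"  {name:<11} precision@|true|: {mean:.3f}  (over {K_SHOW} seeds)")
# Expect Pearson to drop sharply under confounding while the causal
# estimator's precision stays close to the unconfounded case.
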