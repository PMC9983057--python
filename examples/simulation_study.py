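"""Misspecification grid: multiple robustness of the weighted ICE estimator.

Runs a scaled-down replication grid over the three working-model scenarios of
the binary-confounder study (all models correct; only the outcome
regressions correct; only the treatment and censoring models correct) and
tabulates bias/SE/RMSE (x100) per estimator, the conventional simulation-
study presentation.
"""

import ipsi

delta = 0.5
truth = ipsi.monte_carlo_truth("study1", delta, n_mc=1_000_000, seed=5)
print(f"truth at delta={delta}: {truth.psi:.4f} (MCSE {truth.mcse:.5f})\n")

for scenario in ("all_correct", "outcome_only", "treatment_only"):
    cfg = ipsi.ScenarioConfig(dgp="study1", n=1000, delta=delta,
                              scenario=scenario, replications=50,
                              base_seed=11)
    results = ipsi.run_replications(cfg)
    summary = ipsi.summarize_replications(results, truth=truth.psi)
    print(f"scenario: {scenario} (n={cfg.n}, {cfg.replications} reps)")
    print(summary.round(2).to_string(index=False))
    print()

# Reading the table: the weighted ICE estimator stays nearly unbiased in all
# three scenarios (J+1 multiple robustness), while ICE picks up bias when the
# outcome regressions are misspecified and IPW when the treatment models are.
# Increase `replications` for publication-grade Monte-Carlo error.
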