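"""Model what makes a target instance likely to be found.

The instance-level model is a logistic regression with crossed random
intercepts for participant ("worker") and trial: the outcome is whether a
ground-truth instance was selected. Variance explained is summarized on
the latent logit scale (marginal R^2 for fixed effects, conditional R^2
including the random intercepts), and per-predictor contributions come
from single-predictor models against a random-effects-only baseline.
"""

from searchbench import (EXP2_PREDICTORS, GeneratorConfig,
                         build_instance_table, delta_r2_by_predictor,
                         fit_instance_model, predict_selection_probability,
                         pseudo_r2, score_cohort, scored_table,
                         simulate_cohort, vif)

# An Experiment-2-style cohort: selection probability depends on instance
# clarity and template color match in addition to size / distance / count.
cfg = GeneratorConfig.experiment2(n_participants=25, n_trials=50, seed=21)
cohort = simulate_cohort(cfg)
matches = score_cohort(cohort.trials, cohort.selections,
                       participants=list(cohort.worker_effects.index))
table = build_instance_table(scored_table(matches, cohort.trials))
print(f"{len(table)} instance-level observations "
      f"({table['selected'].mean():.0%} selected)")

fit = fit_instance_model(table, EXP2_PREDICTORS)
print(fit.summary_frame().round(3).to_string())
print(f"random-intercept variances: worker {fit.vc['worker']:.2f}, "
      f"trial {fit.vc['trial']:.2f}")

r2m, r2c = pseudo_r2(fit)
print(f"pseudo-R^2: marginal {r2m:.3f}, conditional {r2c:.3f}")

print("\nper-predictor marginal-R^2 gain over the random-effects baseline:")
print(delta_r2_by_predictor(table, EXP2_PREDICTORS)
      ["delta_r2_marginal"].round(4).to_string())

print("\ncollinearity (VIF):")
print(vif(table.loc[:, list(EXP2_PREDICTORS)]).round(3).to_string())

# Predicted probability over a size grid, other covariates held fixed.
print("\npredicted selection probability vs instance side (px):")
for side in (30, 60, 100, 200):
    p = predict_selection_probability(fit, area=side ** 2, distance=299.0,
                                      n_targets=1, clarity=3.0,
                                      color_match=0.0)
    print(f"  {side:>3} px -> {p:.3f}")
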