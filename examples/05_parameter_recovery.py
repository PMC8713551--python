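"""Check that the estimator recovers the simulator's own parameters.

Cohorts are generated from known logit-scale coefficients and
random-intercept variances, run through the full matching pipeline (so the
refit sees exactly what an analyst of real data would see, including
matching noise), and the instance-level model is refit. At desk scale this
uses small cohorts; the acceptance-grade study uses 150 workers x 80
trials x 3 replicates (see scripts/acceptance.py).
"""

from searchbench import GeneratorConfig
from searchbench.recovery import recovery_study

generative = GeneratorConfig.experiment1().beta
print("generative coefficients:", generative)

table = recovery_study(experiment=1, seeds=[11, 12, 13],
                       n_participants=40, n_trials=40)
print("\nrecovered per replicate:")
print(table.round(3).to_string())
print("\nseed-averaged:")
avg = table.drop(columns=["n_obs", "converged"]).mean()
print(avg.round(3).to_string())
print("\nNote: refitting after matching attenuates the size coefficient "
      "slightly\n(assignment noise in dense trials); the acceptance-grade "
      "study stays within\n+-0.10 of the generative 0.92.")
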