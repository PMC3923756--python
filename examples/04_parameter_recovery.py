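"""Parameter recovery: simulate consumers from a known diet, then re-infer it.

Each replicate draws a noisy consumer measurement from the forward model at
the true diet, runs the posterior, and compares the estimate to the truth.
Coverage near 95% says the posterior intervals are honestly calibrated under
the model's own assumptions.
"""

import numpy as np

import dietmix as dm

sc = dm.builtin_scenario("table1")
spec = dm.SimulationSpec(
    scenario=sc,
    true_alpha=np.array([0.70, 0.20, 0.10]),
    noise_measurement=True,
    n_replicates=10,
    seed=2024,
)
config = dm.SamplerConfig(seed=0, n_chains=2, n_iterations=6_000, burn_in=2_000, thin=2)
report = dm.recovery_experiment(spec, config)

print(report.table.head(6).round(3).to_string(index=False))
print(f"\nbias per group:  {report.bias.round(3).to_dict()}")
print(f"rmse per group:  {report.rmse.round(3).to_dict()}")
print(f"95% interval coverage: {report.coverage95:.2f}")
# bias near 0 and coverage near 0.95 mean the sampler recovers the simulated
# diets without systematic error; each row shows one replicate's posterior
# mean/sd and 95% interval against the truth.
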