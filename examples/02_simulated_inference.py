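"""Posterior inference on the simulated three-source scenario.

Runs the adaptive MCMC sampler on the packaged 'table1' scenario and prints
the posterior summary for the diet proportions.  The known truth is
70/20/10%; posterior means land within a couple of points of it.
"""

import dietmix as dm

sc = dm.builtin_scenario("table1")
post = dm.build_posterior_log_density(sc)
config = dm.SamplerConfig(seed=1, n_chains=4, n_iterations=30_000, burn_in=10_000, thin=2)
chains = dm.run_mcmc(post, config)

summary = dm.summarize(chains, [f"alpha[{g}]" for g in sc.groups])
print(summary.round(3).to_string())
# mean / sd columns are the intake estimate and its uncertainty (on the
# proportion scale); p2.5..p97.5 delimit the 68% and 95% credible intervals;
# rhat ~ 1.00 and ess in the hundreds indicate converged, well-mixed chains.

print("\nintake estimates (%):")
for g in sc.groups:
    row = summary.loc[f"alpha[{g}]"]
    print(f"  {g:7s} {100 * row['mean']:5.1f} +/- {100 * row['sd']:4.1f}")
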