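"""Expert prior constraints on the pig-feeding scenario.

Compares the unconstrained dietary scenario (a) with two constrained
variants: (b) 'Corn > Gluten' — the corn intake exceeds the gluten intake —
and (c) '5 < Protein < 40' — dietary protein supplies between 5% and 40% of
dietary carbon.  Constraints enter the posterior as pseudo-observations and
tighten the credible intervals without moving the truth outside them.

Runs are shortened here for a quick demonstration; the packaged defaults
(4 x 30k) are used by the test suite.
"""

import dietmix as dm

truth = dm.hare_true_intake().alpha
config = dm.SamplerConfig(seed=5, n_chains=4, n_iterations=10_000, burn_in=4_000, thin=2)

for name in ("hare_a", "hare_b", "hare_c"):
    sc = dm.builtin_scenario(name)
    chains = dm.run_mcmc(dm.build_posterior_log_density(sc), config)
    summary = dm.summarize(chains, [f"alpha[{g}]" for g in sc.groups])
    label = ", ".join(sc.constraints) if sc.constraints else "no expert priors"
    print(f"\nscenario {name} ({label}):")
    for i, g in enumerate(sc.groups):
        row = summary.loc[f"alpha[{g}]"]
        star = " <- true intake" if truth[i] > 0 else ""
        print(f"  {g:8s} mean {row['mean']:.3f}  95% CI [{row['p2.5']:.3f}, "
              f"{row['p97.5']:.3f}]  truth {truth[i]:.2f}{star}")
# From (a) to (b)/(c) the Corn and Gluten intervals narrow substantially
# while still covering the true 69%/31% intakes.
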