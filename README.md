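# dietmix

Bayesian diet reconstruction from isotopic and elemental proxy signals.

Quantitative diet reconstruction — in archaeology, ecology, forensics and
dietary physiology — works from the principle "you are what you eat": the
chemical signatures of foods are transferred through the diet and recorded
in consumer tissues such as bone collagen. `dietmix` estimates the relative
intake of candidate food groups from such tissue signals, treating the
problem as Bayesian mixture decomposition on the simplex. Beyond the
classical linear mixing model it handles

* **dietary routing** — specific food fractions (macronutrients, single
  amino acids) contribute to a given proxy disproportionately to their
  dietary abundance (bone-collagen δ¹³C draws roughly 74% of its carbon
  from dietary protein);
* **concentration dependence** — each source's contribution is weighted by
  the elemental concentration of the relevant fraction in that food;
* **diet-to-tissue offsets** — systematic enrichment between diet and
  tissue (trophic discrimination);
* **uncertainty in every input** — signals, concentrations, routing weights
  and offsets are latent variables with their stated normal uncertainties;
* **expert prior constraints** — algebraic relations such as
  `Corn > Gluten` or `5 < Protein < 40` (percent of dietary carbon from
  protein), entered as pseudo-observations that reshape the posterior.

## Model

For food groups *i* with unknown intake proportions αᵢ (Σαᵢ = 1), food
fractions *j* and dietary proxies *k*, the predicted consumer signal is

```
P_k = Δ_k + Σ_j (w_jk / 100) · ( Σ_i α_i c_ij s_ijk / Σ_i α_i c_ij )
```

where s, c, w, Δ are the source signals, fraction concentrations, routing
weights and diet-to-tissue offset, all modelled as (truncated) normal
latents at their stated mean ± sd. The measured consumer signals enter a
normal likelihood with the measurement sd; α carries a Dirichlet prior
(unit hyperparameters by default, or informative marginals elicited via
beta moment matching). Derived estimands are the whole-diet fraction
intakes β_j (the concentration-weighted average of intakes) and π_ik, the
share of a proxy signal attributable to each group. Equality constraints
enter as a zero observed under Normal(g, σ_R); inequalities as a one
observed under Bernoulli(H(g)) — i.e. hard truncation of the support. The
posterior is sampled with a self-contained adaptive block random-walk
Metropolis sampler in stick-breaking coordinates (see `docs/methods.md`).

## Worked example

```python
import dietmix as dm

sc = dm.builtin_scenario("table1")      # 3 sources, d15N 2/6/10, offset +3
post = dm.build_posterior_log_density(sc)
chains = dm.run_mcmc(post, dm.SamplerConfig(seed=1))
print(dm.summarize(chains, [f"alpha[{g}]" for g in sc.groups]).round(3))
```

```
                mean  median     sd   p2.5    p16    p50    p84  p97.5   rhat      ess
parameter
alpha[Plant]   0.698   0.702  0.070  0.557  0.623  0.702  0.771  0.814  1.003  926.713
alpha[Animal]  0.198   0.195  0.121  0.008  0.058  0.195  0.334  0.421  1.005  655.808
alpha[Fish]    0.104   0.102  0.060  0.006  0.035  0.102  0.172  0.214  1.004  684.526
```

The consumer in this simulated scenario was "measured" at 6.6 ± 0.2‰ —
exactly the value implied by true intakes of 70/20/10% — and the posterior
recovers 69.8 ± 7.0 / 19.8 ± 12.1 / 10.4 ± 6.0 percent: accurate means with
honest uncertainty, the middle source being the hardest to pin down from a
single proxy. `p16/p84` and `p2.5/p97.5` delimit the 68% and 95% credible
intervals; R̂ ≈ 1.00 indicates converged chains.

The `examples/` directory walks through each capability: the forward model
(`01`), posterior inference (`02`), expert prior constraints on a pig
controlled-feeding scenario (`03`), and simulation-based parameter recovery
(`04`). A thin CLI mirrors the library:

```
dietmix fixtures --name hare_b --out scenarios/hare_b
dietmix validate --scenario scenarios/hare_b
dietmix run --scenario scenarios/hare_b --seed 1 --out report/
dietmix simulate --scenario scenarios/hare_b --alpha 0,0,0,0.69,0.31 --seed 7
```

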