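# Methods

## Model

A dietary scenario couples food groups *i* (unknown intake proportions
αᵢ on the simplex), food fractions *j* (protein, lipids, carbohydrates,
"energy", bulk, single amino acids, ...) and dietary proxies *k* (tissue
signals such as bone-collagen δ¹³C). The forward model for the consumer
signal on proxy *k* is

P_k = Δ_k + Σ_j (w_jk/100) · m_jk,  with  m_jk = Σ_i αᵢ c_ij s_ijk / Σ_i αᵢ c_ij.

m_jk is the concentration-weighted average source signal of fraction *j*;
w_jk routes fractions into the proxy. The normalisation is **per fraction**:
the routing weights describe consumer physiology (e.g. ~74% of collagen
carbon from dietary protein) and are independent of how concentrated each
fraction happens to be in the particular diet, so they are applied to
already-normalised fraction averages rather than to a single global pool.
The offset sign convention is `consumer = diet mixture + Δ`: offsets are
positive diet-to-tissue enrichments. Weights and concentrations are
expressed in percent externally and divided by exactly 100 internally.

Non-routed proxies are encoded by zero routing weights; a fraction with
zero weight (and zero weight-sd) for a proxy is skipped entirely and needs
no signal value there. A whole-food "bulk" pseudo-fraction (used by proxies
that track the scrambled dietary mix, e.g. collagen glutamate δ¹³C) is an
ordinary fraction whose concentration is the summed concentration of the
true macronutrient fractions; it is excluded from whole-diet intake totals
so dietary mass is not double counted.

Derived estimands:

* β_j = Σ_i αᵢ c_ij / Σ_j' Σ_i αᵢ c_ij' — whole-diet relative intake of
  each fraction, computed over the `diet_fractions` subset that additively
  partitions the food base;
* π_ik — the share of proxy *k* signal mass from group *i*: each routed
  fraction's weight is split among groups in proportion to αᵢ c_ij, then
  summed over fractions and renormalised. This decomposition is exactly the
  one implied by the per-fraction form of the mixing equation (with equal
  concentrations and one fraction, π = α).

## Priors, latents and constraints

α carries a Dirichlet prior, unit hyperparameters by default. Informative
marginals are elicited by beta moment matching: a = m(m(1−m)/s² − 1),
b = (1−m)(m(1−m)/s² − 1), feasible iff s² < m(1−m); the remaining Dirichlet
concentration is balanced over the other components.

Every input quantity with a nonzero sd is a latent variable with an
independent normal prior at its stated mean/sd; concentrations and routing
weights are truncated at zero (sampled by rejection in the forward
simulator, by the −∞ prior term in MCMC). The likelihood for each measured
proxy uses the consumer measurement sd only — input uncertainties propagate
hierarchically through the latents rather than being folded into a single
observation error. A consumer sd of `inf` marks a proxy with no usable
measurement (prior-only analysis). When exactly one routing weight in a
proxy is uncertain, sampled weights are not renormalised across fractions;
the draw-level deviation from 100% is part of the stated weight uncertainty.

Expert constraints are linear relations over α and β written in plain text
(`Corn > Gluten`, `Protein < 40`, `A + B = 0.5`). Relations are
canonicalised (`x < y` → `y − x > 0`; `x = y` → `x − y = 0`) to an
expression g and enter the posterior as pseudo-observations: equalities as
a zero observed under Normal(g, σ_R), inequalities as a one observed under
Bernoulli(H(g)) with H(0) = 1 (the boundary is kept; it has zero posterior
mass anyway). Bare literals larger than 1 beside a relation are read as
percentages and divided by 100, matching the field's notation. Defaults and
guards: σ_R = 0.001 on the proportion scale; a warning is logged when σ_R
is not at least 10× smaller than the prior marginal spread of the intakes
it pins (intakes have no reported sd, so their prior spread is the relevant
comparison scale). The grammar is deliberately restricted to linear
expressions with rational constants — all practically arising constraints
are linear, and linearity keeps the truncation region a half-space
intersection that the sampler and the initialiser can reason about.

## Sampling

The unconstrained parameter vector consists of K−1 stick-breaking
(logistic) coordinates for α — offset so the zero vector maps to the
barycenter, with the log-Jacobian included — followed by one standardised
z-score per active latent. Latents that cannot influence the posterior
(e.g. the concentration of an unrouted fraction outside the diet total) are
skipped.

The sampler is an adaptive block random-walk Metropolis: parameters are
grouped into at most four blocks (diet proportions; signals;
concentrations; offsets+weights), each with a per-chain isotropic Gaussian
proposal whose scale adapts during burn-in only (multiplicative updates
every 50 iterations toward an acceptance target of 0.35 for blocks of ≤ 4
parameters and 0.30 for larger ones), so the post-burn-in kernel is a
fixed, valid Metropolis kernel. Proposals violating a hard inequality are
rejected through the −∞ term, preserving detailed balance. All chains are
advanced in one vectorised numpy pass; runs are bitwise reproducible given
(seed, config).

Defaults: 4 chains × 30,000 iterations, 10,000 burn-in, thinning 2 — on the
packaged scenarios (2–43 free parameters) this converges in seconds to tens
of seconds with R̂ < 1.01 and ESS in the hundreds to thousands.
Initialisation: α at the jittered barycenter, latents at their means;
chains starting at zero density (e.g. when the barycenter violates a
constraint) are re-jittered with growing spread up to a bounded retry
count, then an error names the likely cause (jointly unsatisfiable
constraints). Summaries pool post-burn-in draws and report mean, median, sd
and the 2.5/16/50/84/97.5 percentiles (numpy linear interpolation); split-R̂
and ESS come from ArviZ, flagging R̂ > 1.05, ESS < 400, or degenerate
constant chains.

## Packaged scenarios

`table1` is the simulated three-source test: Plant/Animal/Fish protein
δ¹⁵N of 2/6/10‰, one non-routed fraction at uniform concentration 100,
offset +3‰ fixed, consumer 6.6 ± 0.2‰ (the exact value implied by intakes
70/20/10%). Source signals are fixed constants (sd 0); with this choice the
posterior spread reproduces the published estimates, and an independent
importance-sampling oracle over the Dirichlet prior gives the same
posterior moments as the MCMC path.

`hare_a/b/c` reconstruct a controlled pig-feeding experiment: five feeds
(soybean meal, barley grain, alfalfa, ground corn, corn gluten meal; true
intakes 0/0/0/69/31 wt%), three proxies (collagen δ¹³C routed 74 ± 4% from
protein with the remainder from energy, offset 4.8 ± 0.5‰; collagen δ¹⁵N
all from protein, offset 3.6 ± 1.2‰; collagen-glutamate δ¹³C tracking bulk
diet, offset 9.2 ± 1.8‰). Concentrations are carbon dry-weight percent per
macronutrient, derived from dry-weight composition times reference carbon
contents (protein 52.4%, carbohydrates 44.4%, lipids 76.8%), each with a
conservative 2.5% absolute sd; "energy" aggregates carbohydrates and
lipids. The fixture keeps a separate lipids fraction carrying its tabulated
concentration for bookkeeping, but it is unrouted and excluded (with bulk)
from diet totals, since its carbon is already inside energy. The bulk
pseudo-fraction concentration is the protein+lipids+carbs sum with sd
2.5·√3 by quadrature over the three summed rows. Variants differ only in
expert priors: (a) none, (b) `Corn > Gluten`, (c) `5 < Protein < 40` —
protein supplying 5–40% of dietary carbon, a conservative widening of the
10–35% reference calorie range justified by the near-equality of the
macronutrients' energy-to-carbon ratios (≈ 9.0, 7.6 and 11.7 kcal/g C for
carbohydrates, protein and lipids; helpers in `dietmix.fixtures` compute
these).

## What the simulator does and does not emulate

`simulate_consumer` draws any enabled subset of latent noise sources
(signals, concentrations, weights, offsets) from their stated normals and
adds measurement noise at the consumer sd — i.e. data generated exactly
under the model's own assumptions. Recovery and coverage results therefore
certify internal calibration of the pipeline, not robustness to real-data
violations: inter-individual heterogeneity beyond the stated sds, offset
variation with diet composition or body size, correlated errors between
proxies, and mis-specified food-group aggregation are all outside what a
passing test demonstrates.

## Numerical choices and edge cases

* Degenerate fraction mass (no dietary mass reaching a routed fraction)
  raises an error naming the fraction and proxy rather than returning NaN.
* A truth of exactly zero intake sits on the simplex boundary, which an
  equal-tailed interval of a continuous posterior excludes by construction;
  coverage checks for boundary truths use the one-sided bound.
* Recovery reports flag (not fail) non-identifiable designs — posteriors
  whose spread stays at the prior's (e.g. identical source signals).
* Scenario files store percentages as printed and use `mean(sd)` cells with
  shortest round-trip float formatting, so write→read is exact.
* Problem sizes in the test suite are chosen to exercise full-length runs
  (4 × 30k) on the packaged scenarios and shortened runs (2 × 6k) inside
  the 50-replicate coverage experiment, where the dimension is small and
  mixing is fast.

## Known limitations

Offsets are per proxy only (no group- or fraction-specific Δ); constraint
expressions may reference α and β but not π; the sampler is gradient-free
and will mix slowly on problems far larger than the tens-of-parameters
scenarios it targets; no model-comparison machinery (DIC etc.) is provided.
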