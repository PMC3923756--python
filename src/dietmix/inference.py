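"""Posterior sampling for dietary scenarios.

The posterior couples the diet proportions alpha (on the simplex) with one
latent scalar for every uncertain model quantity — source signals, fraction
concentrations, routing weights, and diet-to-tissue offsets.  Each latent
gets an independent normal prior at its stated mean/sd (concentrations
truncated at zero); the likelihood compares the forward-predicted consumer
signal with the measured one using the measurement sd only, so input
uncertainties propagate hierarchically rather than being folded into a
single error term.  Expert constraints enter as pseudo-observation terms
(see :mod:`dietmix.constraints`).

Sampling is a gradient-free adaptive random-walk Metropolis scheme operating
on an unconstrained parameter vector: alpha through a stick-breaking
(logistic) transform with its log-Jacobian, latents standardised to z-scores.
Parameters are updated in a small number of blocks (diet proportions;
signals; concentrations; offsets and weights), each with a per-chain proposal
scale adapted during burn-in only, targeting acceptance rates in the 0.3-0.45
band.  Proposals that violate a hard inequality constraint are rejected via
the -inf likelihood term, which preserves detailed balance.  All chains are
advanced in one vectorised pass, and runs are bitwise reproducible given the
seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .constraints import Constraint, constraint_log_term, parse_constraint
from .priors import DirichletPrior
from .scenario import DietaryScenario, ScenarioError, _beta_batch, _pi_batch, _predict_batch, validate_scenario

__all__ = [
    "SamplerConfig",
    "PosteriorLogDensity",
    "build_posterior_log_density",
    "ArrayTarget",
    "PosteriorChains",
    "run_mcmc",
    "diagnose",
    "summarize",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration; the seed must be given explicitly."""

    seed: int
    n_chains: int = 4
    n_iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 2
    adapt_window: int = 50
    max_init_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# Stick-breaking transform: unconstrained R^(K-1) <-> open simplex.
# The offset log(K - m - 1) centres the transform so z = 0 maps to the
# barycenter (1/K, ..., 1/K).
# ---------------------------------------------------------------------------

def _alpha_from_sticks(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map stick coordinates (B, K-1) to (alpha (B, K), log|Jacobian| (B,))."""
    B, Km1 = z.shape
    K = Km1 + 1
    alpha = np.empty((B, K))
    rem = np.ones(B)
    logjac = np.zeros(B)
    with np.errstate(divide="ignore"):
        for m in range(Km1):
            v = expit(z[:, m] - np.log(K - m - 1))
            alpha[:, m] = rem * v
            logjac += np.log(rem) + np.log(v) + np.log1p(-v)
            rem = rem * (1.0 - v)
    alpha[:, K - 1] = rem
    return alpha, logjac


def _sticks_from_alpha(alpha: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(np.asarray(alpha, float))
    B, K = a.shape
    z = np.empty((B, K - 1))
    rem = np.ones(B)
    for m in range(K - 1):
        v = a[:, m] / rem
        z[:, m] = np.log(v) - np.log1p(-v) + np.log(K - m - 1)
        rem = rem - a[:, m]
    return z


@dataclass(frozen=True)
class _Latent:
    kind: str            # 'signal' | 'conc' | 'weight' | 'offset'
    index: tuple
    mean: float
    sd: float
    lower: float | None  # truncation bound on the value scale, or None
    name: str


def _collect_latents(scenario: DietaryScenario) -> list[_Latent]:
    """Enumerate the uncertain quantities that can influence the posterior.

    Inert latents (e.g. the concentration of an unrouted fraction outside the
    diet total) would only mirror their priors and are skipped.
    """
    lat: list[_Latent] = []
    routed = scenario.routed()
    g, f, p = scenario.groups, scenario.fractions, scenario.proxies
    diet = set(scenario.diet_fractions)
    for i in range(scenario.n_groups):
        for j in range(scenario.n_fractions):
            for k in range(scenario.n_proxies):
                if routed[j, k] and scenario.signal_ok[i, j, k] and scenario.signal_sd[i, j, k] > 0:
                    lat.append(_Latent(
                        "signal", (i, j, k),
                        float(scenario.signal_mean[i, j, k]), float(scenario.signal_sd[i, j, k]),
                        None, f"signal[{g[i]},{f[j]},{p[k]}]"))
    for i in range(scenario.n_groups):
        for j in range(scenario.n_fractions):
            active = routed[j, :].any() or f[j] in diet
            if active and scenario.conc_sd[i, j] > 0:
                lat.append(_Latent(
                    "conc", (i, j),
                    float(scenario.conc_mean[i, j]), float(scenario.conc_sd[i, j]),
                    0.0, f"conc[{g[i]},{f[j]}]"))
    for j in range(scenario.n_fractions):
        for k in range(scenario.n_proxies):
            if scenario.weight_sd[j, k] > 0:
                lat.append(_Latent(
                    "weight", (j, k),
                    float(scenario.weight_mean[j, k]), float(scenario.weight_sd[j, k]),
                    0.0, f"weight[{f[j]},{p[k]}]"))
    for k in range(scenario.n_proxies):
        if scenario.offset_sd[k] > 0:
            lat.append(_Latent(
                "offset", (k,),
                float(scenario.offset_mean[k]), float(scenario.offset_sd[k]),
                None, f"offset[{p[k]}]"))
    return lat


class PosteriorLogDensity:
    """Vectorised log-posterior on an unconstrained parameterisation.

    Layout of the parameter vector: ``n_groups - 1`` stick-breaking
    coordinates for alpha, followed by one standardised z-score per active
    latent.  ``logpdf`` accepts a ``(batch, dim)`` array and returns
    ``(batch,)`` — the batch axis is how multiple chains are advanced in one
    numpy pass.
    """

    def __init__(
        self,
        scenario: DietaryScenario,
        prior: DirichletPrior | None = None,
        constraints: Sequence[Constraint | str] | None = None,
    ):
        problems = validate_scenario(scenario)
        if problems:
            raise ScenarioError("invalid scenario:\n  " + "\n  ".join(problems))
        self.scenario = scenario
        self.prior = prior or DirichletPrior(scenario.n_groups)
        if self.prior.n_groups != scenario.n_groups:
            raise ValueError("prior dimension does not match the number of food groups")
        if constraints is None:
            constraints = scenario.constraints
        self.constraints: tuple[Constraint, ...] = tuple(
            c if isinstance(c, Constraint) else parse_constraint(c, scenario)
            for c in constraints
        )
        self._needs_beta = any(np.any(c.coef_beta != 0) for c in self.constraints)
        self.latents = _collect_latents(scenario)
        self.n_sticks = scenario.n_groups - 1
        self.dim = self.n_sticks + len(self.latents)
        self._lat_mean = np.array([l.mean for l in self.latents])
        self._lat_sd = np.array([l.sd for l in self.latents])
        self._lat_lower = np.array(
            [-np.inf if l.lower is None else l.lower for l in self.latents])
        self._observed = np.isfinite(scenario.consumer_sd)
        self.param_names = (
            [f"stick[{m}]" for m in range(self.n_sticks)] + [l.name for l in self.latents]
        )

    # -- blocks for the sampler ------------------------------------------
    @property
    def blocks(self) -> list[np.ndarray]:
        cols: dict[str, list[int]] = {"alpha": list(range(self.n_sticks))}
        groups = {"signal": [], "conc": [], "scale": []}
        for idx, l in enumerate(self.latents):
            key = l.kind if l.kind in ("signal", "conc") else "scale"
            groups[key].append(self.n_sticks + idx)
        for key, ix in groups.items():
            if ix:
                cols[key] = ix
        return [np.array(ix, dtype=int) for ix in cols.values()]

    # -- state reconstruction --------------------------------------------
    def _unpack(self, Z: np.ndarray):
        """(B, dim) -> alpha (B,nI), logjac (B,), latent value arrays."""
        sc = self.scenario
        B = Z.shape[0]
        alpha, logjac = _alpha_from_sticks(Z[:, : self.n_sticks])
        vals = self._lat_mean + self._lat_sd * Z[:, self.n_sticks:]
        sig = np.broadcast_to(sc.signal_mean, (B,) + sc.signal_mean.shape).copy()
        conc = np.broadcast_to(sc.conc_mean, (B,) + sc.conc_mean.shape).copy()
        wgt = np.broadcast_to(sc.weight_mean, (B,) + sc.weight_mean.shape).copy()
        off = np.broadcast_to(sc.offset_mean, (B,) + sc.offset_mean.shape).copy()
        arrays = {"signal": sig, "conc": conc, "weight": wgt, "offset": off}
        for col, l in enumerate(self.latents):
            arrays[l.kind][(slice(None),) + l.index] = vals[:, col]
        return alpha, logjac, sig, conc, wgt, off, vals

    def logpdf(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, float))
        sc = self.scenario
        alpha, logjac, sig, conc, wgt, off, vals = self._unpack(Z)
        lp = self.prior.logpdf(alpha) + logjac
        # latent priors: standardised normals, truncated below where bounded
        lp = lp - 0.5 * np.sum(Z[:, self.n_sticks:] ** 2, axis=1)
        oob = np.any(vals < self._lat_lower, axis=1)
        lp = np.where(oob, -np.inf, lp)
        ok = np.isfinite(lp)
        if np.any(ok):
            pred = _predict_batch(sc, alpha[ok], conc[ok], sig[ok], wgt[ok], off[ok])
            obs = self._observed
            resid = (sc.consumer_mean[obs] - pred[:, obs]) / sc.consumer_sd[obs]
            loglik = -0.5 * np.sum(resid**2 + _LOG2PI, axis=1) - np.sum(
                np.log(sc.consumer_sd[obs]))
            contrib = np.zeros(Z.shape[0])
            contrib[ok] = loglik
            lp = lp + contrib
        if self.constraints:
            beta = _beta_batch(sc, alpha, conc) if self._needs_beta else None
            for c in self.constraints:
                lp = lp + constraint_log_term(c, alpha, beta)
        return lp

    def initial(self, n_chains: int, rng: np.random.Generator,
                max_retries: int = 200) -> np.ndarray:
        """Chains start at the jittered barycenter with latents at their means;
        chains landing on zero posterior density are re-jittered more widely."""
        Z = np.zeros((n_chains, self.dim))
        Z[:, : self.n_sticks] = 0.1 * rng.standard_normal((n_chains, self.n_sticks))
        lp = self.logpdf(Z)
        tries = 0
        scale = 0.3
        while not np.all(np.isfinite(lp)):
            if tries >= max_retries:
                raise RuntimeError(
                    "could not find a starting point with finite posterior density; "
                    "check that the prior constraints are jointly satisfiable")
            bad = ~np.isfinite(lp)
            Z[bad, : self.n_sticks] = scale * rng.standard_normal((bad.sum(), self.n_sticks))
            Z[bad, self.n_sticks:] = 0.1 * rng.standard_normal((bad.sum(), len(self.latents)))
            lp = self.logpdf(Z)
            tries += 1
            scale = min(scale * 1.2, 3.0)
        return Z

    # -- labelled views of raw draws --------------------------------------
    def named_draws(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        """Expand raw draws (C, T, dim) into named scalar traces (C, T).

        Includes the diet proportions alpha per group, whole-diet fraction
        intakes beta, per-proxy group contributions pi, and every latent on
        its natural scale.
        """
        C, T, _ = Z.shape
        flat = Z.reshape(C * T, -1)
        sc = self.scenario
        alpha, _, sig, conc, wgt, off, vals = self._unpack(flat)
        out: dict[str, np.ndarray] = {}
        for i, gname in enumerate(sc.groups):
            out[f"alpha[{gname}]"] = alpha[:, i].reshape(C, T)
        beta = _beta_batch(sc, alpha, conc)
        for b, fname in enumerate(sc.diet_fractions):
            out[f"beta[{fname}]"] = beta[:, b].reshape(C, T)
        pi = _pi_batch(sc, alpha, conc, wgt)
        for k, pname in enumerate(sc.proxies):
            for i, gname in enumerate(sc.groups):
                out[f"pi[{gname}|{pname}]"] = pi[:, i, k].reshape(C, T)
        for col, l in enumerate(self.latents):
            out[l.name] = vals[:, col].reshape(C, T)
        return out


def build_posterior_log_density(
    scenario: DietaryScenario,
    prior: DirichletPrior | None = None,
    constraints: Sequence[Constraint | str] | None = None,
) -> PosteriorLogDensity:
    """Assemble the posterior for a scenario (validated before any sampling)."""
    return PosteriorLogDensity(scenario, prior, constraints)


class ArrayTarget:
    """Adapter making a plain vectorised log-density usable by :func:`run_mcmc`."""

    def __init__(self, logpdf: Callable[[np.ndarray], np.ndarray], dim: int,
                 initial_point: np.ndarray | None = None):
        self._fn = logpdf
        self.dim = dim
        self._init = np.zeros(dim) if initial_point is None else np.asarray(initial_point, float)

    @property
    def blocks(self) -> list[np.ndarray]:
        return [np.arange(self.dim)]

    def logpdf(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(np.atleast_2d(Z)), float)

    def initial(self, n_chains: int, rng: np.random.Generator, max_retries: int = 200) -> np.ndarray:
        return self._init + 0.1 * rng.standard_normal((n_chains, self.dim))

    def named_draws(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        return {f"z[{d}]": Z[:, :, d] for d in range(self.dim)}


@dataclass
class PosteriorChains:
    """Labelled MCMC draws: per-chain arrays plus the seed and diagnostics."""

    z: np.ndarray                     # (n_chains, n_kept, dim) unconstrained draws
    target: object
    config: SamplerConfig
    acceptance: np.ndarray            # (n_blocks, n_chains) post-burn-in rates
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_chains(self) -> int:
        return self.z.shape[0]

    @property
    def n_draws(self) -> int:
        return self.z.shape[1]

    @property
    def draws(self) -> dict[str, np.ndarray]:
        """Named scalar traces of shape (n_chains, n_draws)."""
        if "named" not in self._cache:
            self._cache["named"] = self.target.named_draws(self.z)
        return self._cache["named"]

    def pooled(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Flat table of draws with chain/iteration columns."""
        named = self.draws
        C, T = self.z.shape[:2]
        data = {"chain": np.repeat(np.arange(C), T), "iteration": np.tile(np.arange(T), C)}
        for k, v in named.items():
            data[k] = v.reshape(-1)
        return pd.DataFrame(data)


def run_mcmc(target, config: SamplerConfig) -> PosteriorChains:
    """Adaptive block random-walk Metropolis, vectorised across chains.

    Proposal scales adapt per block and per chain during burn-in only (so the
    post-burn-in kernel is a fixed, valid Metropolis kernel), then draws are
    thinned and returned.  Bitwise reproducible given (target, config).
    """
    rng = np.random.default_rng(config.seed)
    n_chains = config.n_chains
    blocks = getattr(target, "blocks", [np.arange(target.dim)])
    Z = target.initial(n_chains, rng, max_retries=config.max_init_retries)
    lp = target.logpdf(Z)
    if not np.all(np.isfinite(lp)):
        raise RuntimeError("non-finite log-density at initialization")

    n_blocks = len(blocks)
    scales = np.empty((n_blocks, n_chains))
    targets = np.empty(n_blocks)
    for b, cols in enumerate(blocks):
        d = len(cols)
        scales[b] = 2.38 / np.sqrt(d) if d > 1 else 1.0
        targets[b] = 0.35 if d <= 4 else 0.30
    acc_win = np.zeros((n_blocks, n_chains))
    acc_post = np.zeros((n_blocks, n_chains))
    n_post_updates = 0

    kept = np.empty((n_chains, config.n_kept, target.dim))
    k_out = 0
    for it in range(config.n_iterations):
        for b, cols in enumerate(blocks):
            prop = Z.copy()
            prop[:, cols] += scales[b][:, None] * rng.standard_normal((n_chains, len(cols)))
            lp_prop = target.logpdf(prop)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(n_chains)) < (lp_prop - lp)
            accept &= np.isfinite(lp_prop)
            Z[accept] = prop[accept]
            lp = np.where(accept, lp_prop, lp)
            acc_win[b] += accept
            if it >= config.burn_in:
                acc_post[b] += accept
        if it < config.burn_in:
            if (it + 1) % config.adapt_window == 0:
                rate = acc_win / config.adapt_window
                scales *= np.exp(rate - targets[:, None])
                acc_win[:] = 0.0
        else:
            if n_post_updates == 0:
                acc_win[:] = 0.0
            n_post_updates += 1
            if (it - config.burn_in) % config.thin == 0 and k_out < kept.shape[1]:
                kept[:, k_out] = Z
                k_out += 1
    acceptance = acc_post / max(n_post_updates, 1)
    return PosteriorChains(z=kept[:, :k_out], target=target, config=config,
                           acceptance=acceptance)


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

_PERCENTILES = (2.5, 16.0, 50.0, 84.0, 97.5)


def diagnose(chains: PosteriorChains, rhat_max: float = 1.05, ess_min: float = 400.0) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter (via ArviZ).

    Parameters whose R-hat exceeds ``rhat_max``, whose ESS falls below
    ``ess_min``, or whose chains are degenerate (constant traces, undefined
    R-hat) are flagged.
    """
    import warnings

    import arviz as az

    if chains.n_chains < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, tr in chains.draws.items():
            if np.allclose(tr.std(axis=1), 0.0):
                rows.append((name, np.nan, np.nan, True, "constant chain"))
                continue
            rhat = float(az.rhat(tr))
            ess = float(az.ess(tr))
            reason = ""
            flagged = False
            if not np.isfinite(rhat) or rhat > rhat_max:
                flagged, reason = True, f"rhat > {rhat_max}"
            elif ess < ess_min:
                flagged, reason = True, f"ess < {ess_min:g}"
            rows.append((name, rhat, ess, flagged, reason))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged", "reason"]).set_index("parameter")


def summarize(chains: PosteriorChains, params: Sequence[str] | None = None) -> pd.DataFrame:
    """Posterior summary table: mean, median, sd and the 2.5/16/50/84/97.5
    percentiles (linear interpolation), pooled over post-burn-in chains,
    with split-R-hat / ESS appended when diagnostics are available.
    """
    named = chains.draws
    names = list(named) if params is None else list(params)
    rows = []
    for name in names:
        x = named[name].reshape(-1)
        pct = np.percentile(x, _PERCENTILES)
        rows.append([x.mean(), np.median(x), x.std(ddof=1)] + list(pct))
    df = pd.DataFrame(
        rows, index=pd.Index(names, name="parameter"),
        columns=["mean", "median", "sd", "p2.5", "p16", "p50", "p84", "p97.5"])
    if chains.n_chains >= 2:
        diag = diagnose(chains)
        df["rhat"] = diag.loc[names, "rhat"]
        df["ess"] = diag.loc[names, "ess"]
    return df
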