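"""Dietary scenario data model and deterministic forward computations.

A *dietary scenario* couples three axes — food groups (index ``i``), food
fractions such as macronutrients (index ``j``), and dietary proxies such as
collagen d13C (index ``k``) — with the parameter tables a mixing model needs:

* ``S[i, j, k]``  source signal of fraction *j* of group *i* on proxy *k* (per mil),
* ``c[i, j]``     concentration of fraction *j* in group *i* (% of a common base,
  e.g. carbon dry weight),
* ``w[j, k]``     routing weight: the share (%) of proxy *k*'s signal drawn from
  fraction *j*, summing to 100 over fractions for every proxy,
* ``offset[k]``   diet-to-tissue offset (trophic discrimination factor, per mil),
* ``consumer[k]`` the measured consumer signal (per mil).

Every scalar carries a ``(mean, sd)`` pair; ``sd == 0`` marks a quantity
treated as a fixed constant.  The sign convention throughout is

    consumer signal = diet mixture + offset

i.e. offsets are positive enrichments from diet to tissue.

The forward model (:func:`predict_consumer_signal`) first forms, for each
routed fraction *j*, the concentration-weighted average source signal

    m_jk = sum_i alpha_i c_ij s_ijk / sum_i alpha_i c_ij

and then combines fractions with the physiological routing weights:

    P_k = offset_k + sum_j (w_jk / 100) m_jk.

Routing weights are normalised within each fraction (not globally) because
they describe consumer physiology — e.g. bone collagen carbon drawing ~74%
from dietary protein — independently of how concentrated each fraction
happens to be in the particular diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UncertainValue",
    "DietaryScenario",
    "DietProportions",
    "LatentState",
    "predict_consumer_signal",
    "fraction_intake",
    "proxy_contribution",
    "validate_scenario",
    "ScenarioError",
]

_WEIGHT_SUM_TOL = 1e-9
_SIMPLEX_TOL = 1e-12


class ScenarioError(ValueError):
    """Raised for structurally invalid scenarios or degenerate forward inputs."""


@dataclass(frozen=True)
class UncertainValue:
    """A (mean, sd) pair; ``sd == 0`` encodes a fixed, non-stochastic quantity."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @property
    def fixed(self) -> bool:
        return self.sd == 0.0


def _as_tuple(names) -> tuple[str, ...]:
    return tuple(str(n) for n in names)


@dataclass
class DietaryScenario:
    """Full specification of a diet-reconstruction problem.

    Parameters
    ----------
    groups, fractions, proxies
        Ordered axis names (unique within each axis).
    signal_mean, signal_sd, signal_ok
        ``(n_groups, n_fractions, n_proxies)`` arrays; ``signal_ok`` masks
        cells where a source signal is available at all.  A missing signal is
        legal only where the fraction cannot contribute to the proxy (zero
        routing weight or zero concentration).
    conc_mean, conc_sd
        ``(n_groups, n_fractions)`` concentrations in percent of the common
        reference base.
    weight_mean, weight_sd
        ``(n_fractions, n_proxies)`` routing weights in percent; means must sum
        to 100 over fractions for each proxy.
    offset_mean, offset_sd, consumer_mean, consumer_sd
        ``(n_proxies,)`` diet-to-tissue offsets and measured consumer signals.
        A consumer sd of ``inf`` marks a proxy with no usable measurement
        (prior-only analyses).
    diet_fractions
        The subset of fractions that additively partition the food base; the
        whole-diet fraction intake (beta) is computed over these.  Derived
        pseudo-fractions — e.g. a "bulk" fraction whose concentration is the
        sum of the true macronutrient fractions — are excluded so diet totals
        are not double counted.  Defaults to all fractions.
    constraints
        Expert prior constraints in the text notation of
        :func:`dietmix.constraints.parse_constraint` (e.g. ``"Corn > Gluten"``).
    """

    groups: tuple[str, ...]
    fractions: tuple[str, ...]
    proxies: tuple[str, ...]
    signal_mean: np.ndarray
    signal_sd: np.ndarray
    signal_ok: np.ndarray
    conc_mean: np.ndarray
    conc_sd: np.ndarray
    weight_mean: np.ndarray
    weight_sd: np.ndarray
    offset_mean: np.ndarray
    offset_sd: np.ndarray
    consumer_mean: np.ndarray
    consumer_sd: np.ndarray
    diet_fractions: tuple[str, ...] = ()
    constraints: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        self.groups = _as_tuple(self.groups)
        self.fractions = _as_tuple(self.fractions)
        self.proxies = _as_tuple(self.proxies)
        if not self.diet_fractions:
            self.diet_fractions = self.fractions
        else:
            self.diet_fractions = _as_tuple(self.diet_fractions)
        nI, nJ, nK = len(self.groups), len(self.fractions), len(self.proxies)
        shapes = {
            "signal_mean": (nI, nJ, nK),
            "signal_sd": (nI, nJ, nK),
            "signal_ok": (nI, nJ, nK),
            "conc_mean": (nI, nJ),
            "conc_sd": (nI, nJ),
            "weight_mean": (nJ, nK),
            "weight_sd": (nJ, nK),
            "offset_mean": (nK,),
            "offset_sd": (nK,),
            "consumer_mean": (nK,),
            "consumer_sd": (nK,),
        }
        for attr, shape in shapes.items():
            arr = np.asarray(getattr(self, attr), dtype=bool if attr == "signal_ok" else float)
            if arr.shape != shape:
                raise ScenarioError(f"{attr} has shape {arr.shape}, expected {shape}")
            setattr(self, attr, arr)
        self.constraints = tuple(self.constraints)

    # -- axis helpers -----------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    @property
    def n_proxies(self) -> int:
        return len(self.proxies)

    def group_index(self, name: str) -> int:
        return self.groups.index(name)

    def fraction_index(self, name: str) -> int:
        return self.fractions.index(name)

    def proxy_index(self, name) -> int:
        if isinstance(name, (int, np.integer)):
            return int(name)
        return self.proxies.index(name)

    @property
    def diet_fraction_indices(self) -> np.ndarray:
        return np.array([self.fractions.index(f) for f in self.diet_fractions], dtype=int)

    def signal(self, group: str, fraction: str, proxy: str) -> UncertainValue | None:
        i, j, k = self.group_index(group), self.fraction_index(fraction), self.proxy_index(proxy)
        if not self.signal_ok[i, j, k]:
            return None
        return UncertainValue(float(self.signal_mean[i, j, k]), float(self.signal_sd[i, j, k]))

    def with_constraints(self, constraints) -> "DietaryScenario":
        return replace(self, constraints=tuple(constraints))

    # -- effective routing participation ----------------------------------
    def routed(self) -> np.ndarray:
        """(n_fractions, n_proxies) mask of fractions that can reach a proxy."""
        return (self.weight_mean > 0) | (self.weight_sd > 0)


@dataclass(frozen=True)
class DietProportions:
    """A point on the food-group simplex: alpha_i >= 0, sum alpha_i = 1."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("alpha must be a 1-d vector")
        if np.any(a < -_SIMPLEX_TOL):
            raise ValueError(f"alpha has negative entries: {a}")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError(f"alpha must sum to 1, got {a.sum()!r}")


@dataclass
class LatentState:
    """One realisation of every uncertain quantity in a scenario.

    Quantities with ``sd == 0`` equal their means in every draw; sampled
    concentrations are truncated at zero.
    """

    alpha: np.ndarray
    signal: np.ndarray
    conc: np.ndarray
    weight: np.ndarray
    offset: np.ndarray

    @classmethod
    def from_means(cls, scenario: DietaryScenario, alpha) -> "LatentState":
        """State with every latent pinned at its mean (the modal scenario)."""
        a = alpha.alpha if isinstance(alpha, DietProportions) else np.asarray(alpha, float)
        DietProportions(a)  # validates the simplex
        return cls(
            alpha=a,
            signal=scenario.signal_mean.copy(),
            conc=scenario.conc_mean.copy(),
            weight=scenario.weight_mean.copy(),
            offset=scenario.offset_mean.copy(),
        )


# ---------------------------------------------------------------------------
# Batched forward kernels.  States are stacked on a leading batch axis so the
# MCMC engine can evaluate many chains in one numpy pass.
# ---------------------------------------------------------------------------

def _fraction_averages(scenario, alpha, conc, signal):
    """Per-fraction concentration-weighted source averages m[..., j, k].

    ``alpha``: (..., nI); ``conc``: (..., nI, nJ); ``signal``: (..., nI, nJ, nK).
    Fractions that are not routed into a proxy get m = 0 (they are skipped by
    the zero weight anyway).  Returns (m, denom) with denom of shape (..., nJ).
    """
    routed = scenario.routed()  # (nJ, nK)
    mass = alpha[..., :, None] * conc  # (..., nI, nJ)
    denom = mass.sum(axis=-2)  # (..., nJ)
    sig = np.where(scenario.signal_ok, signal, 0.0)
    num = np.einsum("...ij,...ijk->...jk", mass, sig)
    safe = np.where(denom[..., None] > 0, denom[..., None], 1.0)
    m = np.where(routed, num / safe, 0.0)
    return m, denom


def _predict_batch(scenario, alpha, conc, signal, weight, offset):
    """Predicted consumer signal for every proxy, batched; returns (..., nK)."""
    m, denom = _fraction_averages(scenario, alpha, conc, signal)
    routed = scenario.routed()
    degen = (denom[..., None] <= 0) & routed & (weight != 0)
    if np.any(degen):
        j, k = [int(x) for x in np.argwhere(degen)[0][-2:]]
        raise ScenarioError(
            f"no dietary mass reaches fraction {scenario.fractions[j]!r} for proxy "
            f"{scenario.proxies[k]!r}: sum_i alpha_i * c_ij is zero"
        )
    return offset + np.einsum("...jk,...jk->...k", weight / 100.0, m)


def predict_consumer_signal(scenario: DietaryScenario, state: LatentState, proxy) -> float:
    """Forward-model consumer signal for one proxy given a latent state.

    Implements ``offset_k + sum_j (w_jk/100) * m_jk`` with the per-fraction
    concentration-weighted averages ``m_jk`` described in the module docstring.
    Deterministic given the state.
    """
    k = scenario.proxy_index(proxy)
    pred = _predict_batch(
        scenario, state.alpha, state.conc, state.signal, state.weight, state.offset
    )
    return float(pred[k])


def _beta_batch(scenario, alpha, conc):
    """Whole-diet fraction intakes over ``diet_fractions``; shape (..., nDF)."""
    idx = scenario.diet_fraction_indices
    mass = (alpha[..., :, None] * conc[..., idx]).sum(axis=-2)
    total = mass.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ScenarioError("total dietary mass is zero: all concentrations vanish")
    return mass / total


def fraction_intake(alpha, scenario: DietaryScenario, state: LatentState | None = None) -> np.ndarray:
    """Relative intake beta_j of each diet fraction, a weighted average of
    fraction concentrations by food-group proportions.

    Returns a simplex vector aligned with ``scenario.diet_fractions``.
    """
    a = alpha.alpha if isinstance(alpha, DietProportions) else np.asarray(alpha, float)
    conc = state.conc if state is not None else scenario.conc_mean
    return _beta_batch(scenario, a, conc)


def _pi_batch(scenario, alpha, conc, weight):
    """Share of each proxy signal attributable to each group; (..., nI, nK)."""
    routed = scenario.routed()
    mass = alpha[..., :, None] * conc  # (..., nI, nJ)
    denom = mass.sum(axis=-2)  # (..., nJ)
    safe = np.where(denom > 0, denom, 1.0)
    share = mass / safe[..., None, :]  # (..., nI, nJ) within-fraction group share
    w = np.where(routed, weight, 0.0) / 100.0
    pi = np.einsum("...ij,...jk->...ik", share, w)
    tot = pi.sum(axis=-2, keepdims=True)
    if np.any(tot <= 0):
        raise ScenarioError("zero total signal mass for a proxy")
    return pi / tot


def proxy_contribution(alpha, scenario: DietaryScenario, state: LatentState | None = None, proxy=None) -> np.ndarray:
    """Share pi_ik of the proxy-k signal mass attributable to each food group.

    Each routed fraction contributes its routing weight split among groups in
    proportion to alpha_i * c_ij; shares are renormalised to a simplex over
    groups.  With equal concentrations and a single fraction this reduces to
    pi = alpha.
    """
    if proxy is None:
        raise TypeError("proxy_contribution requires a proxy name or index")
    a = alpha.alpha if isinstance(alpha, DietProportions) else np.asarray(alpha, float)
    conc = state.conc if state is not None else scenario.conc_mean
    weight = state.weight if state is not None else scenario.weight_mean
    k = scenario.proxy_index(proxy)
    return _pi_batch(scenario, a, conc, weight)[..., k]


def validate_scenario(scenario: DietaryScenario) -> list[str]:
    """Check every structural invariant; returns a list of violation messages.

    An empty list means the scenario is valid.  Reported rules: unique axis
    names, non-negative concentrations and sds, routing weights summing to
    100% per proxy, and availability of every source signal that can actually
    contribute (positive routing weight and positive concentration).
    """
    v: list[str] = []
    for axis, names in (("group", scenario.groups), ("fraction", scenario.fractions),
                        ("proxy", scenario.proxies)):
        if len(set(names)) != len(names):
            v.append(f"duplicate {axis} names: {names}")
    if scenario.n_groups < 2:
        v.append(f"need at least 2 food groups, got {scenario.n_groups}")
    for arr, what in ((scenario.signal_sd, "signal"), (scenario.conc_sd, "concentration"),
                      (scenario.weight_sd, "weight"), (scenario.offset_sd, "offset"),
                      (scenario.consumer_sd, "consumer")):
        if np.any(arr < 0):
            v.append(f"negative sd in {what} table")
    if np.any(scenario.conc_mean < 0):
        bad = np.argwhere(scenario.conc_mean < 0)
        for i, j in bad:
            v.append(
                f"negative concentration for group {scenario.groups[i]!r}, "
                f"fraction {scenario.fractions[j]!r}"
            )
    wsum = scenario.weight_mean.sum(axis=0)
    for k, s in enumerate(wsum):
        if abs(s - 100.0) > _WEIGHT_SUM_TOL:
            v.append(
                f"routing weights for proxy {scenario.proxies[k]!r} sum to {s:g}, "
                "expected 100"
            )
    routed = scenario.routed()
    for i in range(scenario.n_groups):
        for j in range(scenario.n_fractions):
            if scenario.conc_mean[i, j] <= 0 and scenario.conc_sd[i, j] == 0:
                continue  # fraction absent from this group
            for k in range(scenario.n_proxies):
                if routed[j, k] and not scenario.signal_ok[i, j, k]:
                    v.append(
                        f"missing signal for group {scenario.groups[i]!r}, fraction "
                        f"{scenario.fractions[j]!r}, proxy {scenario.proxies[k]!r} "
                        "(routed fraction with positive concentration)"
                    )
    unknown = set(scenario.diet_fractions) - set(scenario.fractions)
    if unknown:
        v.append(f"diet_fractions not in fractions: {sorted(unknown)}")
    if np.any(scenario.consumer_sd == 0):
        k = int(np.argmin(scenario.consumer_sd))
        v.append(
            f"consumer signal for proxy {scenario.proxies[k]!r} has sd 0; a measured "
            "signal needs a positive measurement uncertainty (use inf for 'no data')"
        )
    return v
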