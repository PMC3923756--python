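"""Priors on the food-group simplex.

The default prior on diet proportions is a Dirichlet with unit
hyperparameters (uniform on the simplex).  Informative marginals can be
elicited as a mean and standard deviation for one component: a Beta(a, b)
distribution with

    a = m * (m (1 - m) / s^2 - 1),    b = (1 - m) * (m (1 - m) / s^2 - 1)

has exactly mean ``m`` and sd ``s`` whenever ``s^2 < m (1 - m)``.  Since the
marginal of component *i* of a Dirichlet(gamma) is Beta(gamma_i, gamma_0 -
gamma_i), pinning one marginal fixes the total concentration gamma_0 = a + b
and the remainder is spread evenly over the other components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BetaShapes", "beta_shapes_from_moments", "DirichletPrior"]


@dataclass(frozen=True)
class BetaShapes:
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"beta shapes must be positive, got a={self.a}, b={self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def sd(self) -> float:
        t = self.a + self.b
        return float(np.sqrt(self.a * self.b / (t * t * (t + 1.0))))


def beta_shapes_from_moments(mean: float, sd: float) -> BetaShapes:
    """Beta shape parameters reproducing a requested mean and sd exactly.

    Raises
    ------
    ValueError
        If ``sd**2 >= mean * (1 - mean)``, the largest variance a beta
        distribution with that mean can attain.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    bound = mean * (1.0 - mean)
    if sd * sd >= bound:
        raise ValueError(
            f"infeasible beta variance: sd^2 = {sd * sd:g} must be < "
            f"mean*(1-mean) = {bound:g}"
        )
    nu = bound / (sd * sd) - 1.0
    return BetaShapes(mean * nu, (1.0 - mean) * nu)


class DirichletPrior:
    """Dirichlet prior over diet proportions with reproducible sampling."""

    def __init__(self, n_groups: int, concentration=None):
        if n_groups < 2:
            raise ValueError("a mixing prior needs at least 2 groups")
        if concentration is None:
            concentration = np.ones(n_groups)
        gamma = np.asarray(concentration, dtype=float)
        if gamma.shape != (n_groups,):
            raise ValueError(f"expected {n_groups} hyperparameters, got shape {gamma.shape}")
        if np.any(gamma <= 0):
            raise ValueError(f"hyperparameters must be positive, got {gamma}")
        self.n_groups = int(n_groups)
        self.concentration = gamma

    @classmethod
    def with_component(cls, n_groups: int, index: int, mean: float, sd: float) -> "DirichletPrior":
        """Prior whose ``index`` marginal is the Beta matched to (mean, sd),
        with the remaining concentration balanced over the other components."""
        shapes = beta_shapes_from_moments(mean, sd)
        gamma = np.full(n_groups, shapes.b / (n_groups - 1))
        gamma[index] = shapes.a
        return cls(n_groups, gamma)

    @property
    def uniform(self) -> bool:
        return bool(np.all(self.concentration == 1.0))

    def logpdf(self, alpha) -> np.ndarray | float:
        """Log-density on the open simplex; batched over leading axes."""
        a = np.asarray(alpha, dtype=float)
        scalar = a.ndim == 1
        a = np.atleast_2d(a)
        out = np.full(a.shape[0], -np.inf)
        ok = np.all(a > 0, axis=-1) & (np.abs(a.sum(-1) - 1.0) < 1e-8)
        if np.any(ok):
            g = self.concentration
            out[ok] = np.sum((g - 1.0) * np.log(a[ok]), axis=-1) + _log_norm(g)
        return float(out[0]) if scalar else out

    def marginal(self, index: int) -> BetaShapes:
        g0 = float(self.concentration.sum())
        gi = float(self.concentration[index])
        return BetaShapes(gi, g0 - gi)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet(self.concentration, size=size)


def _log_norm(gamma: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(gammaln(gamma.sum()) - gammaln(gamma).sum())
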