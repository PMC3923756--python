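"""Expert prior constraints as pseudo-observations.

Prior knowledge about relative intakes is written as small algebraic
relations over food-group intakes (alpha) and whole-diet fraction intakes
(beta), e.g.::

    Corn > Gluten          # the Corn intake exceeds the Gluten intake
    Protein > 5            # protein supplies more than 5% of the diet
    Protein < 40
    Plant + Animal = 0.5

Each relation is canonicalised to an expression ``g(alpha, beta)`` with
``x < y``  ->  ``y - x > 0`` and ``x = y``  ->  ``x - y = 0``, and enters the
posterior as a fictitious observation:

* equality: a zero observed under Normal(g, sigma_R) with a small fixed
  sigma_R, softly pinning g to zero;
* inequality: a one observed under Bernoulli(H(g)) with H the Heaviside step
  (H(0) = 1), i.e. hard truncation of the posterior to the half-space g >= 0.

The grammar is restricted to linear expressions in alpha and beta with
rational constants; symbols resolve against the scenario's group and
diet-fraction names.  Bare numeric literals larger than 1 on one side of a
relation are read as percentages and divided by 100 (matching the field's
habit of quoting intakes in percent).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .scenario import DietaryScenario

__all__ = ["Constraint", "ConstraintParseError", "parse_constraint", "constraint_log_term"]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_R = 0.001  # proportion scale; "much smaller" than typical prior sds

_LOG_NORM_CONST = -0.5 * np.log(2.0 * np.pi)


class ConstraintParseError(ValueError):
    """Malformed or unresolvable constraint text; carries the source position."""

    def __init__(self, message: str, text: str = "", pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos} in {text!r})"
        super().__init__(message)
        self.pos = pos


@dataclass(frozen=True)
class Constraint:
    """A parsed linear relation, compiled to coefficient vectors.

    ``g = coef_alpha . alpha + coef_beta . beta + const`` with ``kind`` either
    ``"eq"`` (g pinned to 0) or ``"gt"`` (support restricted to g >= 0).
    """

    kind: str  # "eq" | "gt"
    coef_alpha: np.ndarray
    coef_beta: np.ndarray
    const: float
    sigma: float
    text: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("eq", "gt"):
            raise ValueError(f"kind must be 'eq' or 'gt', got {self.kind!r}")
        if self.kind == "eq" and not self.sigma > 0:
            raise ValueError("equality constraints need sigma_R > 0")
        object.__setattr__(self, "coef_alpha", np.asarray(self.coef_alpha, float))
        object.__setattr__(self, "coef_beta", np.asarray(self.coef_beta, float))

    def value(self, alpha, beta=None) -> np.ndarray | float:
        """Evaluate g; batched over leading axes of alpha/beta."""
        a = np.asarray(alpha, float)
        g = a @ self.coef_alpha + self.const
        if np.any(self.coef_beta != 0):
            if beta is None:
                raise ValueError(f"constraint {self.text!r} references fraction intakes")
            g = g + np.asarray(beta, float) @ self.coef_beta
        return g


# -- tokenizer / recursive-descent parser -----------------------------------

_TOKEN = re.compile(
    r"(?:(?P<num>\d+\.?\d*|\.\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<quoted>'[^']*'|\"[^\"]*\")|(?P<op><=|>=|[-+*()<>=]))"
)


def _tokenize(text: str):
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if not m:
            raise ConstraintParseError("unexpected character", text, pos)
        if m.lastgroup == "num":
            tokens.append(("num", float(m.group("num")), pos))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name"), pos))
        elif m.lastgroup == "quoted":
            tokens.append(("name", m.group("quoted")[1:-1], pos))
        else:
            tokens.append(("op", m.group("op"), pos))
        pos = m.end()
    return tokens


class _Lin:
    """Linear form: coefficient per symbol plus a constant."""

    __slots__ = ("coef", "const")

    def __init__(self, coef=None, const=0.0):
        self.coef = dict(coef or {})
        self.const = const

    def __add__(self, other):
        out = _Lin(self.coef, self.const + other.const)
        for s, c in other.coef.items():
            out.coef[s] = out.coef.get(s, 0.0) + c
        return out

    def __neg__(self):
        return _Lin({s: -c for s, c in self.coef.items()}, -self.const)

    def __sub__(self, other):
        return self + (-other)

    def scale(self, k: float):
        return _Lin({s: k * c for s, c in self.coef.items()}, k * self.const)

    @property
    def is_const(self) -> bool:
        return not self.coef


class _Parser:
    def __init__(self, tokens, text):
        self.tokens, self.text, self.i = tokens, text, 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else ("end", "", len(self.text))

    def next(self):
        t = self.peek()
        self.i += 1
        return t

    def expr(self) -> _Lin:
        out = self.term()
        while self.peek()[:2] in (("op", "+"), ("op", "-")):
            _, op, _ = self.next()
            rhs = self.term()
            out = out + rhs if op == "+" else out - rhs
        return out

    def term(self) -> _Lin:
        out = self.factor()
        while self.peek()[:2] == ("op", "*"):
            self.next()
            rhs = self.factor()
            if out.is_const:
                out = rhs.scale(out.const)
            elif rhs.is_const:
                out = out.scale(rhs.const)
            else:
                raise ConstraintParseError(
                    "nonlinear term: products of intake symbols are not supported",
                    self.text, self.peek()[2])
        return out

    def factor(self) -> _Lin:
        kind, val, pos = self.next()
        if kind == "num":
            return _Lin(const=val)
        if kind == "name":
            return _Lin({val: 1.0})
        if kind == "op" and val == "-":
            return -self.factor()
        if kind == "op" and val == "(":
            inner = self.expr()
            k2, v2, p2 = self.next()
            if (k2, v2) != ("op", ")"):
                raise ConstraintParseError("expected ')'", self.text, p2)
            return inner
        raise ConstraintParseError(f"unexpected token {val!r}", self.text, pos)


def _resolve(symbols, scenario: DietaryScenario, text: str):
    """Map symbols to (alpha index | beta index); error on unknown/ambiguous."""
    nI = scenario.n_groups
    nB = len(scenario.diet_fractions)
    ca = np.zeros(nI)
    cb = np.zeros(nB)
    for sym, coef in symbols.items():
        in_g = sym in scenario.groups
        in_f = sym in scenario.diet_fractions
        if in_g and in_f:
            raise ConstraintParseError(
                f"symbol {sym!r} names both a group and a fraction", text)
        if in_g:
            ca[scenario.groups.index(sym)] += coef
        elif in_f:
            cb[list(scenario.diet_fractions).index(sym)] += coef
        else:
            raise ConstraintParseError(
                f"unknown symbol {sym!r}: not a food group or diet fraction", text)
    return ca, cb


def _percent_literal(side: _Lin, text: str) -> _Lin:
    if side.is_const and abs(side.const) > 1.0:
        logger.info("interpreting literal %g in %r as a percentage", side.const, text)
        return _Lin(const=side.const / 100.0)
    return side


def parse_constraint(text: str, scenario: DietaryScenario, sigma: float | None = None) -> Constraint:
    """Parse one constraint line against a scenario's symbol table.

    Accepted relations: ``<``, ``>``, ``=`` (and ``<=``/``>=``, treated as
    their strict counterparts since the boundary has zero posterior mass).
    ``sigma`` sets sigma_R for equality constraints (default 0.001 on the
    proportion scale); a warning is logged when it is not clearly smaller
    than the prior spread of the quantities it pins.
    """
    tokens = _tokenize(text)
    parser = _Parser(tokens, text)
    lhs = parser.expr()
    kind_tok = parser.next()
    if kind_tok[0] != "op" or kind_tok[1] not in ("<", ">", "=", "<=", ">="):
        raise ConstraintParseError("expected a relation (<, > or =)", text, kind_tok[2])
    rhs = parser.expr()
    if parser.peek()[0] != "end":
        raise ConstraintParseError("trailing input after relation", text, parser.peek()[2])

    lhs, rhs = _percent_literal(lhs, text), _percent_literal(rhs, text)
    rel = kind_tok[1][0]
    # canonical form: g > 0 or g = 0
    g = (rhs - lhs) if rel == "<" else (lhs - rhs)
    if g.is_const:
        raise ConstraintParseError("constraint references no intake symbols", text)
    ca, cb = _resolve(g.coef, scenario, text)
    kind = "eq" if rel == "=" else "gt"
    sig = DEFAULT_SIGMA_R if sigma is None else float(sigma)
    if kind == "eq":
        ref_sd = _prior_spread(scenario, ca, cb)
        if ref_sd > 0 and sig > 0.1 * ref_sd:
            logger.warning(
                "sigma_R=%g is not much smaller than the prior spread (%.3g) of the "
                "quantities constrained by %r; the equality will be soft", sig, ref_sd, text)
    return Constraint(kind=kind, coef_alpha=ca, coef_beta=cb, const=g.const,
                      sigma=sig, text=text)


def _prior_spread(scenario: DietaryScenario, ca, cb) -> float:
    """Smallest marginal prior sd (unit Dirichlet) among referenced intakes."""
    n = scenario.n_groups
    sd = np.sqrt((1.0 / n) * (1.0 - 1.0 / n) / (n + 1.0))
    refs = int(np.count_nonzero(ca)) + int(np.count_nonzero(cb))
    return sd if refs else 0.0


def constraint_log_term(constraint: Constraint, alpha, beta=None) -> np.ndarray | float:
    """Log-likelihood contribution of one pseudo-observation.

    Equality: log Normal(0 | g, sigma_R).  Inequality: 0 where g >= 0 and
    -inf otherwise (observing 1 under Bernoulli(H(g)); H(0) = 1 keeps the
    closed half-space).
    """
    g = constraint.value(alpha, beta)
    if constraint.kind == "eq":
        s = constraint.sigma
        return _LOG_NORM_CONST - np.log(s) - 0.5 * (np.asarray(g) / s) ** 2
    return np.where(np.asarray(g) >= 0.0, 0.0, -np.inf)
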