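"""Intervention treatment distributions q^g and their canonical representation.

An intervention treatment distribution assigns treatment at each interval as a
random draw from a distribution that may depend on the observed treatment
process f (the propensity score, at a binary treatment).  Two incremental
propensity score families are built in:

* *multiplicative shift* (delta in [0, 1]): among subjects with the indication
  ``L*_j = 1``, the probability of NOT initiating treatment is multiplied by
  delta, i.e. ``q(a) = (1-delta) l* a + (l* delta + 1 - l*) f(a)``.  delta=1
  leaves the observed process unchanged; delta=0 always treats the indicated.
* *odds shift* (delta in (0, inf)): the propensity odds are multiplied by
  delta, ``q(1) = delta f1 / (delta f1 + 1 - f1)``.

The multiplicative shift (and static/dynamic deterministic rules) admit the
canonical linear form

    q(a | .) = c1 h1 I(a = a*) + c2 h2 f(a | .) + c3 h3 p*(a | .)

on which the efficient-influence-function recursion and the multiply robust
estimators are built.  The odds shift has no exact canonical representation:
it is available evaluate-only (IPW/ICE), and the recursion-based estimators
refuse it explicitly rather than silently produce a non-robust estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "InterventionSpec",
    "PositivityReport",
    "NonCanonicalInterventionError",
    "multiplicative_shift_q",
    "odds_shift_q",
    "multiplicative_shift",
    "odds_shift",
    "static_intervention",
    "dynamic_intervention",
    "canonical_form",
    "positivity_check",
]

HistoryFn = Callable[[Mapping[str, np.ndarray]], np.ndarray]


class NonCanonicalInterventionError(ValueError):
    """The intervention has no canonical-form representation, so the
    recursion-based (weighted ICE / TMLE / EIF) path is unavailable."""


def multiplicative_shift_q(f1, l_star, a, delta):
    """q^g(a | .) under the multiplicative shift.

    Parameters are scalars or broadcastable arrays: ``f1`` the observed
    probability of treatment, ``l_star`` the indication indicator, ``a`` the
    treatment level evaluated, ``delta`` the shift in [0, 1].
    """
    if np.any((np.asarray(delta) < 0) | (np.asarray(delta) > 1)):
        raise ValueError("multiplicative shift requires delta in [0, 1]")
    f1 = np.asarray(f1, dtype=float)
    a = np.asarray(a)
    fa = np.where(a == 1, f1, 1.0 - f1)
    return (1.0 - delta) * l_star * a + (l_star * delta + 1.0 - l_star) * fa


def odds_shift_q(f1, a, delta):
    """q^g(a | .) under the odds shift of the propensity score."""
    if np.any(np.asarray(delta) <= 0):
        raise ValueError("odds shift requires delta > 0")
    f1 = np.asarray(f1, dtype=float)
    q1 = delta * f1 / (delta * f1 + (1.0 - f1))
    return np.where(np.asarray(a) == 1, q1, 1.0 - q1)


def _zero(cols: Mapping[str, np.ndarray]) -> np.ndarray:
    ref = next(iter(cols.values()))
    return np.zeros_like(np.asarray(ref, dtype=float))


def _one(cols: Mapping[str, np.ndarray]) -> np.ndarray:
    ref = next(iter(cols.values()))
    return np.ones_like(np.asarray(ref, dtype=float))


@dataclass(frozen=True)
class InterventionSpec:
    """An intervention treatment distribution, canonical where possible.

    ``h1``, ``h2``, ``h3`` map an interval history row (the accessor contract
    of :meth:`ipsi.panel.PanelData.frame`: covariates at j plus ``Alag``) to
    arrays; ``p_star(a, cols)`` is a non-degenerate pmf over treatment levels.
    ``a_star`` may be an int or a history-dependent callable (dynamic rules).
    """

    family: str
    delta: float | None = None
    a_star: int | HistoryFn | None = None
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    h1: HistoryFn = field(default=_zero)
    h2: HistoryFn = field(default=_zero)
    h3: HistoryFn = field(default=_zero)
    p_star: Callable[[int, Mapping[str, np.ndarray]], np.ndarray] | None = None
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.c3 != 0.0 and self.p_star is None:
            raise ValueError("c3 != 0 requires a p_star distribution")

    def a_star_values(self, cols: Mapping[str, np.ndarray]) -> np.ndarray:
        if callable(self.a_star):
            return np.asarray(self.a_star(cols), dtype=float)
        return np.full_like(_one(cols), float(self.a_star))

    def require_canonical(self) -> None:
        if not self.canonical:
            raise NonCanonicalInterventionError(
                f"intervention family {self.family!r} has no canonical-form "
                "representation; only IPW/ICE evaluation is supported"
            )

    # ---------------------------------------------------------------- evaluate
    def q(self, a, f1, cols: Mapping[str, np.ndarray]) -> np.ndarray:
        """Evaluate q^g(a | .) from the observed treatment probability f1."""
        f1 = np.asarray(f1, dtype=float)
        if self.family == "odds_shift":
            return odds_shift_q(f1, a, self.delta)
        a_arr = np.asarray(a, dtype=float)
        fa = np.where(a_arr == 1, f1, 1.0 - f1)
        out = self.c2 * self.h2(cols) * fa
        if self.c1 != 0.0:
            out = out + self.c1 * self.h1(cols) * (a_arr == self.a_star_values(cols))
        if self.c3 != 0.0:
            out = out + self.c3 * self.h3(cols) * self.p_star(a, cols)
        return out

    def q_observed(self, A, f1, cols) -> np.ndarray:
        """q^g evaluated at the observed treatment (NaN-safe off risk set)."""
        A = np.asarray(A, dtype=float)
        safe = np.where(np.isnan(A), 0.0, A)
        return self.q(safe, f1, cols)


def multiplicative_shift(delta: float) -> InterventionSpec:
    """Canonical multiplicative-shift spec: a*=1, c1=1-delta, c2=1, c3=0,
    h1 = l*, h2 = l* delta + 1 - l*."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("multiplicative shift requires delta in [0, 1]")
    return InterventionSpec(
        family="multiplicative_shift",
        delta=float(delta),
        a_star=1,
        c1=1.0 - delta,
        c2=1.0,
        h1=lambda cols: np.asarray(cols["lstar"], dtype=float),
        h2=lambda cols, d=float(delta): (
            np.asarray(cols["lstar"], dtype=float) * d
            + 1.0
            - np.asarray(cols["lstar"], dtype=float)
        ),
    )


def odds_shift(delta: float) -> InterventionSpec:
    """Evaluate-only odds-shift spec (flagged non-canonical)."""
    if delta <= 0:
        raise ValueError("odds shift requires delta > 0")
    return InterventionSpec(family="odds_shift", delta=float(delta),
                            canonical=False)


def static_intervention(a: int) -> InterventionSpec:
    """Deterministic static rule: q(. | .) = I(. = a)."""
    return InterventionSpec(family="static", a_star=int(a), c1=1.0, h1=_one)


def dynamic_intervention(rule: HistoryFn) -> InterventionSpec:
    """Deterministic dynamic rule; ``rule(cols)`` returns the assigned level."""
    return InterventionSpec(family="dynamic", a_star=rule, c1=1.0, h1=_one)


def canonical_form(family: str, delta: float | None = None,
                   a: int | HistoryFn | None = None) -> InterventionSpec:
    """Build an :class:`InterventionSpec` for a named family."""
    if family == "multiplicative_shift":
        return multiplicative_shift(delta)
    if family == "odds_shift":
        return odds_shift(delta)
    if family == "static":
        return static_intervention(a)
    if family == "dynamic":
        return dynamic_intervention(a)
    raise ValueError(f"unknown intervention family {family!r}")


@dataclass
class PositivityReport:
    """Report-only diagnostic for the generalized positivity condition:
    any treatment level possible under g must be possible in the data."""

    epsilon: float
    flags_per_interval: list[int]
    min_f_on_support: float
    weight_quantiles: dict[str, float]

    @property
    def total_flags(self) -> int:
        return int(sum(self.flags_per_interval))


def positivity_check(spec: InterventionSpec, panel, pi1: np.ndarray,
                     epsilon: float = 1e-3) -> PositivityReport:
    """Flag at-risk person-intervals where q^g(a|.) > 0 but the estimated
    observed treatment probability of that level is below ``epsilon``.

    ``pi1`` is the (n, J) array of fitted probabilities of treatment.  Never
    truncates anything; the report also summarises the distribution of the
    cumulative q-hat / pi-hat products.
    """
    flags: list[int] = []
    min_f = np.inf
    cum = None
    prods: list[np.ndarray] = []
    for j in range(panel.J):
        risk = panel.at_risk(j)
        f1 = pi1[:, j]
        cols = panel.frame(j)
        n_flag = 0
        for a in (0, 1):
            qa = np.asarray(spec.q(a, f1, cols), dtype=float)
            fa = f1 if a == 1 else 1.0 - f1
            on_support = risk & (qa > 0)
            # a near-violation needs g to demand the level beyond what the
            # observed process supplies; when q = f (e.g. delta = 1) the
            # intervention support coincides with the data and nothing is
            # flagged however small f is
            n_flag += int(np.sum(on_support & (fa < epsilon) & (qa > fa)))
            if np.any(on_support):
                min_f = min(min_f, float(np.nanmin(fa[on_support])))
        flags.append(n_flag)
        fobs = np.where(panel.A[:, j] == 1, f1, 1.0 - f1)
        qobs = spec.q_observed(panel.A[:, j], f1, cols)
        r = np.where(risk, qobs / np.clip(fobs, 1e-300, None), 1.0)
        cum = r if cum is None else cum * r
        prods.append(np.where(risk, cum, np.nan))
    allw = np.concatenate(prods)
    allw = allw[np.isfinite(allw)]
    qs = {}
    if allw.size:
        for p in (0.5, 0.9, 0.99, 1.0):
            qs[f"q{p:g}"] = float(np.quantile(allw, p))
    return PositivityReport(
        epsilon=epsilon,
        flags_per_interval=flags,
        min_f_on_support=float(min_f),
        weight_quantiles=qs,
    )
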