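"""Efficient influence functions for survival under canonical interventions.

For an intervention treatment distribution in the canonical form

    q^g(a | .) = c1 h1 I(a = a*) + c2 h2 f(a | .) + c3 h3 p*(a | .)

the EIF of the cumulative survival probability psi^g is the backward recursion

    U = sum_{j=1}^{J} (T_j - Q_{j-1}) prod_{k=0}^{j-1} q^g_k / f_k + T_0 - psi

with T_J = Y_J, Q_j = E(T_{j+1} | history, alive), and

    T_j = c1 Q_j^{A_j=a*} h1 + c2 Q_j h2 + c3 {sum_a p*(a) Q_j^a} h3,

where T_j = 0 whenever Y_j = 0.  Estimators built on this EIF are J+1 model
multiply robust.  For the multiplicative shift the update specialises to

    T_j = (1 - delta) Q_j^{A_j=1} l*_j + Q_j (l*_j delta + 1 - l*_j).

Censoring weights (inverse products of one minus the fitted censoring hazard)
fold into the cumulative ratio products when censoring is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .nuisance import CLIP

__all__ = ["EIFComponents", "tj_update", "eif_from_components",
           "point_treatment_eif"]


@dataclass
class EIFComponents:
    """Per-subject pieces of the EIF recursion.

    ``T[:, j]`` and ``Q[:, j]`` for j = 0..J (T[:, J] = Y_J); ``cumratio[:, j]``
    the cumulative weight product through interval j; ``U`` the final
    per-subject EIF value; ``psi`` the reference parameter value.
    """

    T: np.ndarray
    Q: np.ndarray
    cumratio: np.ndarray
    U: np.ndarray
    psi: float


def tj_update(spec, cols: Mapping[str, np.ndarray], Q_obs: np.ndarray,
              Q_astar: np.ndarray | None = None,
              Q_levels: Mapping[int, np.ndarray] | None = None) -> np.ndarray:
    """The canonical-form T_j update from outcome-regression evaluations.

    ``Q_obs`` is Q_j at the observed treatment, ``Q_astar`` at A_j = a*,
    ``Q_levels`` maps treatment levels to Q_j^a for the p*-weighted term.
    """
    spec.require_canonical()
    T = spec.c2 * spec.h2(cols) * Q_obs if spec.c2 != 0.0 else np.zeros_like(Q_obs)
    if spec.c1 != 0.0:
        if Q_astar is None:
            raise ValueError("c1 != 0 requires Q_j evaluated at a*")
        T = T + spec.c1 * spec.h1(cols) * Q_astar
    if spec.c3 != 0.0:
        if Q_levels is None:
            raise ValueError("c3 != 0 requires Q_j at every treatment level")
        mix = np.zeros_like(Q_obs)
        for a, Qa in Q_levels.items():
            mix = mix + spec.p_star(a, cols) * Qa
        T = T + spec.c3 * spec.h3(cols) * mix
    return T


def eif_from_components(panel, spec, pi1: np.ndarray,
                        Q_obs: np.ndarray, Q_astar: np.ndarray,
                        psi: float,
                        censoring_hazard: np.ndarray | None = None,
                        Q_levels: Sequence[Mapping[int, np.ndarray]] | None = None,
                        ) -> EIFComponents:
    """Evaluate the EIF recursion from fitted nuisance evaluations.

    ``Q_obs[:, j]`` / ``Q_astar[:, j]`` are the interval-j outcome regressions
    at the observed treatment and at a*; rows off the interval-j risk set are
    ignored (their T_j is zero by construction).
    """
    spec.require_canonical()
    n, J = panel.n, panel.J
    T = np.zeros((n, J + 1))
    Q = np.zeros((n, J + 1))
    YJ = panel.Y[:, J]
    T[:, J] = np.where(np.isnan(YJ), 0.0, YJ)
    cum = np.ones((n, J))
    ratio = np.ones((n, J))
    for j in range(J):
        risk = panel.at_risk(j)
        fobs = np.clip(
            np.where(np.where(np.isnan(panel.A[:, j]), 0, panel.A[:, j]) == 1,
                     pi1[:, j], 1.0 - pi1[:, j]),
            CLIP, 1 - CLIP,
        )
        qobs = spec.q_observed(panel.A[:, j], pi1[:, j], panel.frame(j))
        r = np.where(risk, qobs / fobs, 0.0)
        if censoring_hazard is not None:
            unc = risk & (panel.C[:, j + 1] == 0)
            r = np.where(unc,
                         r / np.clip(1.0 - censoring_hazard[:, j], CLIP, None),
                         0.0)
        ratio[:, j] = r
        cum[:, j] = r if j == 0 else cum[:, j - 1] * r
    for j in range(J - 1, -1, -1):
        risk = panel.at_risk(j)
        cols = panel.frame(j)
        Qj = np.where(risk, Q_obs[:, j], 0.0)
        Tj = tj_update(spec, cols, Qj,
                       Q_astar=np.where(risk, Q_astar[:, j], 0.0),
                       Q_levels=None if Q_levels is None else Q_levels[j])
        T[:, j] = np.where(risk, Tj, 0.0)
        Q[:, j] = Qj
    U = T[:, 0] - psi
    for j in range(1, J + 1):
        U = U + (T[:, j] - Q[:, j - 1]) * cum[:, j - 1]
    return EIFComponents(T=T, Q=Q, cumratio=cum, U=U, psi=psi)


def point_treatment_eif(y: np.ndarray, a: np.ndarray,
                        h1_values: np.ndarray, h2_values: np.ndarray,
                        h2_cond_obs: np.ndarray, h2_cond_astar: np.ndarray,
                        f_obs: np.ndarray, c1: float, c2: float,
                        psi: float) -> np.ndarray:
    """Point-treatment (J = 1) EIF for psi = c1 E{h1(O)} + c2 E[E{h2(O)|A=a*,L}].

    ``h2_cond_obs`` and ``h2_cond_astar`` are fitted E{h2(O) | A, L} at the
    observed treatment and at a*; ``f_obs`` is f(A | L) at the observed
    treatment with the indicator I(A = a*) already folded in by passing
    f_obs = f(A|L) and masking through ``a`` (the indicator array I(A=a*)).
    """
    f = np.clip(np.asarray(f_obs, dtype=float), CLIP, 1 - CLIP)
    ind = np.asarray(a, dtype=float)
    aug = ind / f * (np.asarray(h2_values, float) - np.asarray(h2_cond_obs, float))
    return (c1 * np.asarray(h1_values, float)
            + c2 * (aug + np.asarray(h2_cond_astar, float)) - psi)
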