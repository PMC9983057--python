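"""Built-in data-generating processes, intervention-world truths, and
replication drivers.

Two longitudinal survival DGPs over J = 5 treatment intervals are built in:

* ``study1`` -- all-binary confounders ``(L*, L1, L2)``, non-absorbing
  treatment, covariate-dependent censoring.  Designed so that parametric
  working models can be specified exactly right or deliberately wrong
  (:func:`misspecified_formulas`).
* ``study2`` -- continuous covariates, interaction/absolute-value/power terms
  in the hazards, and an absorbing treatment (once initiated it stays on),
  exercising machine-learning nuisance estimation.

Intervention-world truths are computed by Monte Carlo (treatment drawn from
q^g built from the true treatment probabilities, censoring never occurs) or by
exact enumeration on small finite discrete laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .interventions import InterventionSpec, multiplicative_shift
from .panel import PanelData

__all__ = [
    "simulate_study1",
    "simulate_study2",
    "monte_carlo_truth",
    "TruthResult",
    "DiscreteLaw",
    "exact_gformula",
    "sample_discrete_law",
    "empirical_law",
    "misspecified_formulas",
    "ScenarioConfig",
    "run_replications",
    "summarize_replications",
]


# --------------------------------------------------------------- study 1 DGP
# Each conditional law lives in its own small function so that alternate
# readings of the model formulas are one-line changes.

def _s1_lstar0(rng, n):
    return (rng.random(n) < expit(-1)).astype(float)


def _s1_l10(rng, n):
    return (rng.random(n) < expit(-1)).astype(float)


def _s1_l20(rng, lstar0):
    return (rng.random(lstar0.size) < expit(1 + lstar0)).astype(float)


def _s1_lstar(rng, alag, lstar_prev, l1_prev, l2_prev):
    p = expit(-1 - alag + lstar_prev - l1_prev + l2_prev)
    return (rng.random(p.size) < p).astype(float)


def _s1_l1(rng, alag, l1_prev, l2_prev):
    p = expit(-1 + alag + l1_prev - l2_prev)
    return (rng.random(p.size) < p).astype(float)


def _s1_l2(rng, alag, lstar_cur, l2_prev):
    p = expit(1 + alag + lstar_cur + l2_prev)
    return (rng.random(p.size) < p).astype(float)


def _s1_treat_prob(lstar, l1, l2, alag):
    return expit(-1 - 2 * lstar - l1 + l2 + 2 * alag)


def _s1_cens_prob(l1, l2):
    return expit(-2 + l1 - l2)


def _s1_surv_prob(a, lstar, l1, l2):
    return expit(1 + 3 * a - 2 * lstar + l1 - l2)


def _study1_engine(n, seed, delta=None, censoring=True, J=5):
    rng = np.random.default_rng(seed)
    lstar = np.zeros((n, J)); l1 = np.zeros((n, J)); l2 = np.zeros((n, J))
    A = np.zeros((n, J))
    C = np.zeros((n, J + 1)); Y = np.ones((n, J + 1))
    lstar[:, 0] = _s1_lstar0(rng, n)
    l1[:, 0] = _s1_l10(rng, n)
    l2[:, 0] = _s1_l20(rng, lstar[:, 0])
    alag = np.zeros(n)
    for j in range(J):
        alive = (Y[:, j] == 1) & (C[:, j] == 0)
        if j > 0:
            lstar[:, j] = _s1_lstar(rng, alag, lstar[:, j - 1],
                                    l1[:, j - 1], l2[:, j - 1])
            l1[:, j] = _s1_l1(rng, alag, l1[:, j - 1], l2[:, j - 1])
            l2[:, j] = _s1_l2(rng, alag, lstar[:, j], l2[:, j - 1])
        f1 = _s1_treat_prob(lstar[:, j], l1[:, j], l2[:, j], alag)
        if delta is not None:
            p1 = (1 - delta) * lstar[:, j] + (lstar[:, j] * delta
                                              + 1 - lstar[:, j]) * f1
        else:
            p1 = f1
        A[:, j] = (rng.random(n) < p1).astype(float)
        if censoring:
            ch = _s1_cens_prob(l1[:, j], l2[:, j])
            cnew = (rng.random(n) < ch).astype(float)
            C[:, j + 1] = np.where(alive, np.maximum(C[:, j], cnew), C[:, j])
        else:
            C[:, j + 1] = C[:, j]
        unc = alive & (C[:, j + 1] == 0)
        ps = _s1_surv_prob(A[:, j], lstar[:, j], l1[:, j], l2[:, j])
        ynew = (rng.random(n) < ps).astype(float)
        Y[:, j + 1] = np.where(unc, ynew, Y[:, j])
        alag = np.where(alive, A[:, j], alag)
    return {"lstar": lstar, "L1": l1, "L2": l2}, A, C, Y


# --------------------------------------------------------------- study 2 DGP
def _s2_l10(rng, l01):
    return 2 + l01 + rng.standard_normal(l01.size)


def _s2_lstar0(rng, l10, l01, l02):
    p = expit(1.5 - 0.5 * l10 + l01 + 0.25 * l02)
    return (rng.random(p.size) < p).astype(float)


def _s2_l1(rng, alag, lstar_prev, l1_prev, l01):
    return 2 + alag - lstar_prev + 0.5 * l1_prev + l01 \
        + rng.standard_normal(l01.size)


def _s2_lstar(rng, alag, l1_cur, lstar_prev, l01, l02):
    p = expit(1.5 - alag - 0.5 * l1_cur + lstar_prev + l01 + 0.25 * l02)
    return (rng.random(p.size) < p).astype(float)


def _s2_treat_prob(lstar, l1, l01, l02):
    # the l* x l1 product is the literal reading of the interaction term
    return expit(-3 + lstar - 0.5 * l1 + 0.25 * lstar * l1
                 + 0.5 * l01 + 0.25 * l02 + 0.5 * np.abs(l02))


def _s2_cens_prob(a, lstar, l1, l02):
    return expit(-4 - a - lstar - 0.5 * np.abs(l1 * l02)
                 + 1.5 * np.abs(l1) / (1 + np.exp(l02)))


def _s2_surv_prob(a, lstar, l1, l01, l02):
    return expit(-1 + 2 * a - 2 * lstar + 0.25 * lstar * l1
                 + 0.5 * l01 + 0.75 * np.abs(l1 + l02) ** 1.5)


def _study2_engine(n, seed, delta=None, censoring=True, J=5):
    rng = np.random.default_rng(seed)
    l01 = (rng.random(n) < 0.5).astype(float)
    l02 = rng.standard_normal(n)
    l1 = np.zeros((n, J)); lstar = np.zeros((n, J))
    A = np.zeros((n, J))
    C = np.zeros((n, J + 1)); Y = np.ones((n, J + 1))
    l1[:, 0] = _s2_l10(rng, l01)
    lstar[:, 0] = _s2_lstar0(rng, l1[:, 0], l01, l02)
    alag = np.zeros(n)
    for j in range(J):
        alive = (Y[:, j] == 1) & (C[:, j] == 0)
        if j > 0:
            l1[:, j] = _s2_l1(rng, alag, lstar[:, j - 1], l1[:, j - 1], l01)
            lstar[:, j] = _s2_lstar(rng, alag, l1[:, j], lstar[:, j - 1],
                                    l01, l02)
        f1 = _s2_treat_prob(lstar[:, j], l1[:, j], l01, l02)
        f1 = np.where(alag == 1, 1.0, f1)  # absorbing treatment
        if delta is not None:
            p1 = (1 - delta) * lstar[:, j] + (lstar[:, j] * delta
                                              + 1 - lstar[:, j]) * f1
        else:
            p1 = f1
        A[:, j] = (rng.random(n) < p1).astype(float)
        if censoring:
            ch = _s2_cens_prob(A[:, j], lstar[:, j], l1[:, j], l02)
            cnew = (rng.random(n) < ch).astype(float)
            C[:, j + 1] = np.where(alive, np.maximum(C[:, j], cnew), C[:, j])
        else:
            C[:, j + 1] = C[:, j]
        unc = alive & (C[:, j + 1] == 0)
        ps = _s2_surv_prob(A[:, j], lstar[:, j], l1[:, j], l01, l02)
        ynew = (rng.random(n) < ps).astype(float)
        Y[:, j + 1] = np.where(unc, ynew, Y[:, j])
        alag = np.where(alive, A[:, j], alag)
    cov = {
        "lstar": lstar,
        "L1": l1,
        "L01": np.tile(l01[:, None], (1, J)),
        "L02": np.tile(l02[:, None], (1, J)),
    }
    return cov, A, C, Y


def _finalize_panel(cov, A, C, Y, J):
    """Apply the missingness rules: everything after death or censoring is
    missing-coded; Y is NaN once censored, 0 after death."""
    n = A.shape[0]
    for j in range(J):
        gone = (Y[:, j] != 1) | (C[:, j] == 1)
        for arr in cov.values():
            arr[gone, j] = np.nan
        A[gone, j] = np.nan
        Y[:, j + 1] = np.where(C[:, j + 1] == 1, np.nan, Y[:, j + 1])
        dead = Y[:, j] == 0
        Y[dead, j + 1] = 0.0
    return PanelData(covariates=cov, lstar="lstar", A=A, C=C, Y=Y)


def simulate_study1(n: int, seed: int, delta: float | None = None,
                    censoring: bool = True) -> PanelData:
    """Draw a study-1 panel (J = 5, binary confounders).

    ``delta`` switches treatment assignment to the multiplicative-shift
    intervention built from the true treatment probabilities (used for
    intervention-world simulation); ``censoring=False`` disables censoring.
    Identical ``(n, seed)`` give bitwise-identical panels.
    """
    cov, A, C, Y = _study1_engine(n, seed, delta=delta, censoring=censoring)
    return _finalize_panel(cov, A, C, Y, J=5)


def simulate_study2(n: int, seed: int, delta: float | None = None,
                    censoring: bool = True) -> PanelData:
    """Draw a study-2 panel (J = 5, continuous covariates, absorbing
    treatment)."""
    cov, A, C, Y = _study2_engine(n, seed, delta=delta, censoring=censoring)
    return _finalize_panel(cov, A, C, Y, J=5)


# ----------------------------------------------------------------- MC truth
@dataclass(frozen=True)
class TruthResult:
    psi: float
    mcse: float
    n_mc: int

    def __float__(self) -> float:
        return self.psi


def monte_carlo_truth(dgp, delta: float, n_mc: int = 1_000_000,
                      seed: int = 0, chunk: int = 1_000_000) -> TruthResult:
    """Intervention-world survival by forward simulation.

    Treatment is drawn from the multiplicative-shift q^g built from the true
    treatment probabilities, censoring never occurs, and the returned value is
    the fraction surviving through interval J with its Monte-Carlo standard
    error.  ``dgp`` is ``"study1"``, ``"study2"`` or a :class:`DiscreteLaw`.
    With ``delta=1`` the same seed stream reproduces the no-censoring
    observational survival of the DGP exactly.
    """
    if isinstance(dgp, DiscreteLaw):
        spec = multiplicative_shift(delta)
        panel = sample_discrete_law(dgp, n_mc, seed, spec=spec)
        psi = float(np.mean(panel.Y[:, dgp.J]))
        return TruthResult(psi, float(np.sqrt(psi * (1 - psi) / n_mc)), n_mc)
    engine = {"study1": _study1_engine, "study2": _study2_engine}[dgp]
    total, done, k = 0.0, 0, 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        _, _, _, Y = engine(m, seed + k, delta=delta, censoring=False)
        total += float(np.sum(Y[:, -1]))
        done += m
        k += 1
    psi = total / n_mc
    return TruthResult(psi, float(np.sqrt(psi * (1 - psi) / n_mc)), n_mc)


# ------------------------------------------------------------- discrete laws
@dataclass
class DiscreteLaw:
    """A small finite-state longitudinal law for exact enumeration.

    One discrete covariate per interval with values in ``levels``;
    ``p_l(j, l, lhist, ahist)`` is the covariate law given survival to j,
    ``f1(j, lhist, ahist)`` the treatment probability given the history
    including the current covariate, ``surv(j, lhist, ahist)`` the
    probability of surviving interval j given treatment.  ``lstar_of`` maps a
    covariate value to the indication indicator (identity by default).
    """

    J: int
    levels: Sequence[float]
    p_l: Callable[[int, float, tuple, tuple], float]
    f1: Callable[[int, tuple, tuple], float]
    surv: Callable[[int, tuple, tuple], float]
    lstar_of: Callable[[float], float] = field(default=lambda l: float(l))

    def validate(self) -> None:
        tot = sum(self.p_l(0, l, (), ()) for l in self.levels)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"covariate law not normalized at j=0: {tot}")


def _law_cols(law: DiscreteLaw, l: float, a_prev: float) -> dict:
    return {"lstar": np.array([law.lstar_of(l)]), "L": np.array([float(l)]),
            "Alag": np.array([float(a_prev)])}


def exact_gformula(law: DiscreteLaw, spec: InterventionSpec) -> float:
    """Exact summation of the generalized g-formula over all histories."""
    law.validate()

    def rec(j: int, lhist: tuple, ahist: tuple, prob: float) -> float:
        if prob == 0.0:
            return 0.0
        if j == law.J:
            return prob
        total = 0.0
        a_prev = ahist[-1] if ahist else 0.0
        for l in law.levels:
            pl = law.p_l(j, l, lhist, ahist)
            if pl == 0.0:
                continue
            f1 = law.f1(j, lhist + (l,), ahist)
            cols = _law_cols(law, l, a_prev)
            for a in (0.0, 1.0):
                q = float(spec.q(np.array([a]), np.array([f1]), cols)[0])
                if q == 0.0:
                    continue
                s = law.surv(j, lhist + (l,), ahist + (a,))
                total += rec(j + 1, lhist + (l,), ahist + (a,),
                             prob * pl * q * s)
        return total

    return rec(0, (), (), 1.0)


def sample_discrete_law(law: DiscreteLaw, n: int, seed: int,
                        spec: InterventionSpec | None = None) -> PanelData:
    """Sample a (censoring-free) panel from a discrete law, observationally
    or under an intervention spec."""
    rng = np.random.default_rng(seed)
    J = law.J
    L = np.zeros((n, J)); A = np.zeros((n, J))
    Y = np.ones((n, J + 1)); C = np.zeros((n, J + 1))
    lh = [tuple() for _ in range(n)]
    ah = [tuple() for _ in range(n)]
    # row-wise sampling; these laws are tiny fixtures so clarity wins
    for j in range(J):
        u_l = rng.random(n); u_a = rng.random(n); u_y = rng.random(n)
        for i in range(n):
            if Y[i, j] != 1:
                Y[i, j + 1] = 0.0
                L[i, j] = np.nan
                A[i, j] = np.nan
                continue
            acc, lval = 0.0, law.levels[-1]
            for l in law.levels:
                acc += law.p_l(j, l, lh[i], ah[i])
                if u_l[i] < acc:
                    lval = l
                    break
            f1 = law.f1(j, lh[i] + (lval,), ah[i])
            if spec is None:
                p1 = f1
            else:
                a_prev = ah[i][-1] if ah[i] else 0.0
                p1 = float(spec.q(np.array([1.0]), np.array([f1]),
                                  _law_cols(law, lval, a_prev))[0])
            a = 1.0 if u_a[i] < p1 else 0.0
            L[i, j] = lval
            A[i, j] = a
            ps = law.surv(j, lh[i] + (lval,), ah[i] + (a,))
            Y[i, j + 1] = 1.0 if u_y[i] < ps else 0.0
            lh[i] += (lval,)
            ah[i] += (a,)
    lstar = np.vectorize(law.lstar_of)(np.where(np.isnan(L), 0.0, L))
    lstar = np.where(np.isnan(L), np.nan, lstar)
    return PanelData(covariates={"L": L, "lstar": lstar}, lstar="lstar",
                     A=A, C=C, Y=Y)


def empirical_law(panel: PanelData, levels: Sequence[float] | None = None,
                  cov: str = "L") -> DiscreteLaw:
    """The empirical plug-in law of a censoring-free discrete panel.

    Conditional tables are the empirical frequencies given the full observed
    history; unreachable cells get probability zero.  Feeding the result to
    :func:`exact_gformula` gives the empirical plug-in g-formula estimate.
    """
    L, A, Y = panel.covariates[cov], panel.A, panel.Y
    if levels is None:
        levels = sorted(np.unique(L[~np.isnan(L)]).tolist())
    J = panel.J
    lstar_map = {}
    for j in range(J):
        alive = panel.at_risk(j)
        for l in levels:
            sel = alive & (L[:, j] == l)
            if np.any(sel):
                lstar_map[l] = float(
                    panel.covariates[panel.lstar][sel, j][0])
    n = panel.n

    def hist_mask(j, lhist, ahist):
        m = panel.Y[:, j] == 1
        for k in range(len(lhist)):
            m &= (L[:, k] == lhist[k])
        for k in range(len(ahist)):
            m &= (A[:, k] == ahist[k])
        return m

    def p_l(j, l, lhist, ahist):
        base = hist_mask(j, lhist, ahist)
        if not np.any(base):
            return 0.0
        return float(np.mean(L[base, j] == l))

    def f1(j, lhist, ahist):
        base = hist_mask(j, lhist[:-1], ahist) & (L[:, j] == lhist[-1])
        if not np.any(base):
            return 0.0
        return float(np.mean(A[base, j] == 1))

    def surv(j, lhist, ahist):
        base = hist_mask(j, lhist[:-1], ahist[:-1]) \
            & (L[:, j] == lhist[-1]) & (A[:, j] == ahist[-1])
        if not np.any(base):
            return 0.0
        return float(np.mean(Y[base, j + 1] == 1))

    return DiscreteLaw(J=J, levels=list(levels), p_l=p_l, f1=f1, surv=surv,
                       lstar_of=lambda l: lstar_map.get(l, float(l)))


# ------------------------------------------------------- model specification
def misspecified_formulas(scenario: str, J: int = 5) -> dict:
    """Per-interval working-model formulas for the study-1 scenarios.

    ``all_correct``: treatment/censoring in their true functional forms;
    outcome regressions saturated in ``(A, L*, L1, L2)`` for j < J-1 and the
    true main-terms form at j = J-1.  ``outcome_only`` (only the outcome
    models correct): the treatment model drops the treatment lag and the
    censoring working model ignores the censoring process's covariate
    dependence.  ``treatment_only`` (only treatment/censoring correct): the
    outcome regressions drop every treatment-covariate interaction.
    """
    from .nuisance import saturated_formula

    sat = saturated_formula(["A", "lstar", "L1", "L2"])
    cov_sat = saturated_formula(["lstar", "L1", "L2"])
    out_correct = [sat] * (J - 1) + ["A + lstar + L1 + L2"]
    out_wrong = [cov_sat + " + A"] * J
    trt_correct = "lstar + L1 + L2 + Alag"
    trt_wrong = "lstar + L1 + L2"
    cen_correct = "L1 + L2"
    cen_wrong = "1"
    if scenario == "all_correct":
        return {"treatment": trt_correct, "censoring": cen_correct,
                "outcome": out_correct}
    if scenario == "outcome_only":
        return {"treatment": trt_wrong, "censoring": cen_wrong,
                "outcome": out_correct}
    if scenario == "treatment_only":
        return {"treatment": trt_correct, "censoring": cen_correct,
                "outcome": out_wrong}
    raise ValueError(f"unknown scenario {scenario!r}")


# ------------------------------------------------------------ scenario grids
@dataclass
class ScenarioConfig:
    """One cell of a replication grid."""

    dgp: str = "study1"
    n: int = 500
    delta: float = 0.5
    scenario: str = "all_correct"
    replications: int = 200
    base_seed: int = 1
    estimators: Sequence[str] = ("wice", "ice", "ipw")
    learner_seed: int = 0
    folds: int = 5
    tmle_splits: int = 2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")

    def rep_seed(self, i: int) -> int:
        return int((self.base_seed + 1_000_003 * i) % (2 ** 31 - 1))


def _estimate_once(panel, spec, config: ScenarioConfig, seed: int) -> dict:
    from . import estimators as est
    from .nuisance import default_learners, fit_nuisance

    out = {}
    if config.dgp == "study1":
        forms = misspecified_formulas(config.scenario)
        nuis = fit_nuisance(panel, treatment_formulas=forms["treatment"],
                            censoring_formulas=forms["censoring"])
        if "wice" in config.estimators:
            out["wice"] = est.wice_estimate(panel, spec, nuis,
                                            forms["outcome"]).psi_hat
        if "ice" in config.estimators:
            out["ice"] = est.ice_estimate(panel, spec,
                                          forms["outcome"]).psi_hat
        if "ipw" in config.estimators:
            out["ipw"] = est.ipw_estimate(panel, spec, nuis).psi_hat
    else:
        learners = default_learners(seed=config.learner_seed)
        features = ["lstar", "L1", "L01", "L02", "Alag"]
        ofeatures = ["lstar", "L1", "L01", "L02", "A", "Alag"]
        if "ice" in config.estimators:
            out["ice"] = est.ice_estimate(
                panel, spec, learners=learners, outcome_features=ofeatures,
                folds=config.folds, seed=seed,
            ).psi_hat
        if "ipw" in config.estimators:
            nuis = fit_nuisance(panel, learners=learners, features=features,
                                absorbing=True, folds=config.folds, seed=seed)
            out["ipw"] = est.ipw_estimate(panel, spec, nuis).psi_hat
        if "tmle" in config.estimators:
            res = est.tmle_crossfit_estimate(
                panel, spec, learners=learners, M=config.tmle_splits,
                seed=seed, features=features, outcome_features=ofeatures,
                absorbing=True, folds=config.folds,
            )
            out["tmle"] = res.psi_hat
            out["tmle_se"] = res.se
    return out


def run_replications(config: ScenarioConfig) -> pd.DataFrame:
    """Run a replication grid cell; one row per (replication, estimator)."""
    sim = {"study1": simulate_study1, "study2": simulate_study2}[config.dgp]
    spec = multiplicative_shift(config.delta)
    rows = []
    for i in range(config.replications):
        seed = config.rep_seed(i)
        panel = sim(config.n, seed)
        res = _estimate_once(panel, spec, config, seed)
        se = res.pop("tmle_se", None)
        for method, psi in res.items():
            rows.append({"rep": i, "seed": seed, "method": method,
                         "psi_hat": psi,
                         "se": se if method == "tmle" else np.nan})
    return pd.DataFrame(rows)


def summarize_replications(results: pd.DataFrame, truth: float) -> pd.DataFrame:
    """Bias / SE / RMSE (x100, as conventionally tabulated) and, where an SE
    column is available, 95% CI coverage of the truth."""
    out = []
    for method, grp in results.groupby("method"):
        err = grp["psi_hat"].to_numpy() - truth
        row = {
            "method": method,
            "bias_x100": 100 * float(np.mean(err)),
            "se_x100": 100 * float(np.std(grp["psi_hat"], ddof=1)),
            "rmse_x100": 100 * float(np.sqrt(np.mean(err ** 2))),
            "mcse_x100": 100 * float(np.std(grp["psi_hat"], ddof=1)
                                     / np.sqrt(len(grp))),
        }
        if grp["se"].notna().any():
            z = 1.959963984540054
            cover = (np.abs(err) <= z * grp["se"].to_numpy())
            row["coverage"] = float(np.mean(cover))
        out.append(row)
    return pd.DataFrame(out)
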