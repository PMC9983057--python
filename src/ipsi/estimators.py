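"""Estimators of cumulative survival under incremental propensity score
interventions: ICE, IPW, weighted ICE, and cross-fit TMLE.

All four target the generalized g-formula value psi^g = Pr(Y_J^g = 1).  The
weighted ICE estimator runs the canonical-form backward recursion with
sequential weighted fractional-logistic outcome regressions; with unit weights
it is the singly robust ICE, and with intercept-only outcome models it
reproduces the IPW discrete-hazard product exactly.  The TMLE adds an
intercept-only logit fluctuation per interval, solved on held-out splits with
cross-fit nuisances, so that machine-learning nuisance estimators can be used
without Donsker conditions.

Censoring is handled by viewing the intervention as also eliminating
censoring: fitted censoring hazards enter the cumulative weights as inverse
products of one minus the hazard, applied to uncensored at-risk rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .eif import eif_from_components, tj_update
from .interventions import InterventionSpec
from .nuisance import (
    CLIP,
    IntervalModel,
    NuisanceFit,
    build_design,
    clip_probability,
    cv_stack,
    fractional_logistic_fit,
    interval_models,
    _feature_matrix,
)
from .panel import PanelData

__all__ = [
    "EstimateResult",
    "EstimationError",
    "TargetingError",
    "cumulative_weights",
    "ice_estimate",
    "ipw_estimate",
    "wice_estimate",
    "tmle_crossfit_estimate",
    "bootstrap_ci",
    "BootstrapCI",
]

_Z95 = 1.959963984540054


class EstimationError(RuntimeError):
    pass


class TargetingError(RuntimeError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class EstimateResult:
    """A point estimate with per-subject contributions and diagnostics."""

    psi_hat: float
    method: str
    delta: float | None
    T0: np.ndarray
    se: float | None = None
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    eif: np.ndarray | None = None
    weight_diagnostics: dict = field(default_factory=dict)
    convergence_log: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.psi_hat)


# ------------------------------------------------------------------- weights
def _ratio_matrix(panel: PanelData, spec: InterventionSpec,
                  nuisance: NuisanceFit, max_weight: float | None = None,
                  ) -> np.ndarray:
    """Per-interval factors r_j = (q-hat/pi-hat) / (1 - censoring hazard),
    zero for rows that are dead, censored, or censored at j+1."""
    n, J = panel.n, panel.J
    r = np.zeros((n, J))
    for j in range(J):
        risk = panel.at_risk(j)
        pi_obs = nuisance.pi_observed(panel.A[:, j], j)
        qobs = spec.q_observed(panel.A[:, j], nuisance.pi1[:, j], panel.frame(j))
        unc = risk & (panel.C[:, j + 1] == 0)
        keep = 1.0 - np.clip(nuisance.censoring_hazard[:, j], 0.0, 1 - CLIP)
        r[:, j] = np.where(unc, qobs / pi_obs / keep, 0.0)
    return r


def _cumulative(r: np.ndarray, max_weight: float | None = None,
                diagnostics: dict | None = None) -> np.ndarray:
    cum = np.cumprod(r, axis=1)
    if max_weight is not None:
        capped = int(np.sum(cum > max_weight))
        if capped and diagnostics is not None:
            diagnostics["n_capped"] = diagnostics.get("n_capped", 0) + capped
        cum = np.minimum(cum, max_weight)
    return cum


def cumulative_weights(panel: PanelData, spec: InterventionSpec,
                       nuisance: NuisanceFit, j: int) -> np.ndarray:
    """prod_{k<=j} q-hat_k / pi-hat_k, times the inverse-probability-of-
    censoring product through j+1; zero for non-at-risk subjects."""
    r = _ratio_matrix(panel, spec, nuisance)
    return np.cumprod(r[:, : j + 1], axis=1)[:, j]


def _weight_diagnostics(cum: np.ndarray) -> dict:
    w = cum[cum > 0]
    if w.size == 0:
        return {"max": 0.0}
    return {
        "max": float(w.max()),
        "q50": float(np.quantile(w, 0.5)),
        "q90": float(np.quantile(w, 0.9)),
        "q99": float(np.quantile(w, 0.99)),
    }


# ------------------------------------------------- sequential regression core
def _counterfactual_cols(cols: Mapping[str, np.ndarray], spec,
                         level=None) -> dict:
    out = dict(cols)
    if level is None:
        out["A"] = spec.a_star_values(cols)
    else:
        out["A"] = np.full_like(np.asarray(cols["A"], dtype=float),
                                float(level))
    return out


def _predict_Q(model: IntervalModel, cols, risk, spec):
    """Interval-j outcome-regression evaluations needed by the T_j update."""
    Q_obs = np.zeros(len(risk))
    Q_astar = None
    Q_levels = None
    Q_obs[risk] = model.predict(cols, mask=risk)
    if spec.c1 != 0.0:
        cf = _counterfactual_cols(cols, spec)
        Q_astar = np.zeros(len(risk))
        Q_astar[risk] = model.predict(cf, mask=risk)
    if spec.c3 != 0.0:
        Q_levels = {}
        for a in (0, 1):
            cf = _counterfactual_cols(cols, spec, level=a)
            Qa = np.zeros(len(risk))
            Qa[risk] = model.predict(cf, mask=risk)
            Q_levels[a] = Qa
    return Q_obs, Q_astar, Q_levels


def _sequential_estimate(panel: PanelData, spec: InterventionSpec,
                         nuisance: NuisanceFit,
                         outcome_formulas: str | Sequence[str] | None,
                         weighted: bool, method: str,
                         max_weight: float | None = None,
                         learners: Sequence | None = None,
                         outcome_features: Sequence[str] | None = None,
                         folds: int = 5, seed: int = 0,
                         outcome_init: Sequence | None = None) -> EstimateResult:
    spec.require_canonical()
    n, J = panel.n, panel.J
    if (outcome_formulas is None) == (learners is None):
        raise ValueError("supply exactly one of outcome_formulas or learners")
    formulas = None
    if outcome_formulas is not None:
        formulas = interval_models(outcome_formulas, J)
    if learners is not None and outcome_features is None:
        outcome_features = [c for c in panel.covariates] + ["A", "Alag"]
    log: dict = {}
    diag: dict = {}
    if nuisance is None:
        if weighted:
            raise ValueError("weighted ICE requires fitted nuisance models")
        cum = np.ones((n, J))
    else:
        r = _ratio_matrix(panel, spec, nuisance)
        cum = _cumulative(r, max_weight, diag)
    YJ = panel.Y[:, J]
    Tcur = np.where(np.isnan(YJ), 0.0, YJ)
    Q_obs_all = np.zeros((n, J))
    Q_astar_all = np.zeros((n, J))
    for j in range(J - 1, -1, -1):
        risk = panel.at_risk(j)
        fit_rows = risk & (panel.C[:, j + 1] == 0)
        cols = panel.frame(j)
        if not np.any(fit_rows):
            Tcur = np.zeros(n)
            continue
        w = cum[:, j] if weighted else np.ones(n)
        use = fit_rows & (w > 0)
        if not np.any(use):
            raise EstimationError(f"zero total weight at interval {j}")
        if formulas is not None:
            X = build_design(cols, formulas[j], use)
            init = None if outcome_init is None else outcome_init[j]
            try:
                try:
                    fit = fractional_logistic_fit(X, Tcur[use], weights=w[use],
                                                  init=init)
                except Exception:
                    if init is None:
                        raise
                    fit = fractional_logistic_fit(X, Tcur[use], weights=w[use])
            except Exception as err:
                raise EstimationError(
                    f"outcome-model fit failed at interval {j}: {err}"
                ) from err
            log[f"Q{j}"] = {"n_iter": fit.n_iter, "score_norm": fit.score_norm,
                            "theta": fit.theta}
            model = IntervalModel(formula=formulas[j], fit=fit)
        else:
            X = _feature_matrix(cols, outcome_features, use)
            sw = None if not weighted else w[use]
            stack = cv_stack(learners, X, Tcur[use], sample_weight=sw,
                             folds=folds, seed=seed + 31 * j)
            model = IntervalModel(formula=None, fit=None, learner=stack,
                                  features=outcome_features)
        Q_obs, Q_astar, Q_levels = _predict_Q(model, cols, risk, spec)
        Q_obs_all[:, j] = Q_obs
        if Q_astar is not None:
            Q_astar_all[:, j] = Q_astar
        Tnew = tj_update(spec, cols, Q_obs, Q_astar=Q_astar, Q_levels=Q_levels)
        Tcur = np.where(risk, Tnew, 0.0)
        assert np.all((Tcur >= -1e-12) & (Tcur <= 1 + 1e-12)), \
            "T values must stay in [0, 1] (convex combination of expits)"
    psi = float(np.mean(Tcur))
    return EstimateResult(
        psi_hat=psi, method=method, delta=spec.delta, T0=Tcur,
        weight_diagnostics={**_weight_diagnostics(cum), **diag},
        convergence_log=log,
    )


def wice_estimate(panel: PanelData, spec: InterventionSpec,
                  nuisance: NuisanceFit,
                  outcome_formulas: str | Sequence[str],
                  max_weight: float | None = None,
                  outcome_init: Sequence | None = None) -> EstimateResult:
    """Weighted ICE: sequential fractional-logistic regressions with
    cumulative q-hat/pi-hat (and censoring) weights; J+1 multiply robust.

    ``outcome_init`` optionally seeds each interval's IRLS with coefficients
    from a comparable fit (a useful warm start when bootstrapping).
    """
    return _sequential_estimate(panel, spec, nuisance, outcome_formulas,
                                weighted=True, method="wice",
                                max_weight=max_weight,
                                outcome_init=outcome_init)


def ice_estimate(panel: PanelData, spec: InterventionSpec,
                 outcome_formulas: str | Sequence[str] | None = None,
                 nuisance: NuisanceFit | None = None,
                 learners: Sequence | None = None,
                 outcome_features: Sequence[str] | None = None,
                 folds: int = 5, seed: int = 0) -> EstimateResult:
    """Singly robust ICE: the weighted-ICE recursion with unit weights.

    The canonical T_j update consumes only the sequential outcome
    regressions (parametric formulas or stacked learners), so no
    treatment-process fit is required.
    """
    return _sequential_estimate(panel, spec, nuisance, outcome_formulas,
                                weighted=False, method="ice",
                                learners=learners,
                                outcome_features=outcome_features,
                                folds=folds, seed=seed)


def ipw_estimate(panel: PanelData, spec: InterventionSpec,
                 nuisance: NuisanceFit,
                 max_weight: float | None = None) -> EstimateResult:
    """IPW: product over intervals of weighted discrete-hazard complements.

    Each factor is the cumulative-weighted mean of Y_{j+1} among at-risk
    subjects; equivalently the weighted-ICE algorithm with intercept-only
    outcome models.
    """
    n, J = panel.n, panel.J
    diag: dict = {}
    r = _ratio_matrix(panel, spec, nuisance)
    cum = _cumulative(r, max_weight, diag)
    psi = 1.0
    hazards = []
    for j in range(J):
        fit_rows = panel.at_risk(j) & (panel.C[:, j + 1] == 0)
        w = np.where(fit_rows, cum[:, j], 0.0)
        tot = float(np.sum(w))
        if tot <= 0:
            raise EstimationError(f"zero total weight at interval {j}")
        upsilon = float(np.sum(w * np.where(fit_rows, panel.Y[:, j + 1], 0.0))
                        / tot)
        hazards.append(upsilon)
        psi *= upsilon
    T0 = np.full(n, psi)
    return EstimateResult(
        psi_hat=psi, method="ipw", delta=spec.delta, T0=T0,
        weight_diagnostics={**_weight_diagnostics(cum), **diag},
        convergence_log={"survival_factors": hazards},
    )


# ----------------------------------------------------------------------- TMLE
def _solve_fluctuation(offset: np.ndarray, response: np.ndarray,
                       weights: np.ndarray, lo: float = -10.0,
                       hi: float = 10.0) -> float:
    """Root of the intercept-only logit fluctuation score on [lo, hi]."""

    def score(g: float) -> float:
        return float(np.sum(weights * (response - expit(offset + g))))

    s_lo, s_hi = score(lo), score(hi)
    if s_lo == 0.0:
        return lo
    if s_hi == 0.0:
        return hi
    if s_lo * s_hi > 0:
        raise TargetingError(
            "fluctuation root not bracketed in [-10, 10]",
            diagnostics={"score_lo": s_lo, "score_hi": s_hi,
                         "total_weight": float(weights.sum())},
        )
    g = brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16)
    # Newton polish so the solved estimating equation is ~0 to numerical noise
    for _ in range(8):
        p = expit(offset + g)
        s = float(np.sum(weights * (response - p)))
        d = float(np.sum(weights * p * (1.0 - p)))
        if abs(s) < 1e-12 or d <= 0:
            break
        g += s / d
    return float(g)


def tmle_crossfit_estimate(
    panel: PanelData,
    spec: InterventionSpec,
    learners: Sequence | None = None,
    M: int = 2,
    seed: int = 0,
    features: Sequence[str] | None = None,
    outcome_features: Sequence[str] | None = None,
    absorbing: bool = False,
    model_censoring: bool | None = None,
    folds: int = 5,
    min_split_size: int = 50,
) -> EstimateResult:
    """TMLE with sample splitting and cross-fitting (M near-equal splits).

    For each split m, treatment/censoring models and the sequential outcome
    regressions are fit by cross-validated stacked learners on the complement
    S_{-m}; on S_m an intercept-only logit fluctuation per interval is solved
    against the cumulative-weight estimating equation, and T_j is rebuilt from
    the fluctuated regressions.  psi-hat averages the split means of T_0; the
    standard error is the cross-fitted EIF standard error.
    """
    from .nuisance import default_learners, fit_censoring_models, \
        fit_treatment_models

    spec.require_canonical()
    n, J = panel.n, panel.J
    if M < 1:
        raise ValueError("M must be >= 1")
    if M == 1:
        warnings.warn("M=1 disables cross-fitting; nuisances and targeting "
                      "use the same data")
    if n // max(M, 1) < min_split_size:
        raise ValueError(
            f"split size {n // M} below the floor {min_split_size}"
        )
    if learners is None:
        learners = default_learners(seed=seed)
    cov_names = [c for c in panel.covariates]
    if features is None:
        features = cov_names + ["Alag"]
    if outcome_features is None:
        outcome_features = cov_names + ["A", "Alag"]
    if model_censoring is None:
        model_censoring = bool(np.nansum(panel.C) > 0)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    splits = np.array_split(perm, M)

    psi_m = np.zeros(M)
    var_m = np.zeros(M)
    U_all = np.full(n, np.nan)
    log: dict = {"gamma": {}, "post_score": {}}
    diag: dict = {}
    for m, S in enumerate(splits):
        in_S = np.zeros(n, dtype=bool)
        in_S[S] = True
        comp = ~in_S if M > 1 else np.ones(n, dtype=bool)

        _, pi1 = fit_treatment_models(
            panel, learners=learners, features=features, absorbing=absorbing,
            rows=comp, folds=folds, seed=seed + 101 * m,
        )
        if model_censoring:
            _, chaz = fit_censoring_models(
                panel, learners=learners, features=features, rows=comp,
                folds=folds, seed=seed + 101 * m + 1,
            )
        else:
            chaz = np.zeros((n, J))
        nuis = NuisanceFit(pi1=pi1, censoring_hazard=chaz,
                           provenance="learner")
        r = _ratio_matrix(panel, spec, nuis)
        cum = _cumulative(r, None, diag)

        # --- initial sequential regressions on the complement S_{-m}
        YJ = panel.Y[:, J]
        Tcur = np.where(np.isnan(YJ), 0.0, YJ)
        Q_obs_init = np.zeros((n, J))
        Q_astar_init = np.zeros((n, J))
        for j in range(J - 1, -1, -1):
            risk = panel.at_risk(j)
            fit_rows = risk & (panel.C[:, j + 1] == 0) & comp
            cols = panel.frame(j)
            if not np.any(fit_rows):
                Tcur = np.zeros(n)
                continue
            X = _feature_matrix(cols, outcome_features, fit_rows)
            stack = cv_stack(learners, X, Tcur[fit_rows], folds=folds,
                             seed=seed + 997 * m + 31 * j)
            model = IntervalModel(formula=None, fit=None, learner=stack,
                                  features=outcome_features)
            Q_obs, Q_astar, Q_levels = _predict_Q(model, cols, risk, spec)
            Q_obs_init[:, j] = Q_obs
            if Q_astar is not None:
                Q_astar_init[:, j] = Q_astar
            Tnew = tj_update(spec, cols, Q_obs, Q_astar=Q_astar,
                             Q_levels=Q_levels)
            Tcur = np.where(risk, Tnew, 0.0)

        # --- targeting on S_m
        Tt = np.where(np.isnan(YJ), 0.0, YJ)
        Qd_obs = np.zeros((n, J))
        Qd_astar = np.zeros((n, J))
        for j in range(J - 1, -1, -1):
            risk = panel.at_risk(j)
            rows = risk & (panel.C[:, j + 1] == 0) & in_S
            cols = panel.frame(j)
            off_obs = logit(np.clip(Q_obs_init[:, j], CLIP, 1 - CLIP))
            off_ast = logit(np.clip(Q_astar_init[:, j], CLIP, 1 - CLIP))
            w = np.where(rows, cum[:, j], 0.0)
            if np.any(w > 0):
                gamma = _solve_fluctuation(off_obs[rows], Tt[rows], w[rows])
            else:
                gamma = 0.0
            log["gamma"][(m, j)] = gamma
            p = expit(off_obs[rows] + gamma)
            log["post_score"][(m, j)] = float(np.sum(w[rows] * (Tt[rows] - p)))
            Qd_obs[:, j] = expit(off_obs + gamma)
            Qd_astar[:, j] = expit(off_ast + gamma)
            Tnew = tj_update(spec, cols, np.where(risk, Qd_obs[:, j], 0.0),
                             Q_astar=np.where(risk, Qd_astar[:, j], 0.0))
            Tt = np.where(risk, Tnew, 0.0)
        psi_m[m] = float(np.mean(Tt[in_S]))

        comps = eif_from_components(panel, spec, pi1, Qd_obs, Qd_astar,
                                    psi=psi_m[m],
                                    censoring_hazard=chaz if model_censoring
                                    else None)
        U_all[in_S] = comps.U[in_S]
        var_m[m] = float(np.var(comps.U[in_S]))
        diag.update(_weight_diagnostics(cum[in_S]))

    psi = float(np.mean(psi_m))
    se = float(np.sqrt(np.mean(var_m) / n))
    ci = (psi - _Z95 * se, psi + _Z95 * se)
    return EstimateResult(
        psi_hat=psi, method="tmle", delta=spec.delta,
        T0=np.full(n, psi), se=se, ci=ci, eif=U_all,
        weight_diagnostics=diag,
        convergence_log={**log, "psi_splits": psi_m.tolist()},
    )


# ------------------------------------------------------------------ bootstrap
@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float
    estimates: np.ndarray
    n_failed: int

    def __iter__(self):
        return iter((self.lower, self.upper))


def bootstrap_ci(estimator: Callable[[PanelData], object], panel: PanelData,
                 B: int = 1000, level: float = 0.95,
                 seed: int = 0) -> BootstrapCI:
    """Subject-level nonparametric bootstrap percentile interval.

    ``estimator`` maps a panel to a float (or an object with ``psi_hat``).
    Failing replicates are dropped and counted; more than 10% failures is an
    error.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = panel.n
    ests, failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            res = estimator(panel.subset(idx))
            ests.append(float(getattr(res, "psi_hat", res)))
        except Exception:  # noqa: BLE001 - replicate failure tolerated
            failed += 1
    if failed > 0.1 * B:
        raise EstimationError(
            f"{failed}/{B} bootstrap replicates failed"
        )
    ests = np.asarray(ests)
    alpha = 1.0 - level
    lo, hi = np.percentile(ests, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(lower=float(lo), upper=float(hi), level=level,
                       estimates=ests, n_failed=failed)
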