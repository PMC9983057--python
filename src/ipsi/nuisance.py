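"""Nuisance function estimation: treatment process, censoring hazard and
sequential outcome regressions.

Per-interval working models are fractional logistic regressions -- logit-link
fits for responses in [0, 1], solved from the weighted score equation

    sum_i w_i phi_i { t_i - expit(offset_i + theta' phi_i) } = 0

by iteratively reweighted least squares (IRLS) with step-halving, tolerance
1e-8 on the max-abs score component and at most 100 iterations.  With a binary
response, no weights and no offset this coincides with the logistic MLE.

Alternatively, any nuisance can be fit by a pluggable learner or by a
cross-validated convex stack of learners (nonnegative least squares on
out-of-fold predictions of the probability-scale squared error, weights
renormalised to the simplex).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "CLIP",
    "ConvergenceError",
    "DegenerateFitError",
    "FractionalLogitFit",
    "fractional_logistic_fit",
    "build_design",
    "saturated_formula",
    "interval_models",
    "IntervalModel",
    "fit_treatment_models",
    "fit_censoring_models",
    "NuisanceFit",
    "Learner",
    "GLMLearner",
    "GBMLearner",
    "default_learners",
    "cv_stack",
    "StackedModel",
]

#: global probability clipping constant for predictions entering ratios
CLIP = 1e-6


class ConvergenceError(RuntimeError):
    """IRLS failed to reduce the score below tolerance."""

    def __init__(self, msg: str, score_norm: float | None = None):
        super().__init__(msg)
        self.score_norm = score_norm


class DegenerateFitError(ValueError):
    """A binary response is single-class on the fitting rows."""


def clip_probability(p: np.ndarray, where: str = "") -> np.ndarray:
    """Clip predictions to [CLIP, 1-CLIP], logging when clipping occurs."""
    p = np.asarray(p, dtype=float)
    n_clip = int(np.sum((p < CLIP) | (p > 1 - CLIP)))
    if n_clip:
        logger.warning("clipped %d prediction(s) to [%g, %g] %s",
                       n_clip, CLIP, 1 - CLIP, where)
    return np.clip(p, CLIP, 1 - CLIP)


# --------------------------------------------------------------------- design
def build_design(cols: Mapping[str, np.ndarray], formula: str,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Build a design matrix from a ``+``-separated product-term formula.

    Terms are column names joined by ``:`` for products (``"lstar + L1 +
    lstar:A"``); an intercept is always included and ``"1"`` denotes an
    intercept-only design.
    """
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    ref = next(iter(cols.values()))
    n = len(ref) if mask is None else int(np.sum(mask))
    out = [np.ones(n)]
    for term in terms:
        if term == "1":
            continue
        prod = np.ones(n)
        for name in term.split(":"):
            name = name.strip()
            col = np.asarray(cols[name], dtype=float)
            prod = prod * (col[mask] if mask is not None else col)
        out.append(prod)
    return np.column_stack(out)


def saturated_formula(names: Sequence[str]) -> str:
    """All main effects and interaction products of the named columns."""
    terms: list[str] = []
    m = len(names)
    for bits in range(1, 2 ** m):
        terms.append(":".join(names[k] for k in range(m) if bits >> k & 1))
    return " + ".join(terms)


# ------------------------------------------------------- fractional logistic
@dataclass
class FractionalLogitFit:
    theta: np.ndarray
    converged: bool
    n_iter: int
    score_norm: float

    def predict(self, X: np.ndarray, offset=None) -> np.ndarray:
        eta = X @ self.theta
        if offset is not None:
            eta = eta + offset
        return expit(eta)


def fractional_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    init: np.ndarray | None = None,
) -> FractionalLogitFit:
    """Solve the weighted fractional-logistic score equation by IRLS.

    Responses must lie in [0, 1]; weights are nonnegative with at least one
    positive.  Rank-deficient designs fall back to the pseudoinverse step with
    a warning.  Deterministic given inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractional response must lie in [0, 1]")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("at least one positive weight required")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    theta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    if init is None and np.all(X[:, 0] == 1.0):
        ybar = float(np.sum(w * y) / np.sum(w))
        theta[0] = logit(np.clip(ybar, 1e-12, 1 - 1e-12)) - float(
            np.sum(w * off) / np.sum(w)
        )

    Xw = X * w[:, None]

    def evaluate(th):
        mu = expit(off + X @ th)
        s = (y - mu) @ Xw
        mc = np.clip(mu, 1e-300, 1 - 1e-16)
        ll = float(w @ (y * np.log(mc) + (1 - y) * np.log1p(-mc)))
        return s, mu, ll

    s, mu, ll = evaluate(theta)
    norm = float(np.max(np.abs(s)))
    didx = np.diag_indices(p)
    it = 0
    while norm > tol and it < max_iter:
        it += 1
        wirls = w * mu * (1.0 - mu)
        H = X.T @ (X * wirls[:, None])
        # tiny ridge keeps the Newton direction an ascent direction when the
        # design is rank-deficient (e.g. empty cells of a saturated model)
        ridge = 1e-10 * max(float(np.max(H[didx])), 1.0)
        H[didx] += ridge
        try:
            step = np.linalg.solve(H, s)
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient design; using pseudoinverse step")
            step = np.nan_to_num(np.linalg.lstsq(H, s, rcond=None)[0])
        # step-halving on the quasi-binomial log-likelihood
        lam = 1.0
        for _ in range(50):
            cand = theta + lam * step
            s_new, mu_new, ll_new = evaluate(cand)
            if ll_new >= ll - 1e-14 * max(abs(ll), 1.0):
                theta, s, mu, ll = cand, s_new, mu_new, ll_new
                norm = float(np.max(np.abs(s)))
                break
            lam *= 0.5
        else:
            break  # no ascent left at machine precision
    if norm > tol:
        raise ConvergenceError(
            f"fractional logistic IRLS did not converge in {it} iterations "
            f"(max-abs score {norm:.3e})",
            score_norm=norm,
        )
    return FractionalLogitFit(theta=theta, converged=True, n_iter=it,
                              score_norm=norm)


# ------------------------------------------------------- per-interval models
@dataclass
class IntervalModel:
    """A fitted per-interval model: parametric formula fit or learner."""

    formula: str | None
    fit: FractionalLogitFit | None
    learner: "StackedModel | Learner | None" = None
    features: Sequence[str] | None = None
    empty: bool = False

    def predict(self, cols: Mapping[str, np.ndarray],
                mask: np.ndarray | None = None) -> np.ndarray:
        if self.empty:
            raise RuntimeError("no model was fit (empty risk set)")
        if self.fit is not None:
            X = build_design(cols, self.formula, mask)
            return self.fit.predict(X)
        X = _feature_matrix(cols, self.features, mask)
        return clip_probability(self.learner.predict(X))


def _feature_matrix(cols, features, mask=None):
    out = []
    for name in features:
        col = np.asarray(cols[name], dtype=float)
        out.append(col[mask] if mask is not None else col)
    return np.column_stack(out)


def _fit_binary_interval(cols, y, mask, formula=None, learners=None,
                         features=None, folds=5, seed=0, label="", init=None):
    """Fit one per-interval binary model on masked rows, predict everywhere."""
    ym = y[mask]
    if ym.size == 0:
        return IntervalModel(formula=formula, fit=None, empty=True), None
    if formula is not None:
        if ym.min() == ym.max():
            raise DegenerateFitError(
                f"single-class response for {label}: all values {ym[0]:g}"
            )
        X = build_design(cols, formula, mask)
        try:
            fit = fractional_logistic_fit(X, ym, init=init)
        except ConvergenceError:
            if init is None:
                raise
            fit = fractional_logistic_fit(X, ym)  # cold restart
        model = IntervalModel(formula=formula, fit=fit)
    else:
        X = _feature_matrix(cols, features, mask)
        stack = cv_stack(learners, X, ym, folds=folds, seed=seed)
        model = IntervalModel(formula=None, fit=None, learner=stack,
                              features=features)
    pred = model.predict(cols)
    return model, clip_probability(pred, label)


@dataclass
class NuisanceFit:
    """Fitted nuisance predictions with provenance.

    ``pi1[i, j]`` is the fitted probability of treatment for subject i at
    interval j (NaN off the risk set; 1 for already-treated rows under an
    absorbing treatment).  ``censoring_hazard[i, j]`` is the fitted
    probability of being censored at j+1 given at risk at j (zeros when
    censoring is not modeled).
    """

    pi1: np.ndarray
    censoring_hazard: np.ndarray
    provenance: str = "parametric"
    treatment_models: list = field(default_factory=list)
    censoring_models: list = field(default_factory=list)

    def pi_observed(self, A: np.ndarray, j: int | None = None) -> np.ndarray:
        """Probability of the observed treatment, clipped; ``A`` is the full
        (n, J) treatment array or, with ``j`` given, the interval-j column."""
        safe = np.where(np.isnan(A), 0.0, A)
        pi1 = self.pi1 if j is None else self.pi1[:, j]
        p = np.where(safe == 1, pi1, 1.0 - pi1)
        return np.clip(p, CLIP, 1 - CLIP)


def interval_models(formula: str | Sequence[str], J: int) -> list[str]:
    """Broadcast a single formula to all intervals."""
    if isinstance(formula, str):
        return [formula] * J
    if len(formula) != J:
        raise ValueError(f"need {J} per-interval formulas, got {len(formula)}")
    return list(formula)


def fit_treatment_models(
    panel,
    formulas: str | Sequence[str] | None = None,
    learners: "Sequence[Learner] | None" = None,
    features: Sequence[str] | None = None,
    absorbing: bool = False,
    rows: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    init_theta: Sequence[np.ndarray | None] | None = None,
) -> tuple[list[IntervalModel], np.ndarray]:
    """Fit a separate treatment model per interval among at-risk rows.

    With ``absorbing=True`` (treatment stays on once initiated) the initiation
    model is fit only among ``A_{j-1} = 0`` and already-treated rows get
    probability 1.  ``rows`` restricts the fitting subsample (cross-fitting);
    predictions cover every subject.
    """
    if formulas is not None:
        formulas = interval_models(formulas, panel.J)
    models, pi1 = [], np.full((panel.n, panel.J), np.nan)
    fit_rows = np.ones(panel.n, bool) if rows is None else np.asarray(rows)
    for j in range(panel.J):
        cols = panel.frame(j)
        risk = panel.at_risk(j)
        mask = risk & fit_rows
        if absorbing:
            mask = mask & (cols["Alag"] == 0)
        model, pred = _fit_binary_interval(
            cols, panel.A[:, j], mask,
            formula=None if formulas is None else formulas[j],
            learners=learners, features=features, folds=folds,
            seed=seed + 7 * j, label=f"treatment model j={j}",
            init=None if init_theta is None else init_theta[j],
        )
        models.append(model)
        if pred is not None:
            pi1[:, j] = np.where(risk, pred, np.nan)
        if absorbing:
            pi1[:, j] = np.where(risk & (cols["Alag"] == 1), 1.0, pi1[:, j])
    return models, pi1


def fit_censoring_models(
    panel,
    formulas: str | Sequence[str] | None = None,
    learners: "Sequence[Learner] | None" = None,
    features: Sequence[str] | None = None,
    rows: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    init_theta: Sequence[np.ndarray | None] | None = None,
) -> tuple[list[IntervalModel], np.ndarray]:
    """Fit per-interval censoring-hazard models P(C_{j+1}=1 | at risk at j).

    If the panel contains no censoring events at some interval the hazard
    there is zero and the inverse weights are one.
    """
    if formulas is not None:
        formulas = interval_models(formulas, panel.J)
    models, chaz = [], np.zeros((panel.n, panel.J))
    fit_rows = np.ones(panel.n, bool) if rows is None else np.asarray(rows)
    for j in range(panel.J):
        cols = panel.frame(j)
        risk = panel.at_risk(j)
        mask = risk & fit_rows
        c_next = panel.C[:, j + 1]
        if not np.any(c_next[mask] == 1):
            models.append(IntervalModel(formula=None, fit=None, empty=True))
            continue
        model, pred = _fit_binary_interval(
            cols, c_next, mask,
            formula=None if formulas is None else formulas[j],
            learners=learners, features=features, folds=folds,
            seed=seed + 11 * j, label=f"censoring model j={j}",
            init=None if init_theta is None else init_theta[j],
        )
        models.append(model)
        if pred is not None:
            chaz[:, j] = np.where(risk, pred, 0.0)
    return models, chaz


def fit_nuisance(
    panel,
    treatment_formulas=None,
    censoring_formulas=None,
    learners=None,
    features=None,
    absorbing: bool = False,
    model_censoring: bool = True,
    rows: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    warm_start: "NuisanceFit | None" = None,
) -> NuisanceFit:
    """Convenience wrapper fitting treatment and censoring processes.

    ``warm_start`` takes a previous parametric fit on comparable data (e.g.
    the full sample, when bootstrapping) whose coefficients seed the IRLS.
    """
    t_init = c_init = None
    if warm_start is not None:
        t_init = [None if m.fit is None else m.fit.theta
                  for m in warm_start.treatment_models]
        if warm_start.censoring_models:
            c_init = [None if m.fit is None else m.fit.theta
                      for m in warm_start.censoring_models]
    tmod, pi1 = fit_treatment_models(
        panel, treatment_formulas, learners=learners, features=features,
        absorbing=absorbing, rows=rows, folds=folds, seed=seed,
        init_theta=t_init,
    )
    if model_censoring:
        cmod, chaz = fit_censoring_models(
            panel, censoring_formulas, learners=learners, features=features,
            rows=rows, folds=folds, seed=seed + 1, init_theta=c_init,
        )
    else:
        cmod, chaz = [], np.zeros((panel.n, panel.J))
    prov = "parametric" if treatment_formulas is not None else "learner"
    return NuisanceFit(pi1=pi1, censoring_hazard=chaz, provenance=prov,
                       treatment_models=tmod, censoring_models=cmod)


# -------------------------------------------------------------------- learners
class Learner(Protocol):
    """Fit/predict contract: fractional response in [0, 1], optional weights,
    predictions on the probability scale."""

    def fit(self, X: np.ndarray, y: np.ndarray,
            sample_weight: np.ndarray | None = None) -> "Learner": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...

    def clone(self) -> "Learner": ...


class GLMLearner:
    """Fractional logistic GLM on raw features, optionally with pairwise
    interactions (mirrors a main-terms / interaction GLM candidate)."""

    def __init__(self, interactions: bool = False):
        self.interactions = interactions
        self._fit = None

    def clone(self) -> "GLMLearner":
        return GLMLearner(self.interactions)

    def _design(self, X: np.ndarray) -> np.ndarray:
        n, p = X.shape
        blocks = [np.ones((n, 1)), X]
        if self.interactions:
            blocks.extend(
                (X[:, [a]] * X[:, [b]]) for a in range(p) for b in range(a + 1, p)
            )
        return np.hstack(blocks)

    def fit(self, X, y, sample_weight=None):
        D = self._design(np.asarray(X, dtype=float))
        y = np.clip(np.asarray(y, dtype=float), 0.0, 1.0)
        try:
            self._fit = fractional_logistic_fit(D, y, weights=sample_weight)
        except (ConvergenceError, np.linalg.LinAlgError):
            # fall back to the best iterate of a ridge-stabilised refit
            lam = 1e-6 * D.shape[0]
            Xt = np.vstack([D, np.sqrt(lam) * np.eye(D.shape[1])])
            yt = np.concatenate([y, np.full(D.shape[1], 0.5)])
            wt = None
            if sample_weight is not None:
                wt = np.concatenate([sample_weight, np.ones(D.shape[1])])
            self._fit = fractional_logistic_fit(Xt, yt, weights=wt, tol=1e-6,
                                                max_iter=200)
        return self

    def predict(self, X):
        return self._fit.predict(self._design(np.asarray(X, dtype=float)))


class GBMLearner:
    """Gradient-boosted regression trees (squared error on the probability
    scale, predictions clipped to [0, 1])."""

    def __init__(self, n_estimators: int = 60, max_depth: int = 3,
                 learning_rate: float = 0.1, min_child_samples: int = 10,
                 seed: int = 0):
        self.params = dict(n_estimators=n_estimators, max_depth=max_depth,
                           learning_rate=learning_rate,
                           min_child_samples=min_child_samples)
        self.seed = seed
        self._model = None

    def clone(self) -> "GBMLearner":
        return GBMLearner(seed=self.seed, **self.params)

    def fit(self, X, y, sample_weight=None):
        from lightgbm import LGBMRegressor

        self._model = LGBMRegressor(
            random_state=self.seed, verbosity=-1, n_jobs=1,
            min_child_weight=1e-3, **self.params,
        )
        self._model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float),
                        sample_weight=sample_weight)
        return self

    def predict(self, X):
        return np.clip(self._model.predict(np.asarray(X, dtype=float)), 0.0, 1.0)


class ConstantLearner:
    """Weighted-mean predictor; a deliberately weak stacking candidate."""

    def __init__(self):
        self._mean = 0.5

    def clone(self) -> "ConstantLearner":
        return ConstantLearner()

    def fit(self, X, y, sample_weight=None):
        w = np.ones(len(y)) if sample_weight is None else sample_weight
        self._mean = float(np.sum(w * y) / np.sum(w))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self._mean)


def default_learners(seed: int = 0) -> list:
    """The default candidate library: main-terms GLM, GLM with pairwise
    interactions, and gradient-boosted trees."""
    return [GLMLearner(), GLMLearner(interactions=True), GBMLearner(seed=seed)]


@dataclass
class StackedModel:
    """Convex combination of fitted learners selected by cross-validation."""

    learners: list
    weights: np.ndarray
    cv_risks: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.column_stack([
            np.clip(lr.predict(X), 0.0, 1.0) for lr in self.learners
        ])
        return preds @ self.weights


def cv_stack(learners: Sequence, X: np.ndarray, y: np.ndarray,
             sample_weight: np.ndarray | None = None, folds: int = 5,
             seed: int = 0, discrete: bool = False) -> StackedModel:
    """Cross-validated convex stacking of candidate learners.

    Nonnegative least squares of the response on out-of-fold predictions,
    weights renormalised to sum to one (squared-error loss on the probability
    scale).  ``discrete=True`` instead picks the single lowest-CV-risk
    candidate.  With one candidate the weights are (1,).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = len(learners)
    if K == 0:
        raise ValueError("need at least one candidate learner")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)

    fitted, failed = [], []
    for lr in learners:
        try:
            fitted.append(lr.clone().fit(X, y, sample_weight=w))
        except Exception:  # noqa: BLE001 - candidate failure tolerated
            fitted.append(None)
            failed.append(lr)
    if all(f is None for f in fitted):
        raise RuntimeError("all stacking candidates failed to fit")
    ok = [k for k, f in enumerate(fitted) if f is not None]

    if len(ok) == 1:
        return StackedModel([fitted[ok[0]]], weights=np.ones(1),
                            cv_risks=np.full(1, np.nan))
    if n < 2 * folds:  # too few rows to cross-validate: equal weights
        kept = [fitted[k] for k in ok]
        return StackedModel(kept, weights=np.full(len(ok), 1.0 / len(ok)),
                            cv_risks=np.full(len(ok), np.nan))

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    oof = np.full((n, len(ok)), np.nan)
    bounds = np.linspace(0, n, folds + 1).astype(int)
    for f in range(folds):
        test = perm[bounds[f]:bounds[f + 1]]
        train = np.setdiff1d(perm, test, assume_unique=True)
        if len(np.unique(y[train])) == 0:
            continue
        for c, k in enumerate(ok):
            try:
                m = learners[k].clone().fit(X[train], y[train],
                                            sample_weight=w[train])
                oof[test, c] = np.clip(m.predict(X[test]), 0.0, 1.0)
            except Exception:  # noqa: BLE001
                oof[test, c] = np.mean(y[train])
    resid = oof - y[:, None]
    risks = np.nanmean(w[:, None] * resid ** 2, axis=0)
    if discrete:
        weights = np.zeros(len(ok))
        weights[int(np.argmin(risks))] = 1.0
    else:
        sw = np.sqrt(w)[:, None]
        coef, _ = nnls(np.nan_to_num(oof) * sw, y * np.sqrt(w))
        if coef.sum() <= 0:
            weights = np.zeros(len(ok))
            weights[int(np.argmin(risks))] = 1.0
        else:
            weights = coef / coef.sum()
    return StackedModel([fitted[k] for k in ok], weights=weights,
                        cv_risks=risks)
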