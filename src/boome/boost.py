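"""Thresholded boosting over (corrected) estimating functions.

The fitting procedure starts from ``beta = 0_p`` and, for ``T`` iterations,

1. evaluates the configured estimating function ``g`` at the current
   iterate (naive or measurement-error-corrected, per the correction
   flags),
2. forms the active set ``J = {j : |g_j| >= tau * max_j |g_j|}``,
3. moves the active coordinates by a step of magnitude ``eta * |g_j|`` in
   the likelihood-ascent direction, ``beta_j <- beta_j - eta * g_j``
   (the estimating functions carry a leading minus, so subtracting them
   ascends the likelihood and drives ``g`` toward its root).

At ``tau = 0`` every coordinate updates and the procedure is plain
gradient iteration toward the root of ``g``; at ``tau`` near 1 only the
strongest signals move, which is what performs variable selection: the
selected model is the set of coordinates that ever entered the active
set (equivalently, the nonzero entries of the final iterate).

The four correction settings are expressed through two flags:

========= ========= ==========================================
correct_Y correct_X estimating function
========= ========= ==========================================
0         0         naive, on the surrogate data as recorded
1         0         naive, with the misclassification-corrected
                    response substituted
0         1         predictor correction only (the surrogate
                    response is used as the multiplier in the
                    logistic sufficient statistic)
1         1         fully corrected
========= ========= ==========================================

Predictor correction is model-specific: the logistic path substitutes
the sufficient statistic ``X* + Y** Sigma_eps beta`` (re-evaluated at
every iteration since it depends on beta), while the probit path applies
regression calibration once, up front, because the calibration map is
beta-free.

An optional early-stopping rule halts when the L2 change of the
estimating function between consecutive iterates falls below ``xi``; it
is off by default so that fixed-``T`` runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import math

import numpy as np
from scipy.special import expit

from .glm_core import Model, PROBIT_CLIP, _as_matrix, score
from .me_correction import (
    MeasurementErrorSpec,
    MisclassificationProbabilities,
    correct_response,
    fit_regression_calibration,
)
from scipy.special import ndtr

__all__ = ["BoostConfig", "FitResult", "active_set", "boost_fit", "choose_tau", "fit"]


@dataclass(frozen=True)
class BoostConfig:
    """Controls for the boosting procedure.

    Parameters
    ----------
    model:
        ``Model.LOGISTIC`` or ``Model.PROBIT``.
    n_iter:
        Maximum number of boosting iterations ``T`` (>= 1).
    tau:
        Relative threshold in [0, 1] defining the active set.
    eta:
        Learning rate (> 0); the per-coordinate step is ``eta * |g_j|``.
    xi:
        Optional early-stopping tolerance on ``||g_t - g_{t-1}||_2``;
        ``None`` disables early stopping.
    correct_x, correct_y:
        Measurement-error correction flags for predictors / response.
    """

    model: Model = Model.LOGISTIC
    n_iter: int = 1000
    tau: float = 0.9
    eta: float = 0.01
    xi: float | None = None
    correct_x: bool = False
    correct_y: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.xi is not None and self.xi <= 0:
            raise ValueError("xi must be > 0 when given")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a boosting fit.

    ``selected`` holds the 1-based indices of the nonzero coefficients,
    in ascending order, matching how selected predictors are reported to
    users.
    """

    beta_hat: np.ndarray
    selected: tuple[int, ...]
    n_selected: int
    iterations_run: int
    stopped_early: bool
    score_norm_trace: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "estimated_coefficients": self.beta_hat.tolist(),
            "predictors": list(self.selected),
            "number_of_predictors": self.n_selected,
        }


def active_set(delta, tau: float) -> np.ndarray:
    """0-based indices with ``|delta_j| >= tau * max_j |delta_j|``.

    Ties at the threshold are included (the comparison is >=); the set is
    empty exactly when every component is zero.
    """
    a = np.abs(np.asarray(delta, dtype=float))
    if not np.all(np.isfinite(a)):
        raise ValueError("delta must be finite")
    m = a.max() if a.size else 0.0
    if m == 0.0:
        return np.empty(0, dtype=int)
    return np.flatnonzero(a >= tau * m)


def _prepare(X, Y, probs, me, config):
    """Resolve the correction flags into a working response / predictor pair."""
    X = _as_matrix(X)
    Y = np.asarray(Y, dtype=float).ravel()
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y differ in length")
    if config.correct_y:
        if probs is None:
            raise ValueError("correct_y=True requires misclassification probabilities")
        y_work = correct_response(Y, probs)
    else:
        y_work = Y
    if config.correct_x and me is None:
        raise ValueError("correct_x=True requires a measurement-error covariance")
    X_work = X
    if config.correct_x and config.model is Model.PROBIT:
        X_work = fit_regression_calibration(X, me).transform(X)
    return X_work, y_work


def boost_fit(
    X,
    Y,
    probs: MisclassificationProbabilities | None = None,
    me: MeasurementErrorSpec | None = None,
    config: BoostConfig = BoostConfig(),
) -> FitResult:
    """Run the thresholded boosting procedure and return the fitted model.

    ``Y`` is the observed (possibly misclassified) 0/1 response; the
    correction flags in ``config`` decide whether the corrected response
    and/or corrected predictors are used, so a single entry point covers
    all four correction settings.
    """
    X_work, y_work = _prepare(X, Y, probs, me, config)
    n, p = X_work.shape
    logistic_ss = config.correct_x and config.model is Model.LOGISTIC
    sigma_mv = me.matvec if logistic_ss else None

    beta = np.zeros(p)
    trace = []
    prev_g = None
    stopped_early = False
    iterations = 0
    for _ in range(config.n_iter):
        if logistic_ss:
            # g for X_ss = X* + y** Sigma_eps beta, without materialising X_ss:
            # z = X beta + y** (beta' Sigma_eps beta);  X_ss' r = X' r + (Sigma_eps beta)(y**.r)
            sb = sigma_mv(beta)
            z = X_work @ beta + y_work * (beta @ sb)
            resid = y_work - expit(z)
            g = -(X_work.T @ resid + sb * (y_work @ resid)) / n
        elif config.model is Model.LOGISTIC:
            resid = y_work - expit(X_work @ beta)
            g = -(X_work.T @ resid) / n
        else:
            eta_lin = X_work @ beta
            Phi = np.clip(ndtr(eta_lin), PROBIT_CLIP, 1.0 - PROBIT_CLIP)
            phi = np.exp(-0.5 * eta_lin * eta_lin) * (1.0 / math.sqrt(2.0 * math.pi))
            w = phi * (y_work / Phi + (y_work - 1.0) / (1.0 - Phi))
            g = -(X_work.T @ w) / n
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite estimating function during boosting")
        trace.append(float(np.linalg.norm(g)))
        if config.xi is not None and prev_g is not None:
            if float(np.linalg.norm(g - prev_g)) < config.xi:
                stopped_early = True
                break
        prev_g = g
        J = active_set(g, config.tau)
        if J.size == 0:
            stopped_early = True
            iterations += 1
            break
        beta[J] -= config.eta * g[J]
        iterations += 1

    selected = tuple((np.flatnonzero(beta != 0.0) + 1).tolist())
    return FitResult(
        beta_hat=beta,
        selected=selected,
        n_selected=len(selected),
        iterations_run=iterations,
        stopped_early=stopped_early,
        score_norm_trace=np.asarray(trace),
    )


def fit(X, Y, ite, thres, correct_X, correct_Y, pr=None, lr=0.01, matrix=None, model="lr"):
    """Signature-compatible convenience wrapper.

    ``pr`` is an n x 2 array-like with columns (pi10, pi01); ``matrix`` is
    a scalar variance, a vector of per-column variances, or a full
    covariance matrix.  Returns a :class:`FitResult`.
    """
    probs = None
    if pr is not None:
        pr = np.asarray(pr, dtype=float)
        probs = MisclassificationProbabilities(pr[:, 0], pr[:, 1])
    me = MeasurementErrorSpec(matrix) if matrix is not None else None
    config = BoostConfig(
        model=Model(model),
        n_iter=int(ite),
        tau=float(thres),
        eta=float(lr),
        correct_x=bool(correct_X),
        correct_y=bool(correct_Y),
    )
    return boost_fit(X, Y, probs=probs, me=me, config=config)


def _holdout_nll(beta, X_test, y_test_corrected, model: Model) -> float:
    """Mean Bernoulli-style negative log-likelihood on a held-out fold.

    The (possibly corrected, real-valued) response is scored against the
    fitted mean; probabilities are clipped away from {0, 1}.
    """
    eta_lin = _as_matrix(X_test) @ beta
    mu = expit(eta_lin) if model is Model.LOGISTIC else ndtr(eta_lin)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    y = np.asarray(y_test_corrected, dtype=float).ravel()
    return float(-np.mean(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def choose_tau(
    X,
    Y,
    probs: MisclassificationProbabilities | None,
    me: MeasurementErrorSpec | None,
    config: BoostConfig,
    tau_grid,
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """Select the threshold ``tau`` by K-fold cross-validation.

    Each grid value is scored by the mean held-out negative log-likelihood
    of the fitted model, with responses corrected before scoring when
    ``config.correct_y`` is set.  Ties (including the all-equal case) are
    broken toward the largest ``tau``, i.e. the sparsest model.  Folds in
    which the observed response is single-class are re-drawn with a fresh
    seed, at most 5 times.
    """
    tau_grid = [float(t) for t in tau_grid]
    if not tau_grid or any(not 0.0 <= t <= 1.0 for t in tau_grid):
        raise ValueError("tau_grid must be a non-empty subset of [0, 1]")
    if len(tau_grid) == 1:
        return tau_grid[0]

    X = _as_matrix(X)
    Y = np.asarray(Y, dtype=float).ravel()
    n = X.shape[0]
    k_folds = min(k_folds, n)

    folds = None
    for attempt in range(5):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        candidate = np.array_split(perm, k_folds)
        if all(np.unique(Y[f]).size > 1 for f in candidate):
            folds = candidate
            break
    if folds is None:
        raise ValueError("could not form folds with both response classes (5 attempts)")

    losses = []
    for tau in tau_grid:
        fold_losses = []
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            tr = np.flatnonzero(train_mask)
            probs_tr = probs_te = None
            if probs is not None:
                probs_tr = MisclassificationProbabilities(probs.pi10[tr], probs.pi01[tr])
                probs_te = MisclassificationProbabilities(
                    probs.pi10[test_idx], probs.pi01[test_idx]
                )
            res = boost_fit(X[tr], Y[tr], probs=probs_tr, me=me,
                            config=replace(config, tau=tau))
            y_te = Y[test_idx]
            if config.correct_y:
                y_te = correct_response(y_te, probs_te)
            X_te = X[test_idx]
            if config.correct_x and config.model is Model.PROBIT:
                X_te = fit_regression_calibration(X[tr], me).transform(X_te)
            fold_losses.append(_holdout_nll(res.beta_hat, X_te, y_te, config.model))
        losses.append(float(np.mean(fold_losses)))

    best = min(losses)
    # sparsest (largest tau) among the minimisers
    return max(t for t, l in zip(tau_grid, losses) if l <= best + 1e-12)
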