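"""Mean functions and naive estimating functions for binary-response GLMs.

Two models are supported for a binary response :math:`Y_i` given a
:math:`p`-vector of predictors :math:`X_i`:

* logistic regression (LR): :math:`P(Y_i=1\\mid X_i) = \\mathrm{expit}(X_i^\\top\\beta)`,
* probit model (PM): :math:`P(Y_i=1\\mid X_i) = \\Phi(X_i^\\top\\beta)`,

where :math:`\\Phi` is the standard normal CDF.  The estimating functions
returned here are the *negative* average score of the corresponding
Bernoulli log-likelihood,

.. math::

    g_{LR}(\\beta) = -\\tfrac1n \\sum_i X_i\\{Y_i - \\mathrm{expit}(X_i^\\top\\beta)\\},

    g_{PM}(\\beta) = -\\tfrac1n \\sum_i X_i\\,\\phi(X_i^\\top\\beta)
        \\Big\\{\\tfrac{Y_i}{\\Phi(X_i^\\top\\beta)}
        + \\tfrac{Y_i-1}{1-\\Phi(X_i^\\top\\beta)}\\Big\\},

with the leading minus sign retained; the boosting driver, not this module,
decides the direction in which iterates move.  Both functions are exactly
linear in ``Y`` for fixed ``X`` and ``beta``, which is what allows
corrected (real-valued, possibly outside [0, 1]) responses to be pushed
through the same code path.

No intercept is added; callers wanting one prepend a column of ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr
from scipy.stats import norm

__all__ = [
    "Model",
    "RegressionSpec",
    "PROBIT_CLIP",
    "mean_response",
    "score_lr",
    "score_pm",
    "score",
]

#: Probit probabilities are clipped into [PROBIT_CLIP, 1 - PROBIT_CLIP]
#: before division; raw division overflows in the tails.
PROBIT_CLIP = 1e-10


class Model(str, enum.Enum):
    """Which binary-response regression model is being fitted."""

    LOGISTIC = "lr"
    PROBIT = "pm"


@dataclass(frozen=True)
class RegressionSpec:
    """Choice between the logistic and the probit mean model."""

    model: Model = Model.LOGISTIC

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.ndim != 2:
        raise ValueError(f"predictor matrix must be 2-D, got shape {X.shape}")
    return X


def _check_dims(X: np.ndarray, beta: np.ndarray, Y: np.ndarray | None = None) -> None:
    if beta.ndim != 1 or X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, beta has length {beta.shape[0]}"
        )
    if Y is not None and Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[0]} rows, Y has length {Y.shape[0]}"
        )


def mean_response(x, beta, spec: RegressionSpec | Model | str = Model.LOGISTIC):
    """Success probability :math:`P(Y=1\\mid x)` under the chosen model.

    ``x`` may be a single predictor row or an ``n x p`` matrix; the return
    value is a scalar or a length-``n`` vector accordingly, always in [0, 1].
    """
    model = spec.model if isinstance(spec, RegressionSpec) else Model(spec)
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    single = x.ndim == 1
    X = _as_matrix(x)
    _check_dims(X, beta)
    eta = X @ beta
    mu = expit(eta) if model is Model.LOGISTIC else ndtr(eta)
    return float(mu[0]) if single else mu


def score_lr(beta, X, Y) -> np.ndarray:
    """Logistic estimating function (negative average score).

    ``Y`` may be real-valued so that corrected responses reuse this path.
    """
    X = _as_matrix(X)
    beta = np.asarray(beta, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    _check_dims(X, beta, Y)
    resid = Y - expit(X @ beta)
    g = -(X.T @ resid) / X.shape[0]
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite logistic estimating function")
    return g


def score_pm(beta, X, Y) -> np.ndarray:
    """Probit estimating function (negative average score).

    The probit probability is clipped to ``[PROBIT_CLIP, 1 - PROBIT_CLIP]``
    before division so that extreme linear predictors do not overflow.
    ``Y`` may be real-valued.
    """
    X = _as_matrix(X)
    beta = np.asarray(beta, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    _check_dims(X, beta, Y)
    eta = X @ beta
    phi = norm.pdf(eta)
    Phi = np.clip(ndtr(eta), PROBIT_CLIP, 1.0 - PROBIT_CLIP)
    w = phi * (Y / Phi + (Y - 1.0) / (1.0 - Phi))
    g = -(X.T @ w) / X.shape[0]
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite probit estimating function")
    return g


def score(beta, X, Y, spec: RegressionSpec | Model | str) -> np.ndarray:
    """Dispatch to :func:`score_lr` or :func:`score_pm`."""
    model = spec.model if isinstance(spec, RegressionSpec) else Model(spec)
    fn = score_lr if model is Model.LOGISTIC else score_pm
    return fn(beta, X, Y)
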