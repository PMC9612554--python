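"""Measurement-error corrections for responses and predictors.

Misclassified binary responses.  The surrogate response ``Y*`` is linked
to the latent ``Y`` through the per-observation misclassification
probabilities ``pi10 = P(Y*=1 | Y=0, X)`` and ``pi01 = P(Y*=0 | Y=1, X)``.
Inverting the 2x2 misclassification matrix gives the corrected response

    Y** = (Y* - pi10) / (1 - pi10 - pi01),

which satisfies E(Y** | Y, X) = Y and may lie outside [0, 1] (it is a
real-valued pseudo-response, not a probability).  The correction is valid
whenever the misclassification matrix is invertible, i.e.
1 - pi10 - pi01 != 0 -- including the negative-denominator regime where
the surrogate is anti-correlated with the truth.

Error-prone predictors, X* = X + eps with eps ~ N(0, Sigma_eps):

* logistic model -- sufficient-statistic substitution
  ``X_ss = X* + Y** Sigma_eps beta``, re-evaluated at the current boosting
  iterate beta;
* probit model -- regression calibration, replacing X* with the moment
  estimate of E(X | X*), an affine map fitted once from the sample
  moments of X*.

The corrected estimating functions are the naive ones of
:mod:`boome.glm_core` applied to the substituted data, and reduce to them
bitwise when ``Sigma_eps = 0`` and ``pi10 = pi01 = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .glm_core import _as_matrix, score_lr, score_pm

__all__ = [
    "MisclassificationProbabilities",
    "MeasurementErrorSpec",
    "CalibrationModel",
    "correct_response",
    "sufficient_statistic",
    "fit_regression_calibration",
    "corrected_score_lr",
    "corrected_score_pm",
]

#: Minimum tolerated magnitude of the determinant term 1 - pi10 - pi01.
_MIN_DENOM = 1e-12


@dataclass(frozen=True)
class MisclassificationProbabilities:
    """Per-observation misclassification probabilities (pi10, pi01).

    ``pi10[i] = P(Y*_i = 1 | Y_i = 0, X_i)`` and
    ``pi01[i] = P(Y*_i = 0 | Y_i = 1, X_i)``.  Validates that every
    probability lies in [0, 1] and that the misclassification matrix is
    invertible for every observation.
    """

    pi10: np.ndarray
    pi01: np.ndarray

    def __post_init__(self) -> None:
        p10 = np.atleast_1d(np.asarray(self.pi10, dtype=float))
        p01 = np.atleast_1d(np.asarray(self.pi01, dtype=float))
        if p10.shape != p01.shape or p10.ndim != 1:
            raise ValueError("pi10 and pi01 must be 1-D vectors of equal length")
        for name, v in (("pi10", p10), ("pi01", p01)):
            if np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must lie in [0, 1]")
        bad = np.flatnonzero(np.abs(1.0 - p10 - p01) < _MIN_DENOM)
        if bad.size:
            raise ValueError(
                "misclassification matrix is singular (1 - pi10 - pi01 ~ 0) "
                f"at row(s) {bad[:5].tolist()}"
            )
        object.__setattr__(self, "pi10", p10)
        object.__setattr__(self, "pi01", p01)

    def __len__(self) -> int:
        return self.pi10.shape[0]

    @property
    def denominator(self) -> np.ndarray:
        """The determinant term ``1 - pi10 - pi01`` per observation."""
        return 1.0 - self.pi10 - self.pi01

    @classmethod
    def constant(cls, pi10: float, pi01: float, n: int) -> "MisclassificationProbabilities":
        return cls(np.full(n, float(pi10)), np.full(n, float(pi01)))

    def to_array(self) -> np.ndarray:
        """n x 2 array with columns (pi10, pi01)."""
        return np.column_stack([self.pi10, self.pi01])


class MeasurementErrorSpec:
    """Covariance ``Sigma_eps`` of the classical additive predictor error.

    Accepts a scalar (``sigma^2 * I``), a length-p vector of per-column
    variances (diagonal), or a full p x p symmetric positive-semidefinite
    matrix.  A scalar spec adapts to any dimension; vector/matrix specs are
    pinned to their p.
    """

    def __init__(self, sigma_eps) -> None:
        arr = np.asarray(sigma_eps, dtype=float)
        if arr.ndim == 0:
            if arr < 0:
                raise ValueError("scalar error variance must be >= 0")
            self._kind = "scalar"
            self._value = float(arr)
        elif arr.ndim == 1:
            if np.any(arr < 0):
                raise ValueError("diagonal error variances must be >= 0")
            self._kind = "diag"
            self._value = arr.copy()
        elif arr.ndim == 2:
            if arr.shape[0] != arr.shape[1]:
                raise ValueError("Sigma_eps matrix must be square")
            if not np.allclose(arr, arr.T, atol=1e-8):
                raise ValueError("Sigma_eps must be symmetric")
            eigs = np.linalg.eigvalsh(arr)
            if eigs.min() < -1e-10 * max(1.0, abs(eigs.max())):
                raise ValueError("Sigma_eps must be positive semidefinite")
            self._kind = "full"
            self._value = arr.copy()
        else:
            raise ValueError("sigma_eps must be a scalar, vector, or matrix")

    @property
    def is_diagonal(self) -> bool:
        return self._kind in ("scalar", "diag")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(np.asarray(self._value) == 0.0))

    def diagonal(self, p: int) -> np.ndarray:
        """Length-p vector of per-column error variances."""
        if self._kind == "scalar":
            return np.full(p, self._value)
        self._check_p(p)
        return self._value.copy() if self._kind == "diag" else np.diag(self._value)

    def matrix(self, p: int) -> np.ndarray:
        """Dense p x p covariance."""
        if self._kind == "full":
            self._check_p(p)
            return self._value.copy()
        return np.diag(self.diagonal(p))

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """``Sigma_eps @ v`` without materialising the matrix when diagonal."""
        v = np.asarray(v, dtype=float)
        if self._kind == "scalar":
            return self._value * v
        self._check_p(v.shape[0])
        if self._kind == "diag":
            return self._value * v
        return self._value @ v

    def _check_p(self, p: int) -> None:
        have = self._value.shape[0]
        if have != p:
            raise ValueError(f"Sigma_eps is {have}-dimensional, data is {p}-dimensional")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MeasurementErrorSpec(kind={self._kind})"


def correct_response(y_star, probs: MisclassificationProbabilities) -> np.ndarray:
    """Misclassification-corrected response ``Y** = (Y* - pi10)/(1 - pi10 - pi01)``.

    ``E(Y** | Y, X) = Y``, so the corrected response can replace the latent
    one inside any estimating function that is linear in the response.
    Values routinely fall outside [0, 1].
    """
    y = np.asarray(y_star, dtype=float).ravel()
    if y.shape[0] != len(probs):
        raise ValueError("response and misclassification probabilities differ in length")
    return (y - probs.pi10) / probs.denominator


def sufficient_statistic(x_star_row, y_corrected: float, me: MeasurementErrorSpec, beta) -> np.ndarray:
    """Sufficient-statistic substitute ``x* + y** (Sigma_eps beta)`` for one row."""
    x = np.asarray(x_star_row, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape != beta.shape:
        raise ValueError("predictor row and beta differ in length")
    return x + float(y_corrected) * me.matvec(beta)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted regression-calibration map ``x -> mu + A (x - mu)``.

    ``A = (Sigma_hat - Sigma_eps)^T Sigma_hat^{-1}`` in the full-matrix case;
    when both covariances are treated as diagonal, ``A`` reduces to the
    per-column reliability ratios ``(s_j^2 - sigma_eps_j^2)/s_j^2`` and is
    stored as a vector.  ``transform(mu) == mu`` by construction.
    """

    mu_hat: np.ndarray
    cov_hat: np.ndarray
    _map: np.ndarray = field(repr=False)
    diagonal: bool = True

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xc = np.atleast_2d(X) - self.mu_hat
        out = Xc * self._map if self.diagonal else Xc @ self._map.T
        out = out + self.mu_hat
        return out[0] if single else out


def fit_regression_calibration(
    X_star, me: MeasurementErrorSpec, diagonal: bool | None = None
) -> CalibrationModel:
    """Fit the moment-based calibration of ``E(X | X*)`` from observed data.

    Sample moments use the n-1 covariance denominator.  With ``diagonal``
    left as ``None`` the calibration is coordinatewise whenever ``Sigma_eps``
    is diagonal (this is the exact affine map restricted to diagonal
    matrices, and sidesteps the singular p x p covariance when p > n);
    passing ``diagonal=False`` forces the full-matrix map, which raises if
    the sample covariance of X* is singular.
    """
    X = _as_matrix(X_star)
    n, p = X.shape
    if n < 2:
        raise ValueError("regression calibration needs at least 2 observations")
    if diagonal is None:
        diagonal = me.is_diagonal
    if diagonal and not me.is_diagonal:
        raise ValueError("diagonal calibration requested with a non-diagonal Sigma_eps")
    mu = X.mean(axis=0)
    if diagonal:
        s2 = X.var(axis=0, ddof=1)
        if np.any(s2 <= 0):
            raise ValueError("zero-variance predictor column; cannot calibrate")
        ratio = (s2 - me.diagonal(p)) / s2
        return CalibrationModel(mu_hat=mu, cov_hat=s2, _map=ratio, diagonal=True)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "sample covariance of X* is singular (p >= n?); "
            "use diagonal calibration or supply more observations"
        )
    if cond > 1e8:
        warnings.warn("sample covariance of X* is ill-conditioned", RuntimeWarning)
    A = np.linalg.solve(cov.T, cov - me.matrix(p)).T  # (cov - Sigma_eps)^T cov^{-1}
    return CalibrationModel(mu_hat=mu, cov_hat=cov, _map=A, diagonal=False)


def corrected_score_lr(beta, X_star, y_corrected, me: MeasurementErrorSpec) -> np.ndarray:
    """Corrected logistic estimating function.

    Equals :func:`boome.glm_core.score_lr` with every predictor row replaced
    by its sufficient statistic ``x* + y** Sigma_eps beta`` (evaluated at the
    supplied beta) and the response replaced by ``y**``.
    """
    X = _as_matrix(X_star)
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y_corrected, dtype=float).ravel()
    X_ss = X + np.outer(y, me.matvec(beta))
    return score_lr(beta, X_ss, y)


def corrected_score_pm(beta, X_calibrated, y_corrected) -> np.ndarray:
    """Corrected probit estimating function on calibrated predictors.

    ``X_calibrated`` is the output of the regression-calibration transform;
    the correction itself is beta-free, so this is simply the naive probit
    estimating function evaluated on ``(X**, Y**)``.
    """
    return score_pm(beta, X_calibrated, y_corrected)
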