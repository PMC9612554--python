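"""Synthetic data with misclassified responses and error-prone predictors.

The generator emulates a sparse high-dimensional binary-regression study:
predictors are i.i.d. standard normal, the latent response follows the
logistic or probit model at a sparse true coefficient vector (default
``beta_0 = (1, 1, 1, 0, ..., 0)``), the recorded response passes through a
misclassification channel with probabilities ``pi10``/``pi01`` driven by a
logistic or probit model in the latent predictors, and the recorded
predictors carry classical additive normal error ``X* = X + eps`` with
``eps ~ N(0, Sigma_eps)`` independent of ``X``.

Reproducibility contract: every public function takes either an integer
seed or a ``numpy.random.Generator``; identical seeds give bitwise
identical output.  Replicated studies derive per-replicate streams as
``seed + replicate_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .glm_core import Model, RegressionSpec, mean_response
from .me_correction import MeasurementErrorSpec, MisclassificationProbabilities

__all__ = [
    "MisclassificationModel",
    "SimulatedData",
    "generate_true",
    "misclass_probs",
    "misclassify",
    "add_classical_error",
    "me_generate",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class MisclassificationModel:
    """Link and parameters generating per-observation (pi10, pi01).

    Each probability is produced by the chosen link evaluated at
    ``intercept + X_i' slopes``; ``gamma10`` and ``gamma01`` are
    ``(intercept, slopes)`` pairs.  Scalar slopes broadcast over all
    predictors; ``slopes=0`` gives constant probabilities, e.g. the pair
    ``(1, 0)`` under the logistic link gives pi = expit(1) ~ 0.731 for
    every observation.
    """

    link: str = "logistic"
    gamma10: tuple = (1.0, 0.0)
    gamma01: tuple = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.link not in ("logistic", "probit"):
            raise ValueError("link must be 'logistic' or 'probit'")

    def _linpred(self, X: np.ndarray, gamma) -> np.ndarray:
        intercept, slopes = gamma
        slopes = np.asarray(slopes, dtype=float)
        if slopes.ndim == 0:
            if slopes == 0.0:
                return np.full(X.shape[0], float(intercept))
            slopes = np.full(X.shape[1], float(slopes))
        if slopes.shape[0] != X.shape[1]:
            raise ValueError("misclassification slope vector does not match p")
        return float(intercept) + X @ slopes

    def probabilities(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        link = expit if self.link == "logistic" else ndtr
        return (
            link(self._linpred(X, self.gamma10)),
            link(self._linpred(X, self.gamma01)),
        )


@dataclass(frozen=True)
class SimulatedData:
    """Bundle of latent and observed data from one simulated study."""

    X_true: np.ndarray
    Y_true: np.ndarray
    X_obs: np.ndarray
    Y_obs: np.ndarray
    probs: MisclassificationProbabilities
    beta_true: np.ndarray
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        """Observed data as an n x (p+1) table: column 'y' then '1'..'p'."""
        df = pd.DataFrame(self.X_obs, columns=[str(j + 1) for j in range(self.X_obs.shape[1])])
        df.insert(0, "y", self.Y_obs.astype(int))
        return df

    def probs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs.to_array(), columns=["pi10", "pi01"])


def generate_true(n: int, p: int, beta_true, spec=RegressionSpec(), seed=None):
    """Latent data: ``X ~ N(0, I_p)`` rows, ``Y ~ Bernoulli(mu(X' beta))``."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_true.shape != (p,):
        raise ValueError("beta_true must have length p")
    rng = _rng(seed)
    X = rng.standard_normal((n, p))
    mu = mean_response(X, beta_true, spec)
    Y = (rng.random(n) < mu).astype(float)
    return X, Y


def misclass_probs(X, model: MisclassificationModel) -> MisclassificationProbabilities:
    """Per-observation misclassification probabilities from the model.

    Raises when the implied misclassification matrix is singular anywhere
    (``pi10 + pi01 = 1``, e.g. both probabilities 0.5).
    """
    X = np.asarray(X, dtype=float)
    p10, p01 = model.probabilities(X)
    return MisclassificationProbabilities(p10, p01)


def misclassify(Y_true, probs: MisclassificationProbabilities, seed=None) -> np.ndarray:
    """Push the true 0/1 response through the misclassification channel.

    ``Y* = 1`` with probability ``1 - pi01`` when ``Y = 1`` and with
    probability ``pi10`` when ``Y = 0``.
    """
    Y = np.asarray(Y_true, dtype=float).ravel()
    if Y.shape[0] != len(probs):
        raise ValueError("Y and probabilities differ in length")
    rng = _rng(seed)
    p_one = np.where(Y == 1.0, 1.0 - probs.pi01, probs.pi10)
    return (rng.random(Y.shape[0]) < p_one).astype(float)


def add_classical_error(X_true, me: MeasurementErrorSpec, seed=None) -> np.ndarray:
    """Observed predictors ``X* = X + eps``, ``eps ~ N(0, Sigma_eps)`` i.i.d. rows."""
    X = np.asarray(X_true, dtype=float)
    n, p = X.shape
    rng = _rng(seed)
    if me.is_diagonal:
        sd = np.sqrt(me.diagonal(p))
        eps = rng.standard_normal((n, p)) * sd
    else:
        chol = np.linalg.cholesky(me.matrix(p) + 1e-12 * np.eye(p))
        eps = rng.standard_normal((n, p)) @ chol.T
    return X + eps


def me_generate(
    n: int,
    beta_true,
    me: MeasurementErrorSpec,
    X_true=None,
    model: MisclassificationModel = MisclassificationModel(),
    spec=RegressionSpec(),
    seed=None,
) -> SimulatedData:
    """Full simulated study: latent data, misclassification, predictor error.

    ``X_true`` may be supplied (n x p) to reuse a fixed design; otherwise
    the latent predictors are drawn standard normal.  The misclassification
    probabilities are evaluated at the latent predictors.
    """
    beta_true = np.asarray(beta_true, dtype=float)
    p = beta_true.shape[0]
    rng = _rng(seed)
    if X_true is None:
        X_true, Y_true = generate_true(n, p, beta_true, spec, rng)
    else:
        X_true = np.asarray(X_true, dtype=float)
        if X_true.shape != (n, p):
            raise ValueError(f"X_true must be {n} x {p}")
        mu = mean_response(X_true, beta_true, spec)
        Y_true = (rng.random(n) < mu).astype(float)
    probs = misclass_probs(X_true, model)
    Y_obs = misclassify(Y_true, probs, rng)
    X_obs = add_classical_error(X_true, me, rng)
    return SimulatedData(
        X_true=X_true,
        Y_true=Y_true,
        X_obs=X_obs,
        Y_obs=Y_obs,
        probs=probs,
        beta_true=beta_true,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
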