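"""Estimation/selection metrics and replicated-study drivers.

Metrics follow the simulation-study conventions for sparse binary
regression: L1 and L2 norms of ``beta_hat - beta_0``, plus two selection
rates.  Note the naming: here *SPE* is the fraction of truly informative
predictors that were correctly included and *SEN* is the fraction of
truly unimportant predictors correctly excluded -- the reverse of the
usual sensitivity/specificity convention, preserved deliberately because
the study design this module reproduces defines them that way.

``run_simulation_study`` replicates the full pipeline (generate ->
correct -> boost -> score) over a factorial grid of (model, p, sigma^2,
correction setting) and reports Monte Carlo means with standard errors;
``run_sensitivity`` profiles the selection of a single observed dataset
over a grid of assumed error variances, reporting the predictors
commonly selected across the grid (set intersection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .boost import BoostConfig, boost_fit
from .glm_core import Model, RegressionSpec
from .me_correction import MeasurementErrorSpec
from .simulate import MisclassificationModel, me_generate

__all__ = [
    "SelectionMetrics",
    "StudyReport",
    "SETTINGS",
    "estimation_errors",
    "selection_rates",
    "run_simulation_study",
    "run_sensitivity",
]

logger = logging.getLogger("boome")

#: correction flags (correct_x, correct_y) for the four settings:
#: 1 = no corrections, 2 = response only, 3 = predictors only, 4 = both.
SETTINGS = {1: (False, False), 2: (False, True), 3: (True, False), 4: (True, True)}


@dataclass(frozen=True)
class SelectionMetrics:
    """Estimation error norms and selection rates for one fit."""

    l1: float
    l2: float
    spe: float
    sen: float


@dataclass(frozen=True)
class StudyReport:
    """Replicated-study summary: one row per (model, p, sigma2, setting) cell."""

    table: pd.DataFrame
    replicates: int
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def estimation_errors(beta_hat, beta_true) -> tuple[float, float]:
    """(L1, L2) norms of the estimation error ``beta_hat - beta_0``."""
    bh = np.asarray(beta_hat, dtype=float)
    bt = np.asarray(beta_true, dtype=float)
    if bh.shape != bt.shape:
        raise ValueError("beta_hat and beta_true differ in length")
    d = bh - bt
    return float(np.abs(d).sum()), float(np.sqrt((d**2).sum()))


def selection_rates(selected, truth, p: int) -> tuple[float, float]:
    """(SPE, SEN) selection rates.

    ``SPE = |selected ∩ truth| / |truth|`` (informative predictors
    correctly included) and ``SEN = |excluded ∩ non-truth| / (p - |truth|)``
    (unimportant predictors correctly excluded).  Indices are 1-based.
    """
    truth = set(int(j) for j in truth)
    selected = set(int(j) for j in selected)
    if not truth:
        raise ValueError("truth must be nonempty")
    universe = set(range(1, p + 1))
    if not truth <= universe or not selected <= universe:
        raise ValueError("indices must lie in 1..p")
    if len(truth) == p:
        raise ValueError("SEN undefined: no truly unimportant predictors")
    spe = len(selected & truth) / len(truth)
    sen = len((universe - selected) & (universe - truth)) / (p - len(truth))
    return spe, sen


def _default_beta(p: int) -> np.ndarray:
    beta = np.zeros(p)
    beta[:3] = 1.0
    return beta


def run_simulation_study(
    models=(Model.LOGISTIC,),
    p_values=(1000,),
    sigma_values=(0.15,),
    settings=(1, 2, 3, 4),
    n: int = 100,
    reps: int = 100,
    boost_params: dict | None = None,
    seed: int = 0,
    beta_true=None,
    misclass: MisclassificationModel = MisclassificationModel(),
) -> StudyReport:
    """Replicated factorial simulation study.

    For every cell of ``models x p_values x sigma_values x settings``,
    ``reps`` datasets are generated (per-replicate seed = ``seed + r``;
    replicates are shared across settings within a (model, p, sigma) cell
    so that setting contrasts are paired), the boosting fit is run with
    the cell's correction flags, and L1/L2/SPE/SEN are averaged.
    ``boost_params`` overrides :class:`BoostConfig` fields (e.g.
    ``{"n_iter": 1000, "tau": 0.9, "eta": 1e-5}``); the ``model`` and
    correction flags are set per cell.  Replicates that fail numerically
    are logged and excluded; a cell is flagged when more than 10% fail.
    """
    boost_params = dict(boost_params or {})
    boost_params.pop("model", None)
    rows = []
    for model in models:
        model = Model(model)
        spec = RegressionSpec(model)
        for p in p_values:
            beta0 = _default_beta(p) if beta_true is None else np.asarray(beta_true, float)
            truth = set((np.flatnonzero(beta0 != 0) + 1).tolist())
            for s2 in sigma_values:
                me = MeasurementErrorSpec(float(s2))
                per_setting: dict[int, list[SelectionMetrics]] = {s: [] for s in settings}
                failures = {s: 0 for s in settings}
                for r in range(reps):
                    sim = me_generate(n, beta0, me, model=misclass, spec=spec,
                                      seed=seed + r)
                    for setting in settings:
                        cx, cy = SETTINGS[setting]
                        config = BoostConfig(model=model, correct_x=cx, correct_y=cy,
                                             **boost_params)
                        try:
                            res = boost_fit(sim.X_obs, sim.Y_obs, probs=sim.probs,
                                            me=me, config=config)
                        except FloatingPointError as err:
                            failures[setting] += 1
                            logger.warning(
                                "replicate %d failed (model=%s p=%d sigma2=%g setting=%d): %s",
                                r, model.value, p, s2, setting, err,
                            )
                            continue
                        l1, l2 = estimation_errors(res.beta_hat, beta0)
                        spe, sen = selection_rates(res.selected, truth, p)
                        per_setting[setting].append(SelectionMetrics(l1, l2, spe, sen))
                for setting in settings:
                    ms = per_setting[setting]
                    nrep = len(ms)
                    flagged = failures[setting] > 0.1 * reps
                    if flagged:
                        logger.warning(
                            "cell (model=%s p=%d sigma2=%g setting=%d): %d/%d replicates failed",
                            model.value, p, s2, setting, failures[setting], reps,
                        )
                    arr = np.array([[m.l1, m.l2, m.spe, m.sen] for m in ms]) \
                        if nrep else np.full((1, 4), np.nan)
                    mean = arr.mean(axis=0)
                    se = arr.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1 else np.full(4, np.nan)
                    rows.append({
                        "model": model.value, "p": p, "sigma2": s2, "setting": setting,
                        "l1": mean[0], "l2": mean[1], "spe": mean[2], "sen": mean[3],
                        "l1_se": se[0], "l2_se": se[1], "spe_se": se[2], "sen_se": se[3],
                        "replicates": nrep, "failed": failures[setting],
                        "flagged": flagged,
                    })
    return StudyReport(table=pd.DataFrame(rows), replicates=reps, seed=seed)


def run_sensitivity(
    X_obs,
    Y_obs,
    sigma_grid,
    probs,
    settings=(1, 2, 3, 4),
    boost_params: dict | None = None,
    model: Model = Model.LOGISTIC,
) -> dict:
    """Sensitivity profile of selection over assumed error variances.

    For every ``sigma^2`` in ``sigma_grid`` and every correction setting,
    the model is fitted on the observed data with ``Sigma_eps = sigma^2 I``
    and the selected indices and estimates recorded.  For each setting the
    profile also reports the predictors *commonly selected* across the
    whole grid (set intersection), the stable core of the selection.

    Returns ``{setting: {"fits": {sigma2: FitResult}, "table": DataFrame,
    "common": [indices]}}``.
    """
    boost_params = dict(boost_params or {})
    boost_params.pop("model", None)
    out = {}
    for setting in settings:
        cx, cy = SETTINGS[setting]
        config = BoostConfig(model=Model(model), correct_x=cx, correct_y=cy,
                             **boost_params)
        fits = {}
        for s2 in sigma_grid:
            fits[s2] = boost_fit(X_obs, Y_obs, probs=probs,
                                 me=MeasurementErrorSpec(float(s2)), config=config)
        common = set(fits[next(iter(fits))].selected)
        for res in fits.values():
            common &= set(res.selected)
        records = []
        for s2, res in fits.items():
            for j in res.selected:
                records.append({"sigma2": s2, "predictor": j,
                                "estimate": res.beta_hat[j - 1]})
        out[setting] = {
            "fits": fits,
            "table": pd.DataFrame(records, columns=["sigma2", "predictor", "estimate"]),
            "common": sorted(common),
        }
    return out
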