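"""Predictive-ability metrics and model-comparison posteriors.

Metrics for forward validation in the testing set:

ACC
    corrected accuracy — Pearson correlation between observed and
    predicted values divided by the square root of the mean response
    reliability (correcting for the noise in the pseudo-phenotype).
RMSE*
    root-mean-square prediction error divided by the sample standard
    deviation of the observed values (dimensionless; 1 = as bad as
    predicting the mean).
b
    inflation/dispersion factor — slope of the regression of observations
    on predictions; 1 is dispersion-unbiased.
ACCpar
    parametric accuracy sqrt(h2 of the predictions) x genetic
    correlation(observations, predictions), both estimated by a bi-trait
    kernel mixed model fitted to the testing set only; robust to the
    environmental covariance that can inflate ACC under CV2.
lambda_ACC
    posterior difference between two models' ACCpar draws, with
    P[lambda < 0] as the comparison tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmarks import MTGBLUP

__all__ = [
    "acc",
    "rmse_star",
    "inflation_b",
    "acc_par",
    "acc_par_contrast",
    "EvalReport",
    "evaluate_predictions",
]


def _check_pair(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors must have equal length")
    return y_obs, y_pred


def acc(y_obs, y_pred, mean_reliability: float = 1.0) -> float:
    """Corrected accuracy: Pearson r / sqrt(mean reliability)."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    if not 0.0 < mean_reliability <= 1.0:
        raise ValueError("mean_reliability must lie in (0, 1]")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r = float(np.corrcoef(y_obs, y_pred)[0, 1])
    return r / float(np.sqrt(mean_reliability))


def rmse_star(y_obs, y_pred) -> float:
    """Relative RMSE: sqrt(mean squared error) / SD of observations."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    sd = float(np.std(y_obs, ddof=0))
    if sd == 0:
        raise ValueError("observed values are constant; RMSE* undefined")
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    return rmse / sd


def inflation_b(y_obs, y_pred) -> float:
    """Dispersion bias: slope of the regression of y_obs on y_pred."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    var_p = float(np.var(y_pred, ddof=0))
    if var_p == 0:
        raise ValueError("constant predictions; inflation factor undefined")
    cov = float(np.mean((y_obs - y_obs.mean()) * (y_pred - y_pred.mean())))
    return cov / var_p


def acc_par(
    y_obs_test,
    y_pred_test,
    kernel_test,
    n_iter: int = 2_000,
    burn_in: int = 500,
    thin: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Posterior draws of the parametric accuracy on the testing set.

    Fits a bi-trait kernel mixed model to (observations, predictions)
    restricted to the testing individuals; each retained draw yields
    sqrt(h2 of the predictions) x genetic correlation.
    """
    y_obs_test, y_pred_test = _check_pair(y_obs_test, y_pred_test)
    Y = np.column_stack([y_obs_test, y_pred_test])
    res = MTGBLUP(Y, kernel_test).fit(
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed
    )
    h_pred = np.sqrt(res.h2_draws(1))
    r_g = res.genetic_corr_draws(0, 1)
    return h_pred * r_g


def acc_par_contrast(draws_a, draws_b) -> tuple[np.ndarray, float]:
    """lambda = draws_a - draws_b paired by draw index; returns P[lambda < 0].

    The two chains are independent; pairing by index is a convention that
    leaves the marginal distribution of the difference intact. Unequal
    chain lengths are truncated to the shorter.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    n = min(len(a), len(b))
    lam = a[:n] - b[:n]
    return lam, float(np.mean(lam < 0))


@dataclass
class EvalReport:
    """Tabular metric report, optionally with ACCpar posterior draws."""

    table: pd.DataFrame
    acc_par_draws: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def evaluate_predictions(
    y_obs,
    y_pred,
    mean_reliability: float = 1.0,
    generations=None,
    model: str = "model",
    design: str = "",
) -> EvalReport:
    """ACC, RMSE* and b, pooled and (optionally) per test generation."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    rows = [
        {
            "model": model,
            "design": design,
            "generation": "all",
            "n": len(y_obs),
            "ACC": acc(y_obs, y_pred, mean_reliability),
            "RMSE_star": rmse_star(y_obs, y_pred),
            "b": inflation_b(y_obs, y_pred),
        }
    ]
    if generations is not None:
        generations = np.asarray(generations)
        for g in np.unique(generations):
            m = generations == g
            if m.sum() < 3 or np.std(y_obs[m]) == 0 or np.std(y_pred[m]) == 0:
                continue
            rows.append(
                {
                    "model": model,
                    "design": design,
                    "generation": str(int(g)),
                    "n": int(m.sum()),
                    "ACC": acc(y_obs[m], y_pred[m], mean_reliability),
                    "RMSE_star": rmse_star(y_obs[m], y_pred[m]),
                    "b": inflation_b(y_obs[m], y_pred[m]),
                }
            )
    return EvalReport(table=pd.DataFrame.from_records(rows))
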