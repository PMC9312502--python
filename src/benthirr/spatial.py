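"""Random-forest spatial modelling of index values from environmental layers.

The protocol: log10(x+1)-transform the station index values, screen the
predictors for collinearity (|Pearson r| > 0.90, p < 0.05 — the pair member
with the weaker rank correlation to the response is dropped), fit forests of
1000 trees at 1..5 candidate variables per split, keep the setting with the
highest out-of-bag % variance explained, and report out-of-bag permutation
importance (%IncMSE) and Kendall's τ between out-of-bag predictions and
observations.  Full-coverage prediction applies the fitted forest cell-wise
to a co-registered raster stack.

The reference bioturbation-potential (BPc) map uses the same pipeline with
500 trees and 3 variables per split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .raster import PredictorStack, Raster
from .temporal import log10p1

PEARSON_DROP_R = 0.90


@dataclass
class DroppedPredictor:
    name: str
    reason: str
    partner: str | None = None
    correlation: float | None = None


def collinearity_screen(
    predictors: pd.DataFrame,
    response: Sequence[float],
    r_threshold: float = PEARSON_DROP_R,
    p_threshold: float = 0.05,
) -> tuple[list[str], list[DroppedPredictor]]:
    """Iteratively drop one member of every highly collinear predictor pair.

    For each pair with |Pearson r| > ``r_threshold`` (and p < ``p_threshold``)
    the member with the smaller |Spearman| correlation to the response is
    dropped; repeated until no offending pair remains.  Constant predictors
    are dropped up front (their correlations are undefined).
    """
    y = np.asarray(response, dtype=float)
    if predictors.shape[0] != y.size:
        raise ValueError("predictors and response must have the same length")
    if predictors.shape[0] < 3:
        raise ValueError("need at least 3 stations for a correlation screen")

    retained = list(predictors.columns)
    dropped: list[DroppedPredictor] = []
    for name in list(retained):
        if np.std(predictors[name].to_numpy(dtype=float)) == 0:
            retained.remove(name)
            dropped.append(DroppedPredictor(name, "constant predictor"))

    def power(name: str) -> float:
        rho = stats.spearmanr(predictors[name], y).statistic
        return 0.0 if np.isnan(rho) else abs(float(rho))

    while True:
        worst: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(retained, 2):
            r, p = stats.pearsonr(predictors[a], predictors[b])
            if abs(r) > r_threshold and p < p_threshold:
                if worst is None or abs(r) > worst[0]:
                    worst = (abs(r), a, b)
        if worst is None:
            break
        _, a, b = worst
        loser = b if power(a) >= power(b) else a
        keeper = a if loser == b else b
        retained.remove(loser)
        dropped.append(
            DroppedPredictor(loser, "collinear", partner=keeper, correlation=worst[0])
        )
    return retained, dropped


@dataclass
class SpatialFit:
    """Fitted spatial model: estimates, diagnostics and the forest itself."""

    predictors: list[str]
    dropped: list[DroppedPredictor]
    n_trees: int
    mtry: int
    oob_variance_explained_pct: float
    importance_pct_inc_mse: dict[str, float]
    kendall_tau: float | None
    kendall_p: float | None
    seed: int
    forest: RandomForestRegressor = field(repr=False)
    oob_prediction: np.ndarray = field(repr=False)
    response_transformed: np.ndarray = field(repr=False)
    transform: str = "log10p1"

    def summary(self) -> pd.DataFrame:
        rows = [
            ("n stations", len(self.response_transformed)),
            ("predictors retained", len(self.predictors)),
            ("trees", self.n_trees),
            ("variables per split", self.mtry),
            ("OOB variance explained (%)", round(self.oob_variance_explained_pct, 2)),
            ("Kendall tau (OOB vs observed)",
             None if self.kendall_tau is None else round(self.kendall_tau, 3)),
            ("seed", self.seed),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def importance_table(self) -> pd.DataFrame:
        items = sorted(
            self.importance_pct_inc_mse.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return pd.DataFrame(items, columns=["predictor", "pct_inc_mse"])


def _oob_indices(forest: RandomForestRegressor, n_samples: int) -> list[np.ndarray]:
    nb = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    return [
        _generate_unsampled_indices(tree.random_state, n_samples, nb, None)
        for tree in forest.estimators_
    ]


def _oob_predict(
    forest: RandomForestRegressor,
    X: np.ndarray,
    oob_idx: list[np.ndarray],
) -> np.ndarray:
    """Out-of-bag predictions; NaN where a sample was never out of bag."""
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    for tree, idx in zip(forest.estimators_, oob_idx):
        if idx.size == 0:
            continue
        total[idx] += tree.predict(X[idx])
        count[idx] += 1
    out = np.full(n, np.nan)
    seen = count > 0
    out[seen] = total[seen] / count[seen]
    return out


def oob_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """%IncMSE: % increase in out-of-bag MSE when a predictor is permuted.

    Averaged over ``repeats`` independent shuffles with a fixed sub-seed.
    """
    rng = np.random.default_rng(seed)
    oob_idx = _oob_indices(forest, X.shape[0])
    base_pred = _oob_predict(forest, X, oob_idx)
    seen = ~np.isnan(base_pred)
    base_mse = float(np.mean((base_pred[seen] - y[seen]) ** 2))
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        mses = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = _oob_predict(forest, Xp, oob_idx)
            mses.append(float(np.mean((pred[seen] - y[seen]) ** 2)))
        out[name] = 100.0 * (float(np.mean(mses)) - base_mse) / base_mse
    return out


class SpatialModel:
    """Random-forest regression of an index on environmental predictors.

    Parameters
    ----------
    response : station index values (untransformed, non-negative)
    predictors : stations × predictors DataFrame (column names = layer names)
    screen : apply the collinearity screen before fitting
    """

    def __init__(
        self,
        response: Sequence[float],
        predictors: pd.DataFrame,
        screen: bool = True,
    ):
        self.y_raw = np.asarray(response, dtype=float)
        if np.any(self.y_raw < 0):
            raise ValueError("index response must be non-negative")
        if self.y_raw.size < 10:
            raise ValueError("need at least 10 stations to fit the spatial model")
        if predictors.shape[1] < 1:
            raise ValueError("need at least one predictor")
        if predictors.shape[0] != self.y_raw.size:
            raise ValueError("predictors and response must align")
        self.y = log10p1(self.y_raw)
        if screen:
            self.retained, self.dropped = collinearity_screen(predictors, self.y)
        else:
            self.retained, self.dropped = list(predictors.columns), []
        if not self.retained:
            raise ValueError("collinearity screen removed every predictor")
        self.X = predictors[self.retained].to_numpy(dtype=float)

    def fit(
        self,
        n_trees: int = 1000,
        mtry_values: Sequence[int] = (1, 2, 3, 4, 5),
        seed: int = 0,
        importance_repeats: int = 10,
    ) -> SpatialFit:
        """Fit forests over the mtry grid and keep the best OOB setting.

        "Best" is the highest out-of-bag % variance explained; ties go to
        the smaller mtry.  The selected forest is then characterised by OOB
        permutation importance and OOB Kendall's τ.
        """
        p = len(self.retained)
        grid = sorted({min(m, p) for m in mtry_values if m >= 1})
        if not grid:
            raise ValueError("mtry grid is empty")
        best: tuple[float, int, RandomForestRegressor] | None = None
        for m in grid:
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=m,
                oob_score=True,
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            forest.fit(self.X, self.y)
            score = 100.0 * float(forest.oob_score_)
            if best is None or score > best[0]:
                best = (score, m, forest)
        score, mtry, forest = best

        oob_idx = _oob_indices(forest, self.X.shape[0])
        oob_pred = _oob_predict(forest, self.X, oob_idx)
        tau, tau_p = validate(oob_pred, self.y)
        imp = oob_importance(
            forest, self.X, self.y, self.retained,
            repeats=importance_repeats, seed=seed,
        )
        return SpatialFit(
            predictors=list(self.retained),
            dropped=list(self.dropped),
            n_trees=n_trees,
            mtry=mtry,
            oob_variance_explained_pct=score,
            importance_pct_inc_mse=imp,
            kendall_tau=tau,
            kendall_p=tau_p,
            seed=seed,
            forest=forest,
            oob_prediction=oob_pred,
            response_transformed=self.y,
        )


def validate(
    predicted: Sequence[float], observed: Sequence[float]
) -> tuple[float | None, float | None]:
    """Kendall's τ (two-sided p) between modelled and observed values.

    NaNs (samples never out of bag) are dropped pairwise; a constant
    prediction vector leaves τ undefined → ``(None, None)``.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(pred) | np.isnan(obs))
    pred, obs = pred[ok], obs[ok]
    if pred.size < 3:
        raise ValueError("need at least 3 paired values for Kendall's tau")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        return None, None
    res = stats.kendalltau(pred, obs)
    return float(res.statistic), float(res.pvalue)


def predict_raster(
    fit: SpatialFit,
    stack: PredictorStack,
    back_transform: bool = False,
) -> Raster:
    """Cell-wise prediction over a raster stack, on the log10(x+1) scale.

    The stack must contain every retained predictor (extra layers are
    ignored); cells masked in any input layer stay masked.  With
    ``back_transform`` the output is 10^ŷ − 1 (no bias correction).
    """
    sub = stack.subset(fit.predictors)
    matrix, valid = sub.matrix()
    out = sub.blank_like()
    flat = np.full(matrix.shape[0], np.nan)
    if valid.any():
        flat[valid] = fit.forest.predict(matrix[valid])
    if back_transform:
        flat = np.power(10.0, flat) - 1.0
    grid = flat.reshape(out.shape)
    out.data = np.ma.masked_invalid(grid)
    return out


def tabular_predict(fit: SpatialFit, predictors: pd.DataFrame) -> np.ndarray:
    """Predict (log scale) from a stations × predictors table."""
    return fit.forest.predict(predictors[fit.predictors].to_numpy(dtype=float))
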