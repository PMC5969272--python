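"""Single-hidden-layer networks for daily LUE prediction.

The training protocol mirrors the analysis it supports: predictors are
min-max scaled on the training days, the hidden-layer size is selected by
repeated k-fold cross-validation over a node grid (lowest CV RMSE wins,
ties go to the smaller network), the winner is refit on all training days,
and the whole procedure is repeated ``outer_repeats`` times; the ensemble
prediction is the mean over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .types import NNHyper

#: Minimum number of training days required for a site-level model fit.
MIN_TRAIN_DAYS = 500


class InsufficientDataError(RuntimeError):
    """Raised when a site offers too few cleaned days for model training."""


def scale_predictors(features: pd.DataFrame, train_mask=None
                     ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min-max scale each predictor to [0, 1] on the training days.

    The scaling record maps column name to (min, max) fitted on the days
    selected by ``train_mask`` (all days if None) and is reused verbatim at
    prediction time. A zero-range predictor is rejected by name.
    """
    if train_mask is None:
        train_mask = np.ones(len(features), dtype=bool)
    record: dict[str, tuple[float, float]] = {}
    scaled = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        lo = float(np.nanmin(x[train_mask]))
        hi = float(np.nanmax(x[train_mask]))
        if hi - lo <= 0:
            raise ValueError(f"predictor {col!r} has zero range on training data")
        record[col] = (lo, hi)
        scaled[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(scaled, index=features.index), record


def unscale(scaled: pd.DataFrame, record: dict[str, tuple[float, float]]
            ) -> pd.DataFrame:
    """Invert :func:`scale_predictors` (roundtrip identity)."""
    out = {}
    for col, (lo, hi) in record.items():
        out[col] = scaled[col].to_numpy(dtype=float) * (hi - lo) + lo
    return pd.DataFrame(out, index=scaled.index)


def apply_scaling(features: pd.DataFrame,
                  record: dict[str, tuple[float, float]]) -> np.ndarray:
    cols = []
    for col, (lo, hi) in record.items():
        cols.append((features[col].to_numpy(dtype=float) - lo) / (hi - lo))
    return np.column_stack(cols)


@dataclass
class LueNN:
    """A trained LUE predictor: repeat models plus the scaling record."""

    models: list
    scaling: dict[str, tuple[float, float]]
    feature_names: list[str]
    selection_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Mean prediction across repeats on the original feature scale."""
        X = apply_scaling(features[self.feature_names], self.scaling)
        preds = np.column_stack([m.predict(X) for m in self.models])
        return preds.mean(axis=1)


def _mlp(nodes: int, hyper: NNHyper, rs: int) -> MLPRegressor:
    return MLPRegressor(hidden_layer_sizes=(nodes,), solver="lbfgs",
                        alpha=hyper.decay, max_iter=hyper.max_iter,
                        random_state=rs)


def _cv_rmse(X: np.ndarray, y: np.ndarray, nodes: int, hyper: NNHyper,
             base_seed: int) -> float:
    errs = []
    for rep in range(hyper.cv_repeats):
        kf = KFold(n_splits=hyper.n_folds, shuffle=True,
                   random_state=base_seed + rep)
        for k, (tr, te) in enumerate(kf.split(X)):
            m = _mlp(nodes, hyper, base_seed + 97 * rep + k)
            m.fit(X[tr], y[tr])
            r = m.predict(X[te]) - y[te]
            errs.append(np.sqrt(np.mean(r**2)))
    return float(np.mean(errs))


def train_lue_nn(features: pd.DataFrame, target: pd.Series, hyper: NNHyper,
                 day_mask=None, min_days: int = MIN_TRAIN_DAYS) -> LueNN:
    """Train the repeat-averaged LUE network on the masked days.

    ``day_mask`` selects the training days (e.g. moist days for the
    potential-LUE model); days with a missing target are dropped
    automatically. Fewer than ``min_days`` usable days raises
    :class:`InsufficientDataError`.
    """
    if day_mask is None:
        day_mask = np.ones(len(features), dtype=bool)
    day_mask = np.asarray(day_mask, dtype=bool)
    y_all = target.to_numpy(dtype=float)
    usable = day_mask & np.isfinite(y_all) & \
        np.all(np.isfinite(features.to_numpy(dtype=float)), axis=1)
    if usable.sum() < min_days:
        raise InsufficientDataError(
            f"insufficient data: {int(usable.sum())} days < {min_days}")

    scaled, record = scale_predictors(features, train_mask=usable)
    X = scaled.to_numpy()[usable]
    y = y_all[usable]

    models, log_rows = [], []
    grid = sorted(hyper.hidden_nodes_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(hyper.outer_repeats):
            seed = hyper.seed + 1000 * rep
            if len(grid) == 1:
                best, best_rmse = grid[0], np.nan
            else:
                rmses = [_cv_rmse(X, y, h, hyper, seed) for h in grid]
                # strict '<' over the ascending grid: ties keep the smaller net
                best_i = int(np.argmin(rmses))
                best, best_rmse = grid[best_i], rmses[best_i]
            m = _mlp(best, hyper, seed + 7)
            m.fit(X, y)
            models.append(m)
            log_rows.append({"repeat": rep, "nodes": best, "cv_rmse": best_rmse})
    return LueNN(models=models, scaling=record,
                 feature_names=list(features.columns),
                 selection_log=pd.DataFrame(log_rows))
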