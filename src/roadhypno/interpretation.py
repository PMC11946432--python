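"""Feature-importance and explanation analyses for the emission scorers.

Four complementary views of what drives the state decision: split-based
importance (gain / cover / frequency aggregated over every tree of every
per-state scorer), exact tree-path additive attributions (Shapley values
for tree ensembles), a local linear surrogate fitted on a perturbation
neighbourhood of one row, and two selection procedures (L1-penalized
regression and recursive feature elimination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LassoCV, LinearRegression, lasso_path

from .hybrid_hmm import EmissionModel

__all__ = [
    "ImportanceTable",
    "split_importance",
    "additive_attribution",
    "local_surrogate",
    "l1_select",
    "recursive_elimination",
]


@dataclass
class ImportanceTable:
    """Per-feature gain / cover / frequency, aggregated across scorers."""

    table: pd.DataFrame  # index: feature name; columns: gain, cover, frequency
    method: str = "xgboost-split"

    def top(self, metric: str, n: int = 3) -> list[str]:
        return list(self.table.sort_values(metric, ascending=False).index[:n])


def split_importance(model: EmissionModel) -> ImportanceTable:
    """Aggregate total gain, total cover and split frequency per feature.

    Sums over all trees of all per-state scorers.  A feature never used in
    any split has zeros in every column.
    """
    if not model.boosters:
        raise ValueError("untrained model")
    names = model.feature_names
    table = pd.DataFrame(0.0, index=names, columns=["gain", "cover", "frequency"])
    for booster in model.boosters:
        if booster.num_boosted_rounds() == 0:
            raise ValueError("untrained booster in emission model")
        for kind, col in (("total_gain", "gain"), ("total_cover", "cover"),
                          ("weight", "frequency")):
            for key, value in booster.get_score(importance_type=kind).items():
                # keys are feature names (or f<idx> when unnamed)
                name = names[int(key[1:])] if key.startswith("f") and key[1:].isdigit() \
                    and key not in names else key
                table.loc[name, col] += value
    return ImportanceTable(table=table)


def additive_attribution(booster: xgb.Booster, rows: np.ndarray
                         ) -> tuple[np.ndarray, float]:
    """Exact tree-path Shapley attributions for each row.

    Returns ``(contributions, base_value)`` with ``contributions`` of shape
    ``(n_rows, n_features)``; per row, ``base + Σ contributions`` equals the
    raw model output.
    """
    x = np.atleast_2d(np.asarray(rows, dtype=float))
    if booster.num_features() != x.shape[1]:
        raise ValueError(
            f"model expects {booster.num_features()} features, got {x.shape[1]}")
    contrib = booster.predict(xgb.DMatrix(x), pred_contribs=True)
    return contrib[:, :-1], float(contrib[0, -1])


def local_surrogate(predict_fn, row: np.ndarray, n_perturbations: int = 5000,
                    scale: float = 0.5, kernel_width: float | None = None,
                    seed: int = 0) -> tuple[np.ndarray, float, float]:
    """Local linear surrogate of ``predict_fn`` around ``row``.

    Gaussian perturbations (sd ``scale`` per standardized feature) are drawn
    around the row, weighted by an exponential kernel on Euclidean distance,
    and a weighted least-squares linear model is fitted to the black-box
    outputs.  Returns ``(coefficients, intercept, weighted R²)``.
    """
    x0 = np.asarray(row, dtype=float).ravel()
    p = x0.size
    rng = np.random.default_rng(seed)
    perturbed = x0 + rng.normal(scale=scale, size=(n_perturbations, p))
    y = np.asarray(predict_fn(perturbed), dtype=float).ravel()
    dist = np.linalg.norm(perturbed - x0, axis=1)
    width = kernel_width if kernel_width is not None else np.sqrt(p) * scale
    weights = np.exp(-(dist**2) / (width**2))
    if np.ptp(perturbed, axis=0).min() <= 0:
        raise ValueError("degenerate perturbation set")
    fit = LinearRegression().fit(perturbed, y, sample_weight=weights)
    r2 = float(fit.score(perturbed, y, sample_weight=weights))
    return fit.coef_, float(fit.intercept_), r2


def l1_select(features: np.ndarray, target: np.ndarray,
              penalties: np.ndarray | None = None, cv: int = 5,
              seed: int = 0) -> dict:
    """L1-penalized (lasso) coefficient path and cross-validated selection.

    Features are expected standardized; unstandardized input triggers a
    warning and internal z-scoring.  Returns the path, the CV-chosen
    penalty, its coefficients, and the surviving feature indices.  A zero
    penalty reproduces the least-squares solution.
    """
    import warnings

    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    if np.max(np.abs(mu)) > 1e-6 or np.max(np.abs(sd - 1)) > 1e-3:
        warnings.warn("features are not standardized; z-scoring internally",
                      stacklevel=2)
        sd = np.where(sd > 0, sd, 1.0)
        x = (x - mu) / sd
    alphas, coef_path, _ = lasso_path(x, y, alphas=penalties)
    lcv = LassoCV(alphas=penalties, cv=cv, random_state=seed).fit(x, y)
    selected = np.flatnonzero(np.abs(lcv.coef_) > 1e-12)
    return {
        "alphas": alphas,
        "coef_path": coef_path,
        "alpha_cv": float(lcv.alpha_),
        "coefficients": lcv.coef_,
        "intercept": float(lcv.intercept_),
        "selected": selected,
    }


def recursive_elimination(features: np.ndarray, target: np.ndarray,
                          make_estimator=None, step: int = 1,
                          seed: int = 0) -> dict:
    """Recursive feature elimination.

    Repeatedly fits the estimator and drops the ``step`` lowest-importance
    features until one remains.  Returns the elimination order (first
    dropped first) and a rank per feature (1 = kept longest).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    n_features = x.shape[1]
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if step >= n_features:
        raise ValueError("step must be smaller than the number of features")
    if make_estimator is None:
        def make_estimator():
            return xgb.XGBRegressor(n_estimators=60, max_depth=3,
                                    learning_rate=0.2, random_state=seed,
                                    n_jobs=1, tree_method="hist")
    remaining = list(range(n_features))
    eliminated: list[int] = []
    while len(remaining) > 1:
        est = make_estimator()
        est.fit(x[:, remaining], y)
        imp = np.asarray(est.feature_importances_, dtype=float)
        drop_n = min(step, len(remaining) - 1)
        worst = np.argsort(imp, kind="stable")[:drop_n]
        for w in sorted(worst, reverse=True):
            eliminated.append(remaining.pop(int(w)))
    ranking = np.empty(n_features, dtype=int)
    ranking[remaining[0]] = 1
    for pos, feat in enumerate(reversed(eliminated)):
        ranking[feat] = pos + 2
    return {"elimination_order": eliminated, "ranking": ranking,
            "last_kept": remaining[0]}
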