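"""Leave-two-out cross-validation of candidate linear models.

Every one of the C(n, 2) splits holds out two plots, refits the model on
the remaining n - 2, and scores the squared error of the two held-out
predictions.  Two summaries are produced:

* ASS — the average, over splits, of the two-plot validation sum of
  squares; the predictive ranking criterion (smaller is better; its scale
  depends on the attribute's units).
* R^2_CV — a dimensionless leave-d-out predictive R^2: one minus the
  pooled squared prediction error over all n(n-1) held-out predictions
  divided by the pooled total sum of squares of the same observations
  (each y_i enters the pool n-1 times, so the denominator is
  (n-1) * sum_i (y_i - ybar)^2 with ybar the grand mean).  It ranges from
  -inf (worse than predicting the mean: over-fitted) to 1 (perfect).

Predictions and R^2_CV live on the transformed (log) scale; back-transformed
predictions are exposed for reporting on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


def l2o_splits(n: int) -> list[tuple[int, int]]:
    """All C(n, 2) leave-two-out validation pairs, lexicographic order."""
    if n < 4:
        raise ValueError("leave-two-out needs n >= 4")
    return list(combinations(range(n), 2))


@dataclass
class CVResult:
    response: str
    predictors: tuple[str, ...]
    n: int
    ass: float
    r2_cv: float
    predictions: pd.DataFrame  # split_id, plot index, observed, predicted
    excluded_splits: int
    scale: str = "transformed"


def cross_validate(X: np.ndarray, y: np.ndarray, predictors=None,
                   response: str = "y") -> CVResult:
    """Leave-two-out CV of the OLS model y ~ X (intercept included)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if not 1 <= k <= 3:
        raise ValueError("predictor set must have size 1-3")
    if n <= k + 2:
        raise ValueError("too few plots for leave-two-out with this model size")
    design = np.column_stack([np.ones(n), X])

    records = []
    excluded = 0
    for split_id, (i, j) in enumerate(l2o_splits(n)):
        keep = np.ones(n, dtype=bool)
        keep[[i, j]] = False
        A = design[keep]
        try:
            beta, _, rank, _ = np.linalg.lstsq(A, y[keep], rcond=None)
            if rank < A.shape[1]:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            excluded += 1
            continue
        for idx in (i, j):
            records.append({"split": split_id, "plot": idx,
                            "observed": y[idx],
                            "predicted": float(design[idx] @ beta)})
    preds = pd.DataFrame(records)
    err = preds["observed"] - preds["predicted"]
    per_split_ss = (err ** 2).groupby(preds["split"]).sum()
    ass = float(per_split_ss.mean())
    ybar = y.mean()
    denom = float(((preds["observed"] - ybar) ** 2).sum())
    r2_cv = 1.0 - float((err ** 2).sum()) / denom
    if predictors is None:
        predictors = tuple(f"x{c}" for c in range(k))
    return CVResult(response=response, predictors=tuple(predictors), n=n,
                    ass=ass, r2_cv=r2_cv, predictions=preds,
                    excluded_splits=excluded)


def back_transform(predictions: pd.Series, transform: str,
                   offset: float = 1.0) -> pd.Series:
    """Map transformed-scale predictions back to the attribute's scale."""
    if transform == "log":
        return np.exp(predictions)
    if transform == "log-offset":
        return np.exp(predictions) - offset
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-predictions))
    raise ValueError(f"unknown transform {transform!r}")


def select_predictive(results: list[CVResult]) -> CVResult:
    """Best predictive model: smallest ASS, ties by R^2_CV then name order."""
    if not results:
        raise ValueError("no CV results to select from")
    return min(results, key=lambda r: (r.ass, -r.r2_cv, r.predictors))


def cv_table(features: pd.DataFrame, responses: dict[str, np.ndarray],
             model_predictors: dict[tuple[str, int], tuple[str, ...]]) -> pd.DataFrame:
    """CV summary for chosen (attribute, size) -> predictor sets."""
    rows = []
    for (name, k), predictors in model_predictors.items():
        X = features[list(predictors)].to_numpy(dtype=float)
        res = cross_validate(X, np.asarray(responses[name], dtype=float),
                             predictors=predictors, response=name)
        rows.append({"attribute": name, "k": k,
                     "predictors": "+".join(predictors), "ASS": res.ass,
                     "R2_CV": res.r2_cv,
                     "excluded_splits": res.excluded_splits})
    return pd.DataFrame(rows)
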