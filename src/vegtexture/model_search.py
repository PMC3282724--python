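"""Exhaustive best-subset linear modeling of vegetation attributes.

Each (log-transformed) attribute is regressed on every subset of 1, 2 or 3
of the 40 texture variables — 560, 10,920 and 138,320 candidate models over
the 14 attributes.  Within a model size the best model is the one with the
largest R^2 (R^2 has a fixed 0-1 range, so it is comparable across
attributes, unlike AIC); across sizes the best models are compared with the
small-sample corrected AICc, treating a difference below 2 as "equally
good".

The search core precomputes the centered Gram matrix of the predictors, so
the R^2 of every candidate subset reduces to a batched k x k solve; this is
what makes 1,000-replicate permutation nulls over the full candidate set
affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


class TransformError(ValueError):
    pass


def transform_response(values, method: str = "log", offset: float = 1.0):
    """Transform an attribute vector before model fitting.

    ``log``: natural log (requires y > 0).  ``log-offset``: ln(y + offset)
    for attributes containing zeros.  ``logit``: ln(y / (1 - y)) for
    proportions in (0, 1) such as Simpson dominance.
    """
    y = np.asarray(values, dtype=float)
    if method == "log":
        if (y <= 0).any():
            bad = np.nonzero(y <= 0)[0]
            raise TransformError(
                f"log transform of non-positive value(s) at rows {bad.tolist()}; "
                "use method='log-offset'")
        return np.log(y)
    if method == "log-offset":
        if (y + offset <= 0).any():
            raise TransformError("log-offset still non-positive; raise offset")
        return np.log(y + offset)
    if method == "logit":
        if ((y <= 0) | (y >= 1)).any():
            bad = np.nonzero((y <= 0) | (y >= 1))[0]
            raise TransformError(f"logit requires values in (0,1); rows {bad.tolist()}")
        return np.log(y / (1.0 - y))
    raise ValueError(f"unknown transform {method!r}")


def enumerate_models(n_texture: int = 40, n_attributes: int = 14, k: int = 1):
    """Count and iterator over all (attribute index, predictor subset) pairs."""
    if not 1 <= k <= 3:
        raise ValueError("k must be 1, 2 or 3")
    count = n_attributes * comb(n_texture, k)

    def _iter():
        for a in range(n_attributes):
            for subset in combinations(range(n_texture), k):
                yield a, subset

    return count, _iter()


@dataclass
class ModelFit:
    """One fitted candidate: OLS of a transformed attribute on 1-3 predictors."""

    response: str
    transform: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    n: int
    r2: float
    rss: float
    aicc: float

    @property
    def k(self) -> int:
        return len(self.predictors)

    @property
    def signs(self) -> tuple[str, ...]:
        return tuple("+" if c > 0 else "-" for c in self.coefficients)


def aicc_from_rss(rss: float, n: int, k: int) -> float:
    """AICc of a least-squares fit; p = k + 2 counts slopes, intercept and
    the error variance."""
    p = k + 2
    if n - p - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)  # exact fits: keep the log finite
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def fit_ols(X: np.ndarray, y: np.ndarray, predictors=None, response: str = "y",
            transform: str = "log") -> ModelFit:
    """Ordinary least squares with intercept; R^2, RSS and AICc."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y):
        X = X.T
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if predictors is None:
        predictors = tuple(f"x{i}" for i in range(k))
    return ModelFit(response=response, transform=transform,
                    predictors=tuple(predictors), intercept=float(beta[0]),
                    coefficients=beta[1:], n=n, r2=r2, rss=rss,
                    aicc=aicc_from_rss(rss, n, k))


class ExhaustiveSearch:
    """All-subsets R^2 over a fixed predictor matrix.

    Centering the predictors once gives, for a subset S,
    R^2(S) = b_S' C_S^{-1} b_S / TSS with C the centered Gram matrix of X
    and b = Xc' yc.  C (and its subset inverses) depend only on X, so
    permutation replicates that reorder y cost one matrix-vector product
    plus a batched quadratic form.
    """

    def __init__(self, features: pd.DataFrame):
        cols = [c for c in features.columns if c != "plot_id"]
        self.feature_names = cols
        X = features[cols].to_numpy(dtype=float)
        self.n = X.shape[0]
        self.X = X
        self.Xc = X - X.mean(axis=0)
        self.C = self.Xc.T @ self.Xc
        self._combos: dict[int, np.ndarray] = {}
        self._Cinv: dict[int, np.ndarray] = {}

    def _prepare(self, k: int) -> None:
        if k in self._combos:
            return
        combos = np.array(list(combinations(range(len(self.feature_names)), k)))
        sub = self.C[combos[:, :, None], combos[:, None, :]]  # (m, k, k)
        self._combos[k] = combos
        self._Cinv[k] = np.linalg.inv(sub)

    def r2_all(self, y: np.ndarray, k: int) -> np.ndarray:
        """R^2 of every size-k candidate for one response vector."""
        self._prepare(k)
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss == 0:
            return np.zeros(len(self._combos[k]))
        b = self.Xc.T @ yc
        bs = b[self._combos[k]]  # (m, k)
        expl = np.einsum("mi,mij,mj->m", bs, self._Cinv[k], bs)
        return np.clip(expl / tss, 0.0, 1.0)

    def max_r2(self, y: np.ndarray, k: int) -> float:
        return float(self.r2_all(y, k).max())

    def best_subset(self, y: np.ndarray, k: int) -> tuple[tuple[str, ...], float]:
        """Best size-k subset by R^2; ties broken lexicographically by name
        (combinations are generated in lexicographic column order, and
        argmax takes the first maximum)."""
        r2 = self.r2_all(y, k)
        best = int(np.argmax(r2))
        names = tuple(self.feature_names[i] for i in self._combos[k][best])
        return names, float(r2[best])


@dataclass
class SearchResult:
    """Best model per size for one attribute, plus the cross-size verdict."""

    response: str
    best: dict[int, ModelFit]
    n_candidates: dict[int, int]
    equally_good: list[int] = field(default_factory=list)

    def resolve_verdict(self) -> None:
        best_aicc = min(m.aicc for m in self.best.values())
        self.equally_good = sorted(
            k for k, m in self.best.items() if m.aicc - best_aicc < 2.0)


def select_best(features: pd.DataFrame, y: np.ndarray, response: str,
                sizes=(1, 2, 3), transform: str = "log",
                search: ExhaustiveSearch | None = None) -> SearchResult:
    """Exhaustive search per model size; largest R^2 wins within a size,
    sizes within 2 AICc of the minimum are flagged equally good."""
    if search is None:
        search = ExhaustiveSearch(features)
    cols = search.feature_names
    best: dict[int, ModelFit] = {}
    n_candidates = {}
    for k in sizes:
        names, _ = search.best_subset(y, k)
        idx = [cols.index(nm) for nm in names]
        best[k] = fit_ols(search.X[:, idx], y, predictors=names,
                          response=response, transform=transform)
        n_candidates[k] = comb(len(cols), k)
    result = SearchResult(response=response, best=best, n_candidates=n_candidates)
    result.resolve_verdict()
    return result


def paired_t(x, y) -> tuple[float, float, int]:
    """Paired two-sided t test; returns (t, p, df)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = x - y
    m = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, m - 1
        return float(np.inf) * np.sign(d.mean()), 0.0, m - 1
    t = d.mean() / (sd / np.sqrt(m))
    p = 2 * stats.t.sf(abs(t), df=m - 1)
    return float(t), float(p), m - 1
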