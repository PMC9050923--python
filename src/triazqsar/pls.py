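"""Partial least squares modelling of pGI50 on field descriptors.

The descriptor matrix is wide and heavily collinear (thousands of grid
energies, tens of compounds), the textbook PLS setting: project onto a few
latent components maximizing covariance with the response, fit by NIPALS on
column-centered data.  The component count is picked by leave-one-out
cross-validated q2 on the training set (capped low, as is standard for CoMFA
models on ~20 compounds).  Model quality is summarized by the squared Pearson
correlation r2 between observed and predicted response and the root-mean-
square error of prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .activity import QsarDataset

__all__ = [
    "SplitAssignment",
    "PlsModel",
    "ModelReport",
    "diverse_split",
    "fit_pls",
    "loo_q2",
    "choose_components",
    "predict",
    "model_stats",
    "residual_table",
]


@dataclass
class SplitAssignment:
    train_ids: list[int]
    test_ids: list[int]
    method: str  # explicit | diverse
    seed: int | None = None

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class PlsModel:
    """Centered PLS1 fit: predict(X) = (X - x_mean) @ coefficients + y_mean."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    x_scores: np.ndarray = field(repr=False)
    x_weights: np.ndarray = field(repr=False)
    x_loadings: np.ndarray = field(repr=False)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)


@dataclass
class ModelReport:
    rows: list[dict]  # compound_id, experimental, predicted, residual, split
    r2_train: float
    rmse_train: float
    r2_test: float | None = None
    rmse_test: float | None = None
    r2_pooled: float | None = None
    rmse_pooled: float | None = None
    r2_ss_train: float | None = None
    n_components: int | None = None


def diverse_split(
    dataset: QsarDataset,
    n_test: int = 6,
    seed: int = 2020,
    explicit_test: Sequence[int] | None = None,
    X: np.ndarray | None = None,
) -> SplitAssignment:
    """19/6-style split: explicit membership, or greedy maximin in X-space.

    With ``explicit_test`` the ids are used verbatim (the published split).
    Otherwise test compounds are picked greedily to maximize the minimum
    pairwise Euclidean distance among them in descriptor space (seeded first
    pick), the standard diverse-subset heuristic for fresh series.
    """
    ids = dataset.ids
    if explicit_test is not None:
        missing = sorted(set(explicit_test) - set(ids))
        if missing:
            raise ValueError(f"explicit test ids not in dataset: {missing}")
        test = sorted(explicit_test)
        return SplitAssignment(
            train_ids=[i for i in ids if i not in set(test)],
            test_ids=test,
            method="explicit",
        )
    if not 0 <= n_test < len(ids):
        raise ValueError("n_test must be smaller than the dataset")
    if n_test == 0:
        return SplitAssignment(train_ids=list(ids), test_ids=[], method="diverse", seed=seed)
    if X is None:
        raise ValueError("descriptor matrix X required for the diverse split")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(ids)))]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    while len(chosen) < n_test:
        min_d = d[:, chosen].min(axis=1)
        min_d[chosen] = -np.inf
        chosen.append(int(np.argmax(min_d)))
    test = sorted(ids[i] for i in chosen)
    return SplitAssignment(
        train_ids=[i for i in ids if i not in set(test)],
        test_ids=test,
        method="diverse",
        seed=seed,
    )


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """NIPALS PLS1 on column-centered X and centered y (no scaling)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two training compounds")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, min(n-1={n-1}, p={p})]"
        )
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    coef = np.asarray(model.coef_).reshape(-1)
    # scale=False centering uses the plain column means
    return PlsModel(
        n_components=n_components,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        coefficients=coef,
        x_scores=model.x_scores_.copy(),
        x_weights=model.x_weights_.copy(),
        x_loadings=model.x_loadings_.copy(),
    )


def predict(model: PlsModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"column mismatch: model has {model.x_mean.shape[0]}, X has {X.shape[1]}"
        )
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> float:
    """Leave-one-out cross-validated predictive R^2 (q2).

    q2 = 1 - PRESS / SS_tot with PRESS from explicit refits on each n-1
    subset and SS_tot about the full-sample mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = fit_pls(X[mask], y[mask], n_components)
        press += float((predict(sub, X[i : i + 1])[0] - y[i]) ** 2)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def choose_components(X: np.ndarray, y: np.ndarray, max_components: int = 5) -> int:
    """Component count maximizing LOO q2; ties broken toward fewer."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    n, p = np.asarray(X).shape
    upper = min(max_components, n - 2, p)  # n-2: each LOO fold has n-1 samples
    upper = max(upper, 1)
    best_k, best_q2 = 1, -np.inf
    for k in range(1, upper + 1):
        q2 = loo_q2(X, y, k)
        if q2 > best_q2 + 1e-12:
            best_k, best_q2 = k, q2
    return best_k


def model_stats(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """(squared Pearson correlation, root-mean-square error)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(np.corrcoef(y, yhat)[0, 1])
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return r * r, rmse


def r2_explained(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - SS_res/SS_tot, the explained-variance form of R^2."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    return 1.0 - float(((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())


def residual_table(
    dataset: QsarDataset,
    split: SplitAssignment,
    model: PlsModel,
    X_by_id: dict[int, np.ndarray],
) -> ModelReport:
    """Per-compound experimental/predicted/residual rows plus summary stats."""
    rows: list[dict] = []
    y_map = dict(dataset.entries)
    for cid in dataset.ids:
        pred = float(predict(model, X_by_id[cid][None, :])[0])
        exp = y_map[cid]
        rows.append(
            {
                "compound_id": cid,
                "experimental_pgi50": exp,
                "predicted_pgi50": pred,
                "residual": exp - pred,
                "split": "test" if cid in set(split.test_ids) else "train",
            }
        )
    tr = [r for r in rows if r["split"] == "train"]
    te = [r for r in rows if r["split"] == "test"]
    y_tr = [r["experimental_pgi50"] for r in tr]
    p_tr = [r["predicted_pgi50"] for r in tr]
    r2_train, rmse_train = model_stats(y_tr, p_tr)
    report = ModelReport(
        rows=rows,
        r2_train=r2_train,
        rmse_train=rmse_train,
        r2_ss_train=r2_explained(y_tr, p_tr),
        n_components=model.n_components,
    )
    if len(te) >= 2:
        y_te = [r["experimental_pgi50"] for r in te]
        p_te = [r["predicted_pgi50"] for r in te]
        report.r2_test, report.rmse_test = model_stats(y_te, p_te)
        y_all = [r["experimental_pgi50"] for r in rows]
        p_all = [r["predicted_pgi50"] for r in rows]
        report.r2_pooled, report.rmse_pooled = model_stats(y_all, p_all)
    return report
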