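"""PLS1 regression with leave-one-out cross-validation.

The calibration core is a hand-written NIPALS PLS1 (single response)
with column mean-centering, presented statsmodels-style: build a
:class:`PLS1Model` from data, call :meth:`~PLS1Model.fit` and work with
the returned :class:`PLS1Results`.  :func:`loo_cv` wraps the model in
leave-one-out cross-validation, chooses the factor count that minimises
the mean absolute error of the held-out predictions (ties broken toward
fewer factors) and refits the chosen model on the full data.

For a single response, each NIPALS component is closed-form:

    w = X'y / ||X'y||        (weight)
    t = X w                  (score)
    p = X't / t't            (X loading)
    q = y't / t't            (y loading)

after which X and y are deflated by the rank-one fit.  The regression
vector in the original centered X space is b = W (P'W)^{-1} q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLS1Model",
    "PLS1Results",
    "CalibrationResult",
    "pls1_fit",
    "pls1_predict",
    "loo_cv",
    "choose_n_factors",
    "regression_metrics",
]


def choose_n_factors(mae_by_factors: np.ndarray) -> int:
    """Factor count with the lowest validation MAE; ties go to fewer factors."""
    mae_by_factors = np.asarray(mae_by_factors, dtype=float)
    if mae_by_factors.ndim != 1 or mae_by_factors.size == 0:
        raise ValueError("mae_by_factors must be a non-empty 1-D sequence")
    return int(np.argmin(mae_by_factors)) + 1  # argmin returns the first minimum


class PLS1Model:
    """PLS1 regression model for one response variable.

    Parameters
    ----------
    X : (n_samples, n_features) array
        Predictor matrix (e.g. second-derivative intensities at the
        selected band points).
    y : (n_samples,) array
        Response (analyte concentration).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape[0] != X.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if np.ptp(y) == 0:
            raise ValueError("response y is constant")
        self.X = X
        self.y = y

    @classmethod
    def from_dataframe(cls, df, response: str) -> "PLS1Model":
        """Build from a DataFrame: ``response`` column vs all others."""
        y = df[response].to_numpy(dtype=float)
        X = df.drop(columns=[response]).to_numpy(dtype=float)
        return cls(X, y)

    @property
    def max_rank(self) -> int:
        return min(self.X.shape[0] - 1, self.X.shape[1])

    def fit(self, n_components: int) -> "PLS1Results":
        """Fit by NIPALS with ``n_components`` latent variables."""
        if not 1 <= n_components <= self.max_rank:
            raise ValueError(
                f"n_components must be in [1, {self.max_rank}], "
                f"got {n_components}"
            )
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        Xc = self.X - x_mean
        yc = self.y - y_mean

        n_feat = self.X.shape[1]
        W = np.empty((n_feat, n_components))
        P = np.empty((n_feat, n_components))
        q = np.empty(n_components)
        T = np.empty((self.X.shape[0], n_components))
        Xd, yd = Xc.copy(), yc.copy()
        for a in range(n_components):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm <= np.finfo(float).eps * max(1.0, np.abs(Xd).max()):
                raise np.linalg.LinAlgError(
                    f"degenerate deflation: zero weight vector at component {a + 1}"
                )
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            p = Xd.T @ t / tt
            qa = float(yd @ t) / tt
            Xd -= np.outer(t, p)
            yd -= qa * t
            W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t

        coef = W @ np.linalg.solve(P.T @ W, q)
        return PLS1Results(
            model=self,
            n_components=n_components,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=W,
            x_loadings=P,
            y_loadings=q,
            scores=T,
            coefficients=coef,
        )


@dataclass
class PLS1Results:
    """Fitted PLS1 calibration."""

    model: PLS1Model
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (n_features, A) normalised NIPALS weights
    x_loadings: np.ndarray   # (n_features, A)
    y_loadings: np.ndarray   # (A,)
    scores: np.ndarray       # (n_samples, A), mutually orthogonal
    coefficients: np.ndarray  # regression vector in centered X space

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """yhat = y_mean + (X_new - x_mean) . b"""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} features, got {X_new.shape[1]}"
            )
        return self.y_mean + (X_new - self.x_mean) @ self.coefficients

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def rsquared(self) -> float:
        y = self.model.y
        return 1.0 - float(np.sum(self.resid**2) / np.sum((y - y.mean()) ** 2))


def pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLS1Results:
    """Functional wrapper: ``PLS1Model(X, y).fit(n_components)``."""
    return PLS1Model(X, y).fit(n_components)


def pls1_predict(results: PLS1Results, X_new: np.ndarray) -> np.ndarray:
    return results.predict(X_new)


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """r2 = 1 - SSE/SST, rmse and mae of a prediction set.

    With constant ``y_true`` the determination coefficient is undefined
    and reported as nan; rmse and mae are still returned.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length, size >= 2")
    err = y_true - y_pred
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = np.nan if sst == 0 else 1.0 - float(np.sum(err**2)) / sst
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
    }


@dataclass
class CalibrationResult:
    """LOO-validated PLS1 calibration for one analyte.

    ``mae_by_factors[a-1]`` is the LOO mean absolute error with ``a``
    latent factors; ``n_factors_chosen`` minimises it (smallest count on
    ties) and the final model is refit on the full data with that
    count.
    """

    model: PLS1Results
    loo_predictions: np.ndarray
    y_reference: np.ndarray
    n_factors_chosen: int
    mae_by_factors: np.ndarray
    r2_validation: float
    rmse: float
    mae: float
    groups: np.ndarray = field(default=None)  # type: ignore[assignment]

    def summary(self) -> str:
        lines = [
            "PLS1 calibration (leave-one-out validation)",
            "-" * 44,
            f"samples:            {self.y_reference.size}",
            f"features:           {self.model.x_mean.size}",
            f"factors chosen:     {self.n_factors_chosen} (min LOO MAE)",
            f"LOO R^2:            {self.r2_validation:.4f}",
            f"LOO RMSE:           {self.rmse:.4g}",
            f"LOO MAE:            {self.mae:.4g}",
            "MAE by factor count:",
        ]
        for a, m in enumerate(self.mae_by_factors, start=1):
            marker = "  <-- chosen" if a == self.n_factors_chosen else ""
            lines.append(f"  {a:2d}: {m:.4g}{marker}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_factors_chosen": int(self.n_factors_chosen),
            "r2_validation": float(self.r2_validation),
            "rmse": float(self.rmse),
            "mae": float(self.mae),
            "mae_by_factors": [float(m) for m in self.mae_by_factors],
        }


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int | None = None,
    groups: np.ndarray | None = None,
) -> CalibrationResult:
    """Leave-one-out cross-validated PLS1 with min-MAE factor choice.

    ``groups`` assigns each row to a hold-out unit: with per-spectrum
    validation every row is its own group; with per-sample validation
    all replicates of one physical sample share a group, so no replicate
    of the held-out sample leaks into the training folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if groups is None:
        groups = np.arange(X.shape[0])
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 3:
        raise ValueError(f"need >= 3 hold-out groups, got {uniq.size}")
    counts = np.array([(groups == g).sum() for g in uniq])
    cap = min(X.shape[0] - counts.max() - 1, X.shape[1])  # smallest training fold
    if max_components is None:
        max_components = min(10, uniq.size - 2, X.shape[1])
    if not 1 <= max_components <= cap:
        raise ValueError(
            f"max_components must be in [1, {cap}], got {max_components}"
        )

    preds = np.full((max_components, X.shape[0]), np.nan)
    for g in uniq:
        hold = groups == g
        train_model = PLS1Model(X[~hold], y[~hold])
        for a in range(1, max_components + 1):
            preds[a - 1, hold] = train_model.fit(a).predict(X[hold])

    mae_by_factors = np.abs(preds - y).mean(axis=1)
    n_chosen = choose_n_factors(mae_by_factors)
    loo_pred = preds[n_chosen - 1]
    metrics = regression_metrics(y, loo_pred)
    final = PLS1Model(X, y).fit(n_chosen)
    return CalibrationResult(
        model=final,
        loo_predictions=loo_pred,
        y_reference=y.copy(),
        n_factors_chosen=n_chosen,
        mae_by_factors=mae_by_factors,
        r2_validation=metrics["r2"],
        rmse=metrics["rmse"],
        mae=metrics["mae"],
        groups=groups.copy(),
    )
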