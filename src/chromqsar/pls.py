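"""Single-response PLS regression by NIPALS with leave-one-out validation.

For a single response the NIPALS weight vector has the closed form
w ∝ X'y, so each component is computed without inner iteration and the
fit is fully deterministic. Component count is selected by leave-one-out
cross-validation: each sample is held out, centering and block scaling
are recomputed on the remainder, the model is refit, and Q²(c) =
1 − PRESS(c)/SS_total is maximized (ties go to the smaller count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fields import DescriptorMatrix, FieldKind, preprocess_like

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls",
    "loo_cross_validate",
    "predict_activity",
    "field_contributions",
    "regression_stats",
    "external_q2",
]


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray   # (p, c)
    x_loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    x_scores: np.ndarray    # (n, c)
    coefficients: np.ndarray  # (p,), in the (centered/scaled) input space
    intercept: float
    x_means: np.ndarray
    y_mean: float
    training_meta: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coefficients.shape[0]:
            raise ValueError(
                f"column count mismatch: model has {self.coefficients.shape[0]}, got {X.shape[1]}"
            )
        return self.intercept + (X - self.x_means) @ self.coefficients + 0.0


@dataclass
class CVResult:
    q2_by_components: dict[int, float]
    press_by_components: dict[int, float]
    selected_components: int


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def fit_pls(X, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit single-response NIPALS PLS.

    ``X`` may be a :class:`DescriptorMatrix` or a plain array; centering is
    applied internally (idempotent for pre-centered input). The regression
    coefficients are reconstructed as B = W (P'W)⁻¹ q so that
    ``predict(X_train)`` reproduces the fitted values.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if len(y) != n:
        raise ValueError("X row count and y length disagree")
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples for {n_components} components")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")

    x_means = Xm.mean(axis=0)
    y_mean = float(y.mean())
    E = Xm - x_means
    f = y - y_mean
    x_scale = float(np.abs(E).max()) or 1.0

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for c in range(n_components):
        w = E.T @ f
        wn = float(np.linalg.norm(w))
        if wn < 1e-12 * x_scale * (float(np.abs(f).max()) + 1e-300) or wn == 0.0:
            raise ValueError(
                f"requested {n_components} components but X/y covariance is exhausted after {c}"
            )
        w /= wn
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-30:
            raise ValueError(f"degenerate score vector at component {c + 1} (rank exceeded)")
        pvec = (E.T @ t) / tt
        qc = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - qc * t
        W[:, c], P[:, c], q[c], T[:, c] = w, pvec, qc, t

    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean  # in centered coordinates; predict() re-centers X
    return PLSModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coefficients=coef,
        intercept=intercept,
        x_means=x_means,
        y_mean=y_mean,
    )


def predict_activity(model: PLSModel, X) -> np.ndarray:
    """Predicted activities ŷ = intercept + (X − x̄)·B."""
    return model.predict(_as_matrix(X))


def _loo_predictions(
    meta: list[tuple[FieldKind, int]],
    raw: np.ndarray,
    y: np.ndarray,
    max_components: int,
) -> np.ndarray:
    """LOO predictions for every component count, shape (n, max_components).

    NIPALS components are nested, so a single ``max_components`` fit per
    held-out sample yields predictions for every smaller count by
    truncating the deflation sequence.
    """
    n = raw.shape[0]
    preds = np.zeros((n, max_components))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_sub, mu, scales = preprocess_like(meta, raw[mask])
        model = fit_pls(x_sub, y[mask], max_components)
        x_new = raw[i] - mu
        x_new = x_new.copy()
        for kind, s in scales.items():
            idx = np.array([j for j, (k, _) in enumerate(meta) if k == kind])
            x_new[idx] /= s
        # walk the deflation sequence to accumulate per-component predictions
        e = x_new - model.x_means
        yhat = model.y_mean
        for c in range(max_components):
            t = float(e @ model.x_weights[:, c])
            yhat += model.y_loadings[c] * t
            e = e - t * model.x_loadings[:, c]
            preds[i, c] = yhat
    return preds


def loo_cross_validate(X: DescriptorMatrix, y: np.ndarray, max_components: int | None = None) -> CVResult:
    """Leave-one-out component selection.

    Centering and block scaling are recomputed on each training remainder
    (the column filter stays fixed). Q²(c) = 1 − PRESS(c)/Σ(y−ȳ)²;
    the selected count maximizes Q², ties broken toward fewer components.
    """
    if not isinstance(X, DescriptorMatrix):
        raise TypeError("loo_cross_validate expects a DescriptorMatrix")
    y = np.asarray(y, dtype=float).ravel()
    n = X.raw.shape[0]
    if n < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    if max_components is None:
        max_components = min(10, n - 2)
    if max_components >= n - 1:
        raise ValueError(f"max_components={max_components} must be < n−1={n - 1}")
    preds = _loo_predictions(X.column_meta, X.raw, y, max_components)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    press = {c + 1: float(np.sum((y - preds[:, c]) ** 2)) for c in range(max_components)}
    q2 = {c: 1.0 - p / ss_tot for c, p in press.items()}
    selected = min(q2, key=lambda c: (-q2[c], c))
    return CVResult(q2_by_components=q2, press_by_components=press, selected_components=selected)


def field_contributions(model: PLSModel, X: DescriptorMatrix) -> dict[FieldKind, float]:
    """Per-field contribution fractions Σ_j |b_j|·sd_j, normalized to 1."""
    sds = X.X.std(axis=0)
    raw_scores: dict[FieldKind, float] = {}
    for j, (kind, _) in enumerate(X.column_meta):
        raw_scores[kind] = raw_scores.get(kind, 0.0) + abs(float(model.coefficients[j])) * float(sds[j])
    total = sum(raw_scores.values())
    if total == 0.0:
        return {k: 1.0 / len(raw_scores) for k in raw_scores}
    return {k: v / total for k, v in raw_scores.items()}


def regression_stats(y_true, y_pred, r2_mode: str = "determination") -> tuple[float, float]:
    """R² and RMSE between observed and predicted activities.

    ``r2_mode="determination"`` gives 1 − SSres/SStot; ``"pearson"`` gives
    the squared Pearson correlation.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 entries")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined for constant y_true")
    if r2_mode == "determination":
        r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    elif r2_mode == "pearson":
        r2 = float(np.corrcoef(y_true, y_pred)[0, 1]) ** 2
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return r2, rmse


def external_q2(y_test, y_pred, y_train_mean: float) -> float:
    """External-test Q² = 1 − Σ(y_test − ŷ)² / Σ(y_test − ȳ_train)²."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    denom = float(np.sum((y_test - y_train_mean) ** 2))
    if denom == 0.0:
        raise ValueError("external Q² undefined: test activities equal the training mean")
    return 1.0 - float(np.sum((y_test - y_pred) ** 2)) / denom
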