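"""Predicting innate POR probability from ensemble PN activity.

The model is a single squashed linear unit: predicted POR for odor o is
``sigmoid(w . n_o + bias)`` where ``n_o`` holds each PN's mean spike count
during the chosen 4-s epoch (ON or OFF).  Weights are fitted by full-batch
gradient descent on the mean-squared error, the output unit guaranteeing
predictions in (0, 1).  The scalar "softmax" of the original formulation
is the logistic sigmoid, the only monotone squashing function with that
range for a single unit.

Exposed on top of the model: leave-one-odor-out cross-validation, shuffled
target controls, weight-consistency analysis across the per-fold models,
and PN-subsampling Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ValenceRegression",
    "ValenceRegressionResults",
    "LOOCVResult",
    "loocv_predict",
    "shuffled_control",
    "weight_analysis",
    "monte_carlo_pn_subsample",
]


def _auto_learning_rate(X: np.ndarray) -> float:
    """Step size scaled to the feature magnitude.

    Gradient descent on the sigmoid-MSE loss is stable for steps below
    roughly ``4 / E[|x|^2]`` (the loss curvature is bounded by about
    ``E[|x|^2] / 4``); for unit-scale 89-d features this evaluates to the
    conventional 0.05 default.
    """
    msq = float(np.mean(np.sum(X * X, axis=1))) + 1.0  # +1 for the bias input
    return 4.0 / msq


def _masked_gd(X, y, mask, learning_rate, maxiter, tol, patience):
    """Fit ``m`` sigmoid-linear models simultaneously by gradient descent.

    ``mask`` is (m, n_obs); model k trains on the rows where mask[k] is
    True.  Returns (W (m, p), b (m,), loss trace (iters, m), diverged (m,)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = mask.shape
    p = X.shape[1]
    W = np.zeros((m, p))
    b = np.zeros(m)
    n_train = mask.sum(axis=1)
    losses = []
    best = np.full(m, np.inf)
    bad_streak = np.zeros(m, dtype=int)
    prev = None
    for _ in range(maxiter):
        Z = W @ X.T + b[:, None]  # (m, n)
        P = expit(Z)
        E = (P - y[None, :]) * mask
        loss = (E * E).sum(axis=1) / n_train
        losses.append(loss)
        grad_core = 2.0 * E * P * (1.0 - P) / n_train[:, None]
        W -= learning_rate * (grad_core @ X)
        b -= learning_rate * grad_core.sum(axis=1)
        bad_streak = np.where(loss > best + 1e-15, bad_streak + 1, 0)
        best = np.minimum(best, loss)
        if prev is not None and np.all(np.abs(loss - prev) < tol):
            break
        prev = loss
    diverged = bad_streak >= patience
    return W, b, np.asarray(losses), diverged


class ValenceRegression:
    """Squashed linear regression from PN features to POR probability.

    Parameters
    ----------
    endog : array (n_odors,)
        Normalized POR scores, each in [0, 1].
    exog : array (n_odors, n_pns)
        Mean odor-evoked spike counts per PN.
    """

    def __init__(self, endog, exog, odor_ids=None, pn_ids=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.endog.ndim != 1:
            raise ValueError("endog must be 1-D and exog 2-D")
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog and exog disagree on the number of odors")
        if not np.isfinite(self.exog).all() or not np.isfinite(self.endog).all():
            raise ValueError("non-finite values in the design")
        if ((self.endog < 0) | (self.endog > 1)).any():
            raise ValueError("targets must lie in [0, 1]")
        if len(self.endog) < 2:
            raise ValueError("need at least two training odors")
        self.odor_ids = list(odor_ids) if odor_ids is not None else list(range(len(self.endog)))
        self.pn_ids = list(pn_ids) if pn_ids is not None else list(range(self.exog.shape[1]))

    def fit(
        self,
        learning_rate: float | str = "auto",
        maxiter: int = 10000,
        tol: float = 1e-10,
        patience: int = 200,
    ) -> "ValenceRegressionResults":
        lr = _auto_learning_rate(self.exog) if learning_rate == "auto" else float(learning_rate)
        mask = np.ones((1, len(self.endog)), dtype=bool)
        W, b, losses, diverged = _masked_gd(
            self.exog, self.endog, mask, lr, maxiter, tol, patience
        )
        if diverged[0]:
            warnings.warn("gradient descent diverged (loss increased persistently)", stacklevel=2)
        return ValenceRegressionResults(
            self, W[0], float(b[0]), losses[:, 0], bool(diverged[0]), lr
        )


@dataclass
class ValenceRegressionResults:
    """Fitted valence regressor: weights, bias and the loss trace."""

    model: ValenceRegression
    params: np.ndarray
    bias: float
    loss_trace: np.ndarray
    diverged: bool
    learning_rate: float

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return expit(X @ self.params + self.bias)

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def summary(self) -> str:
        pred = self.predict()
        lines = [
            "Valence regression (sigmoid-linear, gradient descent)",
            f"  odors: {len(self.model.endog)}   PNs: {len(self.params)}",
            f"  learning rate: {self.learning_rate:.3e}   iterations: {len(self.loss_trace)}",
            f"  final MSE: {self.final_loss:.5f}   diverged: {self.diverged}",
            f"  training R^2 (corr^2): {squared_correlation(pred, self.model.endog):.4f}",
            "  largest |weights|:",
        ]
        top = np.argsort(np.abs(self.params))[::-1][:5]
        for i in top:
            lines.append(f"    {self.model.pn_ids[i]}: {self.params[i]:+.5f}")
        return "\n".join(lines)


def squared_correlation(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LOOCVResult:
    """Leave-one-odor-out predictions and the per-fold weight vectors."""

    predictions: np.ndarray
    targets: np.ndarray
    weights: np.ndarray  # (n_odors, n_pns), row o trained with odor o held out
    biases: np.ndarray
    r_squared: float  # squared Pearson correlation (headline convention)
    r_squared_rss: float  # 1 - RSS/TSS alternative
    odor_ids: list = field(default_factory=list)

    @property
    def mse(self) -> float:
        return float(np.mean((self.predictions - self.targets) ** 2))


def loocv_predict(
    features,
    targets,
    odor_ids=None,
    learning_rate: float | str = "auto",
    maxiter: int = 10000,
    tol: float = 1e-10,
    patience: int = 200,
) -> LOOCVResult:
    """Leave-one-odor-out cross-validation of the valence regressor.

    One model per odor is trained on the remaining odors (all folds are
    descended simultaneously); the held-out odor's prediction comes from
    its own fold's model.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three odors for cross-validation")
    model = ValenceRegression(y, X, odor_ids)  # validates the design
    lr = _auto_learning_rate(X) if learning_rate == "auto" else float(learning_rate)
    mask = ~np.eye(n, dtype=bool)
    W, b, _, diverged = _masked_gd(X, y, mask, lr, maxiter, tol, patience)
    if diverged.any():
        warnings.warn(
            f"{int(diverged.sum())} of {n} folds diverged", stacklevel=2
        )
    preds = expit(np.einsum("op,op->o", W, X) + b)
    tss = ((y - y.mean()) ** 2).sum()
    rss = ((y - preds) ** 2).sum()
    return LOOCVResult(
        predictions=preds,
        targets=y,
        weights=W,
        biases=b,
        r_squared=squared_correlation(preds, y),
        r_squared_rss=float(1.0 - rss / tss) if tss > 0 else float("nan"),
        odor_ids=list(model.odor_ids),
    )


def shuffled_control(
    features, targets, seed: int, n_shuffles: int = 1, **fit_kwargs
) -> np.ndarray:
    """LOOCV predictions after randomly permuting the targets.

    Returns an (n_shuffles, n_odors) array of cross-validated predictions;
    with no neural-behavioral mapping left, predictions concentrate near
    the mean target.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(targets, dtype=float)
    out = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(y))
        out.append(loocv_predict(features, y[perm], **fit_kwargs).predictions)
    return np.asarray(out)


def weight_analysis(weights_on: np.ndarray, weights_off: np.ndarray) -> dict:
    """Pairwise Pearson correlations of per-fold weight vectors, within and
    across the ON/OFF epochs.

    Constant weight vectors are excluded (with a notice in the result).
    """
    def _valid(W):
        keep = np.ptp(W, axis=1) > 0
        return W[keep], int((~keep).sum())

    W_on, dropped_on = _valid(np.asarray(weights_on, dtype=float))
    W_off, dropped_off = _valid(np.asarray(weights_off, dtype=float))
    if W_on.shape[1] != W_off.shape[1]:
        raise ValueError("ON and OFF weight vectors must have equal length")
    allw = np.vstack([W_on, W_off])
    corr = np.corrcoef(allw)
    n_on = len(W_on)
    within_on = corr[:n_on, :n_on][np.triu_indices(n_on, k=1)]
    n_off = len(W_off)
    within_off = corr[n_on:, n_on:][np.triu_indices(n_off, k=1)]
    cross = corr[:n_on, n_on:].ravel()
    return {
        "correlation_matrix": corr,
        "within_on": within_on,
        "within_off": within_off,
        "cross": cross,
        "dropped_constant": dropped_on + dropped_off,
    }


def monte_carlo_pn_subsample(
    features, targets, n: int, n_sims: int = 100, seed: int | None = None, **fit_kwargs
) -> float:
    """Mean LOOCV mean-squared error over random PN subsets of size ``n``."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not 1 <= n <= X.shape[1]:
        raise ValueError("subset size must satisfy 1 <= n <= n_pns")
    rng = np.random.default_rng(seed)
    if n == X.shape[1]:
        return loocv_predict(X, y, **fit_kwargs).mse  # only one possible subset
    mses = []
    for _ in range(n_sims):
        cols = rng.choice(X.shape[1], size=n, replace=False)
        mses.append(loocv_predict(X[:, cols], y, **fit_kwargs).mse)
    return float(np.mean(mses))
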