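"""L1-regularized mapping from time-varying ensemble PN activity to
palp-opening-response dynamics.

For each conditioning paradigm the design concatenates, for the four
conditioning odorants, a 2 s baseline + 4 s ON + 4 s OFF segment sampled
at 10 Hz: X is (n_pns x 400) of trial-averaged spiking and y the 400-point
mean palp separation.  The fit minimizes

    (1 / 2T) * ||y - X'w - b||^2 + alpha * ||w||_1

with an unpenalized intercept — the scaling convention of the scikit-learn
lasso, whose ``alpha = 0.01`` is the pinned default.  The L1 penalty drives
about half the PN weights to exactly zero, the sparse readout the model is
after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from .datasets import PORTrace, SpikeDataset
from . import ephys

__all__ = [
    "PORDesign",
    "build_design",
    "PORLasso",
    "PORLassoResults",
    "kkt_residual",
    "weight_dissection",
]


@dataclass
class PORDesign:
    """Paired neural (X) and behavioral (y) time courses.

    X is (n_pns x T) with T = columns_per_odor * n_odors; stimulus onset
    falls at column ``baseline_columns`` of each odor segment.
    """

    X: np.ndarray
    y: np.ndarray
    odor_ids: list[str]
    pn_ids: list[str]
    columns_per_odor: int
    rate_hz: float
    baseline_columns: int

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[1] != len(self.y):
            raise ValueError("X and y disagree on the number of time points")
        if self.X.shape[1] != self.columns_per_odor * len(self.odor_ids):
            raise ValueError("column count must equal columns_per_odor * n_odors")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in the design")

    def odor_slice(self, odor_id: str) -> slice:
        j = self.odor_ids.index(odor_id)
        return slice(j * self.columns_per_odor, (j + 1) * self.columns_per_odor)


def _resample_trace(trace: PORTrace, rate_hz: float, baseline_s: float, total_s: float):
    """Block-average a palp trace from its native fps down to ``rate_hz``,
    aligned so the first sample sits ``baseline_s`` before stimulus onset."""
    block = int(round(trace.fps / rate_hz))
    start = trace.onset - int(round(baseline_s * trace.fps))
    n_frames = int(round(total_s * trace.fps))
    if start < 0 or start + n_frames > trace.n_frames:
        raise ValueError("trace does not cover the requested window")
    seg = trace.separation[start : start + n_frames]
    return seg.reshape(-1, block).mean(axis=1)


def build_design(
    dataset: SpikeDataset,
    traces: dict[str, list[PORTrace]],
    odor_ids: list[str] | None = None,
    rate_hz: float = 10.0,
    baseline_s: float = 2.0,
) -> PORDesign:
    """Assemble the regression design from spikes and POR traces.

    ``traces`` maps each odor to that cohort's test-phase traces, which are
    averaged across locusts before resampling to ``rate_hz``.
    """
    odor_ids = list(odor_ids) if odor_ids is not None else list(dataset.odor_ids)
    missing = [o for o in odor_ids if o not in dataset.odor_ids or o not in traces]
    if missing:
        raise ValueError(f"odors missing from spikes or traces: {missing}")
    w = dataset.window
    total_s = baseline_s + w.on + w.off
    bin_width = 1.0 / rate_hz
    cols = int(round(total_s * rate_hz))
    counts, _ = ephys.bin_spikes(dataset, bin_width, (-baseline_s, w.on + w.off))
    mean = counts.mean(axis=2)  # (pn, odor, bin)
    X = np.concatenate(
        [mean[:, dataset.odor_ids.index(o), :] for o in odor_ids], axis=1
    )
    y = np.concatenate(
        [
            np.mean([_resample_trace(t, rate_hz, baseline_s, total_s) for t in traces[o]], axis=0)
            for o in odor_ids
        ]
    )
    return PORDesign(
        X,
        y,
        odor_ids,
        list(dataset.pn_ids),
        columns_per_odor=cols,
        rate_hz=rate_hz,
        baseline_columns=int(round(baseline_s * rate_hz)),
    )


def kkt_residual(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, alpha: float) -> float:
    """Maximum violation of the lasso stationarity conditions.

    For the objective (1/2T)||y - X'w - b||^2 + alpha ||w||_1 the gradient
    g = (1/T) X (X'w + b - y) must satisfy g_j = -alpha*sign(w_j) where
    w_j != 0 and |g_j| <= alpha where w_j = 0 (intercept gradient must
    vanish).
    """
    T = len(y)
    r = X.T @ w + b - y
    g = X @ r / T
    active = w != 0
    viol = np.zeros_like(w)
    viol[active] = np.abs(g[active] + alpha * np.sign(w[active]))
    viol[~active] = np.clip(np.abs(g[~active]) - alpha, 0.0, None)
    return float(max(viol.max() if len(viol) else 0.0, abs(r.mean())))


class PORLasso:
    """Lasso model from a :class:`PORDesign`."""

    def __init__(self, design: PORDesign, alpha: float = 0.01):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.design = design
        self.alpha = alpha

    def fit(self, tol: float = 1e-8, max_iter: int = 100000) -> "PORLassoResults":
        est = Lasso(alpha=self.alpha, fit_intercept=True, tol=tol, max_iter=max_iter)
        est.fit(self.design.X.T, self.design.y)
        return PORLassoResults(self, est.coef_.copy(), float(est.intercept_))


@dataclass
class PORLassoResults:
    """Fitted sparse PN -> POR readout."""

    model: PORLasso
    params: np.ndarray
    intercept: float

    @property
    def design(self) -> PORDesign:
        return self.model.design

    def predict(self, design: PORDesign | None = None) -> np.ndarray:
        d = design if design is not None else self.design
        return d.X.T @ self.params + self.intercept

    def kkt_residual(self) -> float:
        d = self.design
        return kkt_residual(d.X, d.y, self.params, self.intercept, self.model.alpha)

    def per_odor_correlations(self, design: PORDesign | None = None) -> pd.DataFrame:
        """Pearson r between predicted and observed POR per odor segment,
        with a two-sided t-test on n-2 degrees of freedom."""
        d = design if design is not None else self.design
        yhat = self.predict(d)
        rows = []
        for odor in d.odor_ids:
            s = d.odor_slice(odor)
            a, b = yhat[s], d.y[s]
            n = s.stop - s.start
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append({"odor_id": odor, "r": np.nan, "p_value": np.nan, "df": n - 2})
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            df = n - 2
            tstat = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
            p = 2.0 * stats.t.sf(abs(tstat), df)
            rows.append({"odor_id": odor, "r": r, "p_value": float(p), "df": df})
        return pd.DataFrame(rows).set_index("odor_id")

    def whole_trace_correlation(self) -> float:
        yhat = self.predict()
        return float(np.corrcoef(yhat, self.design.y)[0, 1])

    def summary(self) -> str:
        w = self.params
        corr = self.per_odor_correlations()
        lines = [
            f"POR lasso (alpha={self.model.alpha})",
            f"  PNs: {len(w)}   time points: {len(self.design.y)}",
            f"  weights >0: {int((w > 0).sum())}   <0: {int((w < 0).sum())}"
            f"   =0: {int((w == 0).sum())}",
            f"  KKT residual: {self.kkt_residual():.2e}",
            "  per-odor prediction r:",
        ]
        for odor, row in corr.iterrows():
            lines.append(f"    {odor}: r={row.r:+.3f} (P={row.p_value:.2e})")
        return "\n".join(lines)


def weight_dissection(results: list[PORLassoResults]) -> dict:
    """Compare the per-paradigm lasso readouts PN by PN.

    Averages weights across the fitted models, assigns each PN to a
    positive / negative / zero group by its mean weight, reports pairwise
    weight-vector correlations, per-group mean firing time courses (from
    the first model's design) and, within each sign group, the per-odor
    correlation between mean ON-epoch firing rate and weight.
    """
    if not results:
        raise ValueError("need at least one fitted model")
    pn_ids = results[0].design.pn_ids
    for r in results[1:]:
        if r.design.pn_ids != pn_ids:
            raise ValueError("models disagree on PN ordering")
    W = np.vstack([r.params for r in results])
    mean_w = W.mean(axis=0)
    groups = np.where(mean_w > 0, "positive", np.where(mean_w < 0, "negative", "zero"))
    corr = np.corrcoef(W) if len(results) > 1 else np.ones((1, 1))
    d = results[0].design
    psth = {
        g: d.X[groups == g].mean(axis=0) if (groups == g).any() else np.zeros(d.X.shape[1])
        for g in ("positive", "negative")
    }
    b0 = d.baseline_columns
    on_cols = int(round(4.0 * d.rate_hz))
    rate_weight_corr = {}
    for g in ("positive", "negative"):
        sel = groups == g
        rate_weight_corr[g] = {}
        for odor in d.odor_ids:
            s = d.odor_slice(odor)
            rates = d.X[sel, s.start + b0 : s.start + b0 + on_cols].mean(axis=1)
            if sel.sum() < 3 or np.ptp(rates) == 0 or np.ptp(mean_w[sel]) == 0:
                rate_weight_corr[g][odor] = np.nan
            else:
                rate_weight_corr[g][odor] = float(np.corrcoef(rates, mean_w[sel])[0, 1])
    return {
        "mean_weights": mean_w,
        "groups": pd.Series(groups, index=pn_ids),
        "n_positive": int((mean_w > 0).sum()),
        "n_negative": int((mean_w < 0).sum()),
        "n_zero": int((mean_w == 0).sum()),
        "pairwise_weight_correlations": corr,
        "group_psth": psth,
        "rate_weight_correlations": rate_weight_corr,
    }
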