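"""Behavioral statistics: preference indices, valence classification,
resampling stability, POR-trace response detection and normalization.

The preference index of an odor is its normalized POR score (fraction of
locusts responding) minus the median normalized score across the panel, so
the median odor has index 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PORMatrix, PORTrace

__all__ = [
    "compute_scores",
    "ValenceCall",
    "classify_valence",
    "monte_carlo_locust_subsample",
    "detect_por_response",
    "normalize_trace_set",
    "linear_trend",
]

_SD_FLOOR = 1e-6


def compute_scores(matrix: PORMatrix) -> pd.DataFrame:
    """Per-odor total score, normalized score and preference index.

    total = column sum of the binary POR matrix; norm_score = total / number
    of locusts; preference_index = norm_score - median norm_score over odors.
    """
    totals = matrix.responses.sum(axis=0)
    norm = totals / matrix.n_locusts
    pref = norm - np.median(norm)
    return pd.DataFrame(
        {"total": totals, "norm_score": norm, "preference_index": pref},
        index=pd.Index(matrix.odor_ids, name="odor_id"),
    )


@dataclass(frozen=True)
class ValenceCall:
    odor_id: str
    valence_class: str  # appetitive | neutral | unappetitive
    p_value: float  # the one-sided tail that decided the call (min of the two)


def classify_valence(
    matrix: PORMatrix, alpha: float = 0.1, null_probability: float | None = None
) -> list[ValenceCall]:
    """Classify each odor by a one-sided exact binomial test.

    The observed total POR count of each odor is tested against a binomial
    null with success probability equal to the median normalized score
    across odors (or ``null_probability`` if given).  Appetitive if the
    upper tail P(X >= total) < alpha, unappetitive if the lower tail
    P(X <= total) < alpha, otherwise neutral.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    scores = compute_scores(matrix)
    p0 = float(np.median(scores["norm_score"])) if null_probability is None else null_probability
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("null probability must lie in [0, 1]")
    n = matrix.n_locusts
    calls = []
    for odor, total in scores["total"].items():
        total = int(total)
        upper = float(stats.binom.sf(total - 1, n, p0))  # P(X >= total)
        lower = float(stats.binom.cdf(total, n, p0))  # P(X <= total)
        if upper < alpha:
            cls = "appetitive"
        elif lower < alpha:
            cls = "unappetitive"
        else:
            cls = "neutral"
        calls.append(ValenceCall(str(odor), cls, min(upper, lower)))
    return calls


def monte_carlo_locust_subsample(
    matrix: PORMatrix, n: int, n_sims: int = 100, seed: int | None = None
) -> tuple[float, float]:
    """Stability of preference indices under locust subsampling.

    Draws ``n`` locusts without replacement ``n_sims`` times; each draw's
    preference indices are Pearson-correlated with the full-sample indices.
    Returns (mean, s.e.m.) of the squared correlation across draws.  Draws
    whose subset indices are constant (correlation undefined) are excluded.
    """
    if not 1 <= n <= matrix.n_locusts:
        raise ValueError("subset size must satisfy 1 <= n <= n_locusts")
    if n == matrix.n_locusts:
        return 1.0, 0.0  # every draw is the full sample: r identically 1
    rng = np.random.default_rng(seed)
    full = compute_scores(matrix)["preference_index"].to_numpy()
    r2 = []
    for _ in range(n_sims):
        idx = rng.choice(matrix.n_locusts, size=n, replace=False)
        sub = compute_scores(matrix.subset(idx))["preference_index"].to_numpy()
        if np.ptp(sub) == 0 or np.ptp(full) == 0:
            continue
        r = np.corrcoef(sub, full)[0, 1]
        r2.append(r * r)
    if not r2:
        return float("nan"), float("nan")
    r2 = np.asarray(r2)
    sem = r2.std(ddof=1) / np.sqrt(len(r2)) if len(r2) > 1 else 0.0
    return float(r2.mean()), float(sem)


def detect_por_response(
    trace: PORTrace,
    sd_threshold: float = 6.5,
    min_frames: int = 30,
    separation_gate: float = 1.5,
    post_offset_window_s: float = 4.0,
    contiguous: bool = False,
) -> bool:
    """Did this trace contain a palp-opening response?

    True iff at least ``min_frames`` frames between stimulus onset and
    ``post_offset_window_s`` after offset exceed the pre-stimulus baseline
    mean by ``sd_threshold`` baseline standard deviations *and* exceed the
    absolute ``separation_gate`` (the tracking noise floor).  Frames need
    not be contiguous unless ``contiguous`` is set.
    """
    baseline_frames = int(round(2.0 * trace.fps))
    if trace.onset < baseline_frames:
        raise ValueError("trace must cover at least 2 s before stimulus onset")
    baseline = trace.separation[trace.onset - baseline_frames : trace.onset]
    mu, sd = baseline.mean(), max(baseline.std(), _SD_FLOOR)
    end = min(len(trace.separation), trace.offset + int(round(post_offset_window_s * trace.fps)))
    window = trace.separation[trace.onset : end]
    hits = (window > mu + sd_threshold * sd) & (window > separation_gate)
    if not contiguous:
        return int(hits.sum()) >= min_frames
    # longest run of consecutive hit frames
    best = run = 0
    for h in hits:
        run = run + 1 if h else 0
        best = max(best, run)
    return best >= min_frames


def normalize_trace_set(traces: list[PORTrace]) -> tuple[list[PORTrace], bool]:
    """Rescale one locust's traces to [0, 1] using its global min/max
    across all test odors.  Returns (normalized traces, flat_flag); a flat
    trace set (zero range) maps to all zeros with the flag set.
    """
    if not traces:
        raise ValueError("need at least one trace")
    lo = min(t.separation.min() for t in traces)
    hi = max(t.separation.max() for t in traces)
    flat = hi == lo
    out = []
    for t in traces:
        sep = np.zeros_like(t.separation) if flat else (t.separation - lo) / (hi - lo)
        out.append(PORTrace(sep, t.onset, t.offset, t.locust_id, t.odor_id, t.fps))
    return out, flat


def linear_trend(x, y) -> dict:
    """Ordinary least-squares line fit; returns slope, intercept and R^2
    (1 - RSS/TSS)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if tss == 0 else 1.0 - ((y - yhat) ** 2).sum() / tss
    return {"slope": float(res.slope), "intercept": float(res.intercept), "r_squared": float(r2)}
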