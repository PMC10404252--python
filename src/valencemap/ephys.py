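"""Spike-train processing: consistency filtering, binning, ON/OFF/inhibited
response classification, tuning/valence summaries, and the delta-RMS
preprocessing chain for behaving-locust multiunit recordings.

Response classification follows a per-trial criterion: a trial is
ON-positive if any 50-ms bin in the ON window exceeds that trial's
pre-stimulus baseline mean by 6.5 baseline standard deviations, and a
(PN, odor) pair is ON-responsive if at least half of its trials are
positive (5 of 10 at the recorded trial count).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .datasets import BinnedResponseMatrix, SpikeDataset

__all__ = [
    "filter_consistent_pns",
    "bin_spikes",
    "binned_response_matrix",
    "classify_pn_response",
    "classify_all",
    "mean_epoch_response",
    "tuning_and_valence_stats",
    "rms_preprocess",
]

_SD_FLOOR = 1e-6


def filter_consistent_pns(
    dataset: SpikeDataset, baseline_window: float = 4.0, threshold: float = 0.15
) -> list[str]:
    """PNs whose baseline firing never drops below ``threshold`` times their
    own maximum baseline rate, across every trial of every odor.

    The baseline rate is counted over ``baseline_window`` seconds before
    stimulus onset (clipped, with a warning, to the recorded pre-stimulus
    span).
    """
    avail = dataset.window.baseline
    w = min(baseline_window, avail)
    if w < baseline_window:
        warnings.warn(
            f"baseline window clipped to the available {avail:g} s of pre-stimulus data",
            stacklevel=2,
        )
    if w <= 0:
        raise ValueError("no pre-stimulus baseline available")
    kept = []
    for pn in dataset.pn_ids:
        rates = []
        for odor in dataset.odor_ids:
            for trial in range(dataset.n_trials):
                t = dataset.spike_times(pn, odor, trial)
                rates.append(np.count_nonzero((t >= -w) & (t < 0)) / w)
        rates = np.asarray(rates)
        if rates.min() >= threshold * rates.max():
            kept.append(pn)
    return kept


def bin_spikes(
    dataset: SpikeDataset, bin_width: float, interval: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bin spike counts into half-open bins ``[t, t + width)``.

    Returns ``(counts, edges)`` with counts shaped
    (n_pns, n_odors, n_trials, n_bins).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if interval is None:
        interval = (dataset.window.t_start, dataset.window.t_end)
    t0, t1 = interval
    n_bins = int(round((t1 - t0) / bin_width))
    if abs(n_bins * bin_width - (t1 - t0)) > 1e-9:
        raise ValueError("bin width must evenly divide the window length")
    counts = np.zeros((dataset.n_pns, dataset.n_odors, dataset.n_trials, n_bins))
    for i, pn in enumerate(dataset.pn_ids):
        for j, odor in enumerate(dataset.odor_ids):
            for k in range(dataset.n_trials):
                t = dataset.spike_times(pn, odor, k)
                t = t[(t >= t0) & (t < t1)]
                if len(t):
                    idx = np.floor((t - t0) / bin_width).astype(int)
                    np.clip(idx, 0, n_bins - 1, out=idx)
                    counts[i, j, k] = np.bincount(idx, minlength=n_bins)
    edges = t0 + bin_width * np.arange(n_bins + 1)
    return counts, edges


def binned_response_matrix(
    dataset: SpikeDataset, bin_width: float = 0.05, interval: tuple[float, float] | None = None
) -> BinnedResponseMatrix:
    """Trial-averaged PN x (odors * bins) matrix, odor segments concatenated."""
    if interval is None:
        interval = (dataset.window.t_start, dataset.window.t_end)
    counts, _ = bin_spikes(dataset, bin_width, interval)
    mean = counts.mean(axis=2)  # (pn, odor, bin)
    data = mean.reshape(dataset.n_pns, -1)
    return BinnedResponseMatrix(
        data, bin_width, list(dataset.pn_ids), list(dataset.odor_ids), interval[0], dataset.window
    )


def _trial_flags(counts_pair: np.ndarray, edges: np.ndarray, window, sd_threshold: float,
                 pooled_baseline: bool):
    """Per-trial ON/OFF/inhibited booleans for one (PN, odor) count block
    shaped (n_trials, n_bins)."""
    left = edges[:-1]
    base = (left >= -2.0 - 1e-9) & (left < -1e-9)
    on = (left >= -1e-9) & (left < window.on - 1e-9)
    off = (left >= window.on - 1e-9) & (left < window.on + window.off - 1e-9)
    b = counts_pair[:, base]
    if pooled_baseline:
        mu = np.full(len(counts_pair), b.mean())
        sd = np.full(len(counts_pair), max(b.std(), _SD_FLOOR))
    else:
        mu = b.mean(axis=1)
        sd = np.maximum(b.std(axis=1), _SD_FLOOR)
    hi = mu + sd_threshold * sd
    on_pos = (counts_pair[:, on] > hi[:, None]).any(axis=1)
    off_pos = (counts_pair[:, off] > hi[:, None]).any(axis=1)
    quiet = ~(counts_pair[:, on] > (mu + 2.0 * sd)[:, None]).any(axis=1)
    inh_pos = quiet & (counts_pair[:, on].mean(axis=1) < mu)
    return on_pos, off_pos, inh_pos


def classify_all(
    dataset: SpikeDataset,
    bin_width: float = 0.05,
    sd_threshold: float = 6.5,
    pooled_baseline: bool = False,
) -> pd.DataFrame:
    """Classify every (PN, odor) pair as ON / OFF / inhibited / none.

    Precedence when several criteria are met is ON > OFF > inhibited.
    Returns a tidy frame with per-trial positive counts.
    """
    counts, edges = bin_spikes(dataset, bin_width)
    need = int(np.ceil(dataset.n_trials / 2))
    rows = []
    for i, pn in enumerate(dataset.pn_ids):
        for j, odor in enumerate(dataset.odor_ids):
            on_pos, off_pos, inh_pos = _trial_flags(
                counts[i, j], edges, dataset.window, sd_threshold, pooled_baseline
            )
            n_on, n_off, n_inh = int(on_pos.sum()), int(off_pos.sum()), int(inh_pos.sum())
            if n_on >= need:
                label = "ON"
            elif n_off >= need:
                label = "OFF"
            elif n_inh >= need:
                label = "inhibited"
            else:
                label = "none"
            rows.append((pn, odor, label, n_on, n_off, n_inh))
    return pd.DataFrame(
        rows, columns=["pn_id", "odor_id", "label", "n_on_trials", "n_off_trials", "n_inh_trials"]
    )


def classify_pn_response(
    dataset: SpikeDataset,
    pn: str,
    odor: str,
    bin_width: float = 0.05,
    sd_threshold: float = 6.5,
    pooled_baseline: bool = False,
) -> str:
    """Label a single (PN, odor) pair; see :func:`classify_all`."""
    sub = dataset.subset_pns([pn])
    table = classify_all(sub, bin_width, sd_threshold, pooled_baseline)
    row = table[(table.pn_id == pn) & (table.odor_id == odor)]
    if row.empty:
        raise KeyError(f"no data for ({pn}, {odor})")
    return row.label.iloc[0]


def mean_epoch_response(dataset: SpikeDataset, interval: tuple[float, float]) -> pd.DataFrame:
    """Trial-averaged spike count per (PN, odor) inside ``interval``."""
    t0, t1 = interval
    out = np.zeros((dataset.n_pns, dataset.n_odors))
    for i, pn in enumerate(dataset.pn_ids):
        for j, odor in enumerate(dataset.odor_ids):
            c = [
                np.count_nonzero(
                    (dataset.spike_times(pn, odor, k) >= t0)
                    & (dataset.spike_times(pn, odor, k) < t1)
                )
                for k in range(dataset.n_trials)
            ]
            out[i, j] = np.mean(c)
    return pd.DataFrame(out, index=dataset.pn_ids, columns=dataset.odor_ids)


def tuning_and_valence_stats(
    classifications: pd.DataFrame,
    mean_on: pd.DataFrame,
    mean_off: pd.DataFrame,
    preference_index: pd.Series,
) -> pd.DataFrame:
    """Per-PN tuning breadth and correlation with the behavioral preference.

    ``mean_on``/``mean_off`` are PN x odor trial-averaged responses;
    correlations of a constant response vector are reported as NaN.
    """
    odors = list(preference_index.index)
    if set(odors) != set(mean_on.columns) or set(odors) != set(mean_off.columns):
        raise ValueError("response matrices and preference indices must cover identical odors")
    pref = preference_index.loc[odors].to_numpy(dtype=float)
    counts = (
        classifications.assign(
            is_on=classifications.label == "ON", is_off=classifications.label == "OFF"
        )
        .groupby("pn_id")[["is_on", "is_off"]]
        .sum()
    )
    rows = []
    for pn in mean_on.index:
        r = {}
        for name, mat in (("r_on", mean_on), ("r_off", mean_off)):
            v = mat.loc[pn, odors].to_numpy(dtype=float)
            r[name] = np.nan if np.ptp(v) == 0 else float(np.corrcoef(v, pref)[0, 1])
        rows.append(
            {
                "pn_id": pn,
                "n_on_odors": int(counts.loc[pn, "is_on"]) if pn in counts.index else 0,
                "n_off_odors": int(counts.loc[pn, "is_off"]) if pn in counts.index else 0,
                **r,
            }
        )
    return pd.DataFrame(rows).set_index("pn_id")


def rms_preprocess(
    raw: np.ndarray,
    fs: float = 15000.0,
    onset_s: float | None = None,
    band: tuple[float, float] = (300.0, 6000.0),
    clip_sd: float = 5.0,
    rms_window_s: float = 0.02,
    downsample1: int = 150,
    smooth_points: int = 10,
    downsample2: int = 5,
    baseline_s: float = 1.0,
    clip: bool = True,
) -> np.ndarray:
    """Delta-RMS firing-activity proxy from raw multiunit voltage.

    Chain: 4th-order zero-phase Butterworth band-pass (300-6000 Hz) ->
    clip samples beyond +/- ``clip_sd`` baseline s.d. -> moving RMS with a
    20 ms window -> downsample x150 -> 10-point moving average ->
    downsample x5 -> subtract the mean of the 1 s pre-stimulus baseline.
    Output rate is ``fs / (downsample1 * downsample2)`` (20 Hz at 15 kHz).
    """
    raw = np.asarray(raw, dtype=float)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    warmup = 3 * 2 * 4  # conservative filtfilt pad length for a 4th-order sos
    if raw.ndim != 1 or len(raw) <= max(warmup * 3, downsample1 * downsample2):
        raise ValueError("trace too short for the filter chain")
    x = signal.sosfiltfilt(sos, raw)
    onset_idx = len(x) if onset_s is None else int(round(onset_s * fs))
    if clip:
        base = x[:onset_idx]
        sd = base.std()
        if sd > 0:
            x = np.clip(x, -clip_sd * sd, clip_sd * sd)
    rms = np.sqrt(uniform_filter1d(x**2, size=max(int(round(rms_window_s * fs)), 1)))
    y = rms[::downsample1]
    y = uniform_filter1d(y, size=smooth_points)
    y = y[::downsample2]
    out_fs = fs / (downsample1 * downsample2)
    if onset_s is None:
        base_mean = y.mean()
    else:
        k = int(round(onset_s * out_fs))
        nb = int(round(baseline_s * out_fs))
        base_mean = y[max(k - nb, 0) : k].mean() if k > 0 else 0.0
    return y - base_mean
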