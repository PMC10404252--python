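"""Neuron/anti-neuron conditioning model.

Two decoding units read out the full PN ensemble: DN1 drives the
palp-opening response and DN2 suppresses it.  Both weight vectors are
initialized as least-squares decoders of binary valence targets over the
concatenated time bins of the four conditioning odorants,

    W1 = (X X')^-1 X Y1',    W2 = (X X')^-1 X Y2',

where Y1 marks the presentation bins of the appetitive odorants (hexanol,
isoamyl acetate) and Y2 those of the non-appetitive ones (benzaldehyde,
citral).  DN1's threshold sits just above its maximum pre-learning drive
(no POR before conditioning); DN2's is the half-maximum of its drive.
Conditioning applies a reward-gated Hebbian step, delta = 0.25, to the W1
entries of ensemble-1 PNs that respond to the conditioned odor; all other
connections are frozen.  The behavioral readout is
POR(t) = max(DN1(t) - DN2(t), 0) with DN_i(t) = max(x(t)'W_i - theta_i, 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datasets import BinnedResponseMatrix

__all__ = [
    "HebbianNetwork",
    "partition_ensembles",
    "on_responsive_masks",
    "peak_responsive_masks",
]

_SD_FLOOR = 1e-6


def peak_responsive_masks(X: BinnedResponseMatrix, sd_threshold: float = 6.5) -> dict:
    """ON-responsive mask per odor from trial-averaged binned activity.

    A PN counts as responding to an odor if its peak odor-evoked activity
    (any ON-window bin of the trial-averaged matrix) exceeds its
    pre-stimulus baseline mean by ``sd_threshold`` baseline standard
    deviations.
    """
    base = X.segment_mask((X.t_start, 0.0))
    on = X.segment_mask(X.window.on_interval())
    masks = {}
    b = X.bins_per_odor
    for j, odor in enumerate(X.odor_ids):
        seg = X.data[:, j * b : (j + 1) * b]
        mu = seg[:, base].mean(axis=1)
        sd = np.maximum(seg[:, base].std(axis=1), _SD_FLOOR)
        masks[odor] = seg[:, on].max(axis=1) > mu + sd_threshold * sd
    return masks


def partition_ensembles(mean_hex, mean_bza) -> np.ndarray:
    """Split PNs into two near-equal groups by odor preference.

    Returns a boolean mask, True for ensemble 1 (PNs responding more to the
    appetitive conditioning odor than to the non-appetitive one).  Ties are
    assigned to whichever group is currently smaller.
    """
    hex_r = np.asarray(mean_hex, dtype=float)
    bza_r = np.asarray(mean_bza, dtype=float)
    mask = hex_r > bza_r
    for i in np.flatnonzero(hex_r == bza_r):
        mask[i] = mask.sum() < (len(mask) - mask.sum())
    if mask.all() or not mask.any():
        warnings.warn("degenerate ensemble partition: every PN prefers one odor", stacklevel=2)
    return mask


def on_responsive_masks(
    classifications: pd.DataFrame, pn_ids: list[str], odor_ids: list[str]
) -> dict[str, np.ndarray]:
    """Boolean ON-responsive mask per odor from an ephys classification table."""
    masks = {}
    for odor in odor_ids:
        sub = classifications[
            (classifications.odor_id == odor) & (classifications.label == "ON")
        ]
        hot = set(sub.pn_id)
        masks[odor] = np.array([pn in hot for pn in pn_ids])
    return masks


class HebbianNetwork:
    """The conditioning network over a four-odor binned response matrix.

    Parameters
    ----------
    X : BinnedResponseMatrix
        Trial-averaged 50-ms binned activity whose odor segments cover
        baseline, ON and OFF windows of the four conditioning odorants.
    appetitive_odors, nonappetitive_odors : pairs of odor ids in ``X``.
    responsive : mapping odor id -> boolean PN mask (ON-responsive).
    ensemble_mask : boolean PN mask, True for encoding ensemble 1.
    delta : Hebbian learning rate.
    epsilon : headroom of DN1's threshold above its pre-learning maximum
        (default 0.45: large enough that post-learning baseline drive of the
        potentiated ensemble stays subthreshold, small enough that
        conditioned-odor drive crosses).
    theta2_mode : "global" (half of the overall max drive) or "per_odor"
        (half of the smallest per-odor maximum among the non-appetitive
        odors).
    """

    def __init__(
        self,
        X: BinnedResponseMatrix,
        appetitive_odors: tuple[str, str],
        nonappetitive_odors: tuple[str, str],
        responsive: dict[str, np.ndarray],
        ensemble_mask: np.ndarray,
        delta: float = 0.25,
        epsilon: float = 0.45,
        theta2_mode: str = "global",
    ):
        if delta < 0:
            raise ValueError("learning rate must be non-negative")
        for o in (*appetitive_odors, *nonappetitive_odors):
            if o not in X.odor_ids:
                raise ValueError(f"odor {o!r} not in the response matrix")
        self.X = X
        self.appetitive_odors = tuple(appetitive_odors)
        self.nonappetitive_odors = tuple(nonappetitive_odors)
        self.responsive = {k: np.asarray(v, dtype=bool) for k, v in responsive.items()}
        self.ensemble_mask = np.asarray(ensemble_mask, dtype=bool)
        if len(self.ensemble_mask) != X.n_pns:
            raise ValueError("ensemble mask length must equal the number of PNs")
        self.delta = float(delta)
        self.epsilon = float(epsilon)

        data = X.data
        Y1 = self._target_vector(self.appetitive_odors)
        Y2 = self._target_vector(self.nonappetitive_odors)
        self.Y1, self.Y2 = Y1, Y2
        G = data @ data.T
        try:
            self.W1 = np.linalg.solve(G, data @ Y1)
            self.W2 = np.linalg.solve(G, data @ Y2)
        except np.linalg.LinAlgError:
            lam = 1e-8 * np.trace(G) / G.shape[0]
            warnings.warn("singular X X'; using ridge-stabilized pseudoinverse", stacklevel=2)
            Greg = G + lam * np.eye(G.shape[0])
            self.W1 = np.linalg.solve(Greg, data @ Y1)
            self.W2 = np.linalg.solve(Greg, data @ Y2)
        drive1 = data.T @ self.W1
        drive2 = data.T @ self.W2
        self.theta1 = (1.0 + self.epsilon) * drive1.max()
        if theta2_mode == "global":
            self.theta2 = 0.5 * drive2.max()
        elif theta2_mode == "per_odor":
            per_max = [
                drive2[self._segment_index(o)].max() for o in self.nonappetitive_odors
            ]
            self.theta2 = 0.5 * min(per_max)
        else:
            raise ValueError("theta2_mode must be 'global' or 'per_odor'")

    # -- construction helpers -------------------------------------------------

    def _segment_index(self, odor: str) -> np.ndarray:
        j = self.X.odor_ids.index(odor)
        b = self.X.bins_per_odor
        return np.arange(j * b, (j + 1) * b)

    def _on_bins(self, odor: str) -> np.ndarray:
        seg = self._segment_index(odor)
        return seg[self.X.segment_mask(self.X.window.on_interval())]

    def _target_vector(self, odors) -> np.ndarray:
        y = np.zeros(self.X.data.shape[1])
        for o in odors:
            y[self._on_bins(o)] = 1.0
        return y

    @classmethod
    def from_dataset(
        cls,
        dataset,
        appetitive_odors: tuple[str, str],
        nonappetitive_odors: tuple[str, str],
        bin_width: float = 0.05,
        delta: float = 0.25,
        epsilon: float = 0.45,
        theta2_mode: str = "global",
    ) -> "HebbianNetwork":
        """Build the network from spike data: bins the four conditioning
        odors, finds ON responders by the peak-activity criterion, and
        partitions the ensembles by hexanol-vs-benzaldehyde preference."""
        from . import ephys

        odor_ids = [*appetitive_odors, *nonappetitive_odors]
        sub = {o for o in odor_ids}
        spikes = {
            k: dataset.spike_times(*k)
            for k in (
                (pn, o, t)
                for pn in dataset.pn_ids
                for o in dataset.odor_ids
                if o in sub
                for t in range(dataset.n_trials)
            )
        }
        from .datasets import SpikeDataset

        ds4 = SpikeDataset(spikes, dataset.window, dataset.panel)
        Xfull = ephys.binned_response_matrix(ds4, bin_width)
        # reorder segments into the requested odor order
        data = np.concatenate([Xfull.odor_segment(o) for o in odor_ids], axis=1)
        X = BinnedResponseMatrix(
            data, bin_width, list(ds4.pn_ids), odor_ids, Xfull.t_start, ds4.window
        )
        responsive = peak_responsive_masks(X)
        on_mean = ephys.mean_epoch_response(ds4, ds4.window.on_interval())
        mask = partition_ensembles(
            on_mean[appetitive_odors[0]].loc[X.pn_ids],
            on_mean[nonappetitive_odors[0]].loc[X.pn_ids],
        )
        return cls(
            X,
            appetitive_odors,
            nonappetitive_odors,
            responsive,
            mask,
            delta=delta,
            epsilon=epsilon,
            theta2_mode=theta2_mode,
        )

    # -- learning and readout -------------------------------------------------

    def hebbian_update(self, conditioned_odor: str, n_sessions: int = 1) -> np.ndarray:
        """Reward-gated Hebbian step on W1.

        W1 <- W1 + delta * (mean reward-bin activity elementwise-masked by
        ensemble-1 PNs responsive to the conditioned odor); W2 and both
        thresholds are frozen.  Returns the updated W1.
        """
        if conditioned_odor not in (*self.appetitive_odors, *self.nonappetitive_odors):
            raise ValueError(f"unknown conditioning odor {conditioned_odor!r}")
        reward_bins = self._on_bins(conditioned_odor)
        xbar = self.X.data[:, reward_bins].mean(axis=1)
        mask = self.ensemble_mask & self.responsive.get(
            conditioned_odor, np.zeros(self.X.n_pns, dtype=bool)
        )
        for _ in range(n_sessions):
            self.W1 = self.W1 + self.delta * (xbar * mask)
        return self.W1

    def simulate_por(self, odor: str) -> dict[str, np.ndarray]:
        """Decoding-unit and POR time courses for one odor's bins."""
        seg = self.X.data[:, self._segment_index(odor)]
        dn1 = np.clip(seg.T @ self.W1 - self.theta1, 0.0, None)
        dn2 = np.clip(seg.T @ self.W2 - self.theta2, 0.0, None)
        por = np.clip(dn1 - dn2, 0.0, None)
        return {"dn1": dn1, "dn2": dn2, "por": por, "times": self.X.bin_times()}

    def simulate_all(self) -> dict[str, dict[str, np.ndarray]]:
        return {o: self.simulate_por(o) for o in self.X.odor_ids}

    def summary(self) -> str:
        n1 = int(self.ensemble_mask.sum())
        lines = [
            "Hebbian neuron/anti-neuron network",
            f"  PNs: {self.X.n_pns} (ensemble 1: {n1}, ensemble 2: {self.X.n_pns - n1})",
            f"  delta: {self.delta}   theta1: {self.theta1:.4f}   theta2: {self.theta2:.4f}",
            "  peak POR per odor:",
        ]
        for o in self.X.odor_ids:
            lines.append(f"    {o}: {self.simulate_por(o)['por'].max():.4f}")
        return "\n".join(lines)
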