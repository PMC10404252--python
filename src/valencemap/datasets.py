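"""Core data containers shared by every analysis stage.

All times are in seconds relative to stimulus onset (onset = 0); time bins
are half-open ``[t, t + dt)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WindowSpec",
    "PORMatrix",
    "PORTrace",
    "SpikeDataset",
    "BinnedResponseMatrix",
]


@dataclass(frozen=True)
class WindowSpec:
    """Stimulus protocol windows (seconds).

    ``baseline`` seconds of recorded pre-stimulus activity precede odor
    onset (4 s recorded by default; analysis windows may use less), the ON
    window is ``[0, on)`` and the OFF window is ``[on, on + off)``.
    """

    baseline: float = 4.0
    on: float = 4.0
    off: float = 4.0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.on <= 0 or self.off < 0:
            raise ValueError("window durations must be non-negative (ON > 0)")

    @property
    def t_start(self) -> float:
        return -self.baseline

    @property
    def t_end(self) -> float:
        return self.on + self.off

    @property
    def duration(self) -> float:
        return self.baseline + self.on + self.off

    def on_interval(self) -> tuple[float, float]:
        return (0.0, self.on)

    def off_interval(self) -> tuple[float, float]:
        return (self.on, self.on + self.off)


@dataclass
class PORMatrix:
    """Binary palp-opening responses, one row per locust, one column per odor."""

    responses: np.ndarray
    odor_ids: list[str]
    locust_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D locusts x odors matrix")
        if self.responses.size == 0:
            raise ValueError("empty POR matrix")
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("POR entries must be 0 or 1")
        self.responses = self.responses.astype(np.int8)
        if len(self.odor_ids) != self.responses.shape[1]:
            raise ValueError("odor_ids length must match number of columns")
        if not self.locust_ids:
            self.locust_ids = [f"locust{i:02d}" for i in range(self.responses.shape[0])]
        if len(self.locust_ids) != self.responses.shape[0]:
            raise ValueError("locust_ids length must match number of rows")

    @property
    def n_locusts(self) -> int:
        return self.responses.shape[0]

    @property
    def n_odors(self) -> int:
        return self.responses.shape[1]

    def subset(self, locust_idx: np.ndarray) -> "PORMatrix":
        locust_idx = np.asarray(locust_idx)
        return PORMatrix(
            self.responses[locust_idx],
            list(self.odor_ids),
            [self.locust_ids[i] for i in locust_idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, index=self.locust_ids, columns=self.odor_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PORMatrix":
        return cls(frame.to_numpy(), list(map(str, frame.columns)), list(map(str, frame.index)))


@dataclass
class PORTrace:
    """A single palp-separation time series (arbitrary units, 30 fps)."""

    separation: np.ndarray
    onset: int
    offset: int
    locust_id: str = ""
    odor_id: str = ""
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        if self.separation.ndim != 1:
            raise ValueError("separation must be a 1-D series")
        if (self.separation < 0).any():
            raise ValueError("palp separation cannot be negative")
        if not (0 <= self.onset < self.offset <= len(self.separation)):
            raise ValueError("need 0 <= onset < offset <= trace length")

    @property
    def n_frames(self) -> int:
        return len(self.separation)


class SpikeDataset:
    """Spike times per (PN, odor, trial) with the stimulus window spec.

    Parameters
    ----------
    spikes : mapping ``(pn_id, odor_id, trial) -> array of spike times``
        Times in seconds relative to stimulus onset.
    window : WindowSpec
    panel : optional mapping ``odor_id -> (valence_class, por_probability)``
    """

    def __init__(self, spikes, window: WindowSpec, panel: dict | None = None):
        self.window = window
        self.panel = dict(panel) if panel else {}
        self._spikes: dict[tuple[str, str, int], np.ndarray] = {}
        pns, odors, trials = set(), set(), {}
        for (pn, odor, trial), times in spikes.items():
            times = np.asarray(times, dtype=float)
            if not np.isfinite(times).all():
                raise ValueError(f"non-finite spike time for ({pn}, {odor}, {trial})")
            self._spikes[(pn, odor, trial)] = np.sort(times)
            pns.add(pn)
            odors.add(odor)
            trials.setdefault((pn, odor), set()).add(trial)
        self.pn_ids = sorted(pns)
        self.odor_ids = sorted(odors)
        counts = {len(v) for v in trials.values()}
        if len(counts) > 1:
            raise ValueError("trial counts must be uniform across (PN, odor) pairs")
        self.n_trials = counts.pop() if counts else 0

    @property
    def n_pns(self) -> int:
        return len(self.pn_ids)

    @property
    def n_odors(self) -> int:
        return len(self.odor_ids)

    def spike_times(self, pn: str, odor: str, trial: int) -> np.ndarray:
        return self._spikes[(pn, odor, trial)]

    def subset_pns(self, pn_ids) -> "SpikeDataset":
        keep = set(pn_ids)
        spikes = {k: v for k, v in self._spikes.items() if k[0] in keep}
        return SpikeDataset(spikes, self.window, self.panel)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (pn_id, odor_id, trial, spike_time_s)."""
        rows = []
        for (pn, odor, trial), times in sorted(self._spikes.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "pn_id": pn,
                        "odor_id": odor,
                        "trial": trial,
                        "spike_time_s": times,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["pn_id", "odor_id", "trial", "spike_time_s"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        window: WindowSpec,
        panel: dict | None = None,
        keys: pd.DataFrame | None = None,
    ) -> "SpikeDataset":
        """Rebuild from the long table.

        ``keys`` optionally enumerates every (pn_id, odor_id, trial)
        combination so that spike-free trials survive the round trip.
        """
        spikes: dict[tuple[str, str, int], np.ndarray] = {}
        if keys is not None:
            for pn, odor, trial in keys.itertuples(index=False):
                spikes[(str(pn), str(odor), int(trial))] = np.empty(0)
        for (pn, odor, trial), grp in frame.groupby(["pn_id", "odor_id", "trial"], sort=False):
            spikes[(str(pn), str(odor), int(trial))] = grp["spike_time_s"].to_numpy()
        return cls(spikes, window, panel)


@dataclass
class BinnedResponseMatrix:
    """Trial-averaged PN x time-bin firing matrix.

    ``data`` concatenates equal-length per-odor segments (``bins_per_odor``
    columns each, ordered as ``odor_ids``); ``t_start`` is the time of the
    first bin edge of each segment relative to stimulus onset.
    """

    data: np.ndarray
    bin_width: float
    pn_ids: list[str]
    odor_ids: list[str]
    t_start: float
    window: WindowSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (PNs x bins)")
        if self.data.shape[1] % len(self.odor_ids):
            raise ValueError("column count must be a multiple of the number of odors")
        if (self.data < 0).any():
            raise ValueError("binned counts must be non-negative")

    @property
    def n_pns(self) -> int:
        return self.data.shape[0]

    @property
    def bins_per_odor(self) -> int:
        return self.data.shape[1] // len(self.odor_ids)

    def bin_times(self) -> np.ndarray:
        """Left edges of one odor segment's bins, relative to onset."""
        return self.t_start + self.bin_width * np.arange(self.bins_per_odor)

    def odor_segment(self, odor_id: str) -> np.ndarray:
        j = self.odor_ids.index(odor_id)
        b = self.bins_per_odor
        return self.data[:, j * b : (j + 1) * b]

    def segment_mask(self, interval: tuple[float, float]) -> np.ndarray:
        """Boolean mask over one segment's bins whose left edge lies in ``interval``."""
        t = self.bin_times()
        return (t >= interval[0] - 1e-9) & (t < interval[1] - 1e-9)
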