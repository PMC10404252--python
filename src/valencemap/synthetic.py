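"""Synthetic locust olfaction data with the statistical structure the
downstream analyses assume.

The generator emulates a panel of 22 odorants presented to a population of
antennal-lobe projection neurons (PNs) and to a cohort of locusts scored
for palp-opening responses (PORs).  PNs are partitioned into four response
pools (appetitive-ON, appetitive-OFF, non-appetitive-ON, non-appetitive-OFF);
odorants recruit responders from the pools of their valence class in a
nested fashion ordered by innate POR probability, so higher-valence odors
drive more PNs — the qualitative trend seen in recordings.  Spiking is
piecewise-constant-rate Poisson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import PORMatrix, PORTrace, SpikeDataset, WindowSpec

__all__ = [
    "OdorSpec",
    "SyntheticConfig",
    "DEFAULT_ODOR_PANEL",
    "generate_por_matrix",
    "generate_pn_population",
    "generate_por_traces",
    "ensemble_pools",
]

APPETITIVE = "appetitive"
NEUTRAL = "neutral"
UNAPPETITIVE = "unappetitive"
VALENCE_CLASSES = (APPETITIVE, NEUTRAL, UNAPPETITIVE)


@dataclass(frozen=True)
class OdorSpec:
    odor_id: str
    valence_class: str
    por_probability: float

    def __post_init__(self):
        if self.valence_class not in VALENCE_CLASSES:
            raise ValueError(f"unknown valence class {self.valence_class!r}")
        if not 0.0 <= self.por_probability <= 1.0:
            raise ValueError("POR probability must be in [0, 1]")


#: 22-odor default panel: 5 appetitive, 9 neutral, 8 unappetitive odorants
#: with innate POR probabilities spanning the observed behavioral range
#: (panel mean ~0.4).
DEFAULT_ODOR_PANEL: tuple[OdorSpec, ...] = tuple(
    OdorSpec(o, c, p)
    for o, c, p in [
        ("hexanol10", APPETITIVE, 0.85),
        ("hexanol", APPETITIVE, 0.75),
        ("isoamyl_acetate", APPETITIVE, 0.70),
        ("hexanal", APPETITIVE, 0.65),
        ("2octanol", APPETITIVE, 0.60),
        ("apple", NEUTRAL, 0.50),
        ("mint", NEUTRAL, 0.48),
        ("eucalyptol", NEUTRAL, 0.45),
        ("ethyl_acetate", NEUTRAL, 0.42),
        ("cyclohexanone", NEUTRAL, 0.40),
        ("ammonium", NEUTRAL, 0.38),
        ("vanilla", NEUTRAL, 0.35),
        ("garlic", NEUTRAL, 0.33),
        ("neem", NEUTRAL, 0.30),
        ("benzaldehyde", UNAPPETITIVE, 0.28),
        ("citral", UNAPPETITIVE, 0.25),
        ("hexanol01", UNAPPETITIVE, 0.22),
        ("butyric_acid", UNAPPETITIVE, 0.18),
        ("octanoic_acid", UNAPPETITIVE, 0.15),
        ("geraniol", UNAPPETITIVE, 0.12),
        ("decanol", UNAPPETITIVE, 0.08),
        ("linalool", UNAPPETITIVE, 0.05),
    ]
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the recorded study's scale: 89 PNs, 26 locusts,
    22 odorants, 10 trials per odor, 2 s baseline / 4 s ON / 4 s OFF.
    """

    n_pns: int = 89
    n_locusts: int = 26
    odor_panel: tuple[OdorSpec, ...] = DEFAULT_ODOR_PANEL
    n_trials: int = 10
    sampling: float = 1.0 / 15000.0
    window: WindowSpec = field(default_factory=WindowSpec)
    baseline_rate: float = 2.0
    on_gain: float = 20.0
    off_gain: float = 15.0
    ensemble_overlap: float = 0.7
    cross_activation: float = 0.2
    cross_gain_fraction: float = 0.25
    inhibition_prob: float = 0.5
    inhibited_fraction: float = 0.2
    n_extra_responders: int = 2
    trace_fps: float = 30.0
    trace_baseline: float = 0.5
    trace_noise_sd: float = 1.0
    trace_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pns <= 0 or self.n_locusts <= 0 or self.n_trials <= 0:
            raise ValueError("n_pns, n_locusts and n_trials must be positive")
        if self.baseline_rate < 0 or self.on_gain < 0 or self.off_gain < 0:
            raise ValueError("firing rates must be non-negative")
        for frac in (
            self.ensemble_overlap,
            self.cross_activation,
            self.inhibition_prob,
            self.inhibited_fraction,
            self.cross_gain_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions and probabilities must be in [0, 1]")
        if self.sampling <= 0:
            raise ValueError("sampling resolution must be positive")
        self.odor_panel = tuple(
            o if isinstance(o, OdorSpec) else OdorSpec(*o) for o in self.odor_panel
        )

    @property
    def odor_ids(self) -> list[str]:
        return [o.odor_id for o in self.odor_panel]

    @property
    def panel_map(self) -> dict:
        return {o.odor_id: (o.valence_class, o.por_probability) for o in self.odor_panel}

    def to_json(self) -> str:
        d = asdict(self)
        d["window"] = asdict(self.window)
        d["odor_panel"] = [asdict(o) for o in self.odor_panel]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["window"] = WindowSpec(**d["window"])
        d["odor_panel"] = tuple(OdorSpec(**o) for o in d["odor_panel"])
        return cls(**d)


# Fractions of the PN population assigned to each response pool.  The
# appetitive ON pool is the largest so that high-valence odors can recruit
# more responders than low-valence ones (the recorded tuning-breadth trend).
_POOL_FRACTIONS = {
    "app_on": 0.38,
    "app_off": 0.22,
    "nonapp_on": 0.24,
    "nonapp_off": 0.16,
}


def ensemble_pools(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Deterministic partition of PN indices into the four response pools."""
    n = config.n_pns
    sizes = {}
    acc = 0
    keys = list(_POOL_FRACTIONS)
    for k in keys[:-1]:
        sizes[k] = int(round(_POOL_FRACTIONS[k] * n))
        acc += sizes[k]
    sizes[keys[-1]] = n - acc
    pools, start = {}, 0
    for k in keys:
        pools[k] = np.arange(start, start + sizes[k])
        start += sizes[k]
    return pools


def _pn_ids(config: SyntheticConfig) -> list[str]:
    return [f"pn{i:03d}" for i in range(config.n_pns)]


def _drive_strength(odor: OdorSpec) -> float:
    """Class-consistent drive in (0, 1]: appetitive odors drive their pools
    in proportion to innate POR probability, non-appetitive odors in
    proportion to how unappetitive they are (compressed so the appetitive
    pools stay the broadest)."""
    p = odor.por_probability
    return p if odor.valence_class == APPETITIVE else 0.5 + 0.35 * (1.0 - p)


def response_structure(config: SyntheticConfig):
    """Per-(PN, odor) response roles used by the spike generator.

    Returns boolean arrays (n_pns x n_odors) ``on``, ``off``, ``cross``
    (weakly driven appetitive-pool PNs), ``inhibited``, plus a per-odor
    ``strength`` vector that also scales response gains (stronger valence
    recruits more PNs *and* drives them harder).  Recruitment within each
    pool is nested: the first ``ceil(overlap * pool)`` PNs form the class
    core, and odorants with stronger class-consistent valence recruit
    longer prefixes of the pool.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    pools = ensemble_pools(config)
    n_odors = len(config.odor_panel)
    on = np.zeros((config.n_pns, n_odors), dtype=bool)
    off = np.zeros_like(on)
    cross = np.zeros_like(on)
    inhibited = np.zeros_like(on)
    strength = np.zeros(n_odors)

    n_cross = int(np.ceil(config.cross_activation * len(pools["app_on"])))
    cross_pns = pools["app_on"][:n_cross]

    for j, odor in enumerate(config.odor_panel):
        strength[j] = _drive_strength(odor)
        if odor.valence_class == APPETITIVE:
            on_pool, off_pool = pools["app_on"], pools["app_off"]
        else:
            on_pool, off_pool = pools["nonapp_on"], pools["nonapp_off"]
        for pool, mask in ((on_pool, on), (off_pool, off)):
            n_core = int(np.ceil(config.ensemble_overlap * len(pool)))
            n_recruit = max(n_core, int(round(strength[j] * len(pool))))
            mask[pool[:n_recruit], j] = True
        # idiosyncratic weak extra responders: OFF-pool PNs of the same
        # class fire weakly during ON for this odor only (mixed ON/OFF
        # tuning occurs in recordings); kept weak so odor identity, not
        # single-PN quirks, carries the valence signal
        if config.n_extra_responders and len(off_pool):
            extras = rng.choice(
                off_pool, size=min(config.n_extra_responders, len(off_pool)), replace=False
            )
            cross[extras, j] = True
        if odor.valence_class != APPETITIVE:
            cross[cross_pns, j] = True
        if config.inhibition_prob > 0:
            # inhibition deepens as valence falls (lateral suppression of
            # the non-recruited ensembles), the recorded Fig-2d-style trend
            silent = ~(on[:, j] | cross[:, j])
            p_inh = config.inhibition_prob * (1.0 - odor.por_probability)
            inhibited[:, j] = silent & (rng.random(config.n_pns) < p_inh)
    cross &= ~on  # a PN already ON-recruited is not additionally cross-driven
    return {"on": on, "off": off, "cross": cross, "inhibited": inhibited, "strength": strength}


def _piecewise_rates(config: SyntheticConfig, roles, i: int, j: int):
    """(duration, rate) segments for PN i, odor j over baseline/ON/OFF."""
    w = config.window
    base = config.baseline_rate
    gain_scale = 0.5 + roles["strength"][j]
    on_rate = base
    if roles["on"][i, j]:
        on_rate = base + config.on_gain * gain_scale
    elif roles["cross"][i, j]:
        on_rate = base + config.cross_gain_fraction * config.on_gain
    elif roles["inhibited"][i, j]:
        on_rate = base * config.inhibited_fraction
    if roles["off"][i, j]:
        off_rate = base + config.off_gain * gain_scale
    elif roles["inhibited"][i, j]:
        # lateral suppression outlasts the stimulus
        off_rate = base * config.inhibited_fraction
    else:
        off_rate = base
    return [(w.baseline, base), (w.on, on_rate), (w.off, off_rate)]


def generate_por_matrix(config: SyntheticConfig, probabilities=None) -> PORMatrix:
    """Bernoulli POR matrix: entry (locust, odor) ~ Bernoulli(p_odor)."""
    if probabilities is None:
        probabilities = [o.por_probability for o in config.odor_panel]
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("POR probabilities must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    responses = (rng.random((config.n_locusts, len(p))) < p).astype(np.int8)
    return PORMatrix(responses, config.odor_ids)


def generate_pn_population(config: SyntheticConfig) -> SpikeDataset:
    """Inhomogeneous-Poisson spike trains for the whole PN population.

    Spike times are drawn segment-wise (homogeneous Poisson within the
    baseline/ON/OFF windows) and quantized to ``config.sampling``.
    """
    roles = response_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    pn_ids = _pn_ids(config)
    spikes = {}
    w = config.window
    for i, pn in enumerate(pn_ids):
        for j, odor in enumerate(config.odor_panel):
            segments = _piecewise_rates(config, roles, i, j)
            for trial in range(config.n_trials):
                times = []
                t0 = w.t_start
                for duration, rate in segments:
                    n = rng.poisson(rate * duration)
                    if n:
                        times.append(t0 + rng.random(n) * duration)
                    t0 += duration
                if times:
                    t = np.sort(np.concatenate(times))
                    t = np.round(t / config.sampling) * config.sampling
                    # quantization may push a spike onto the window end
                    t = np.clip(t, w.t_start, w.t_end - config.sampling)
                else:
                    t = np.empty(0)
                spikes[(pn, odor.odor_id, trial)] = t
    return SpikeDataset(spikes, w, panel=config.panel_map)


def _on_response_profile(t: np.ndarray, onset_s: float, offset_s: float, amp: float):
    """ON-paradigm learned POR: fast rise after onset, slow adaptation,
    decay after offset.  Peak lies inside the stimulus window."""
    y = np.zeros_like(t)
    stim = (t >= onset_s) & (t < offset_s)
    post = t >= offset_s
    y[stim] = amp * (1.0 - np.exp(-(t[stim] - onset_s) / 0.3)) * np.exp(
        -(t[stim] - onset_s) / 8.0
    )
    level_at_off = amp * (1.0 - np.exp(-(offset_s - onset_s) / 0.3)) * np.exp(
        -(offset_s - onset_s) / 8.0
    )
    y[post] = level_at_off * np.exp(-(t[post] - offset_s) / 0.8)
    return y


def _off_response_profile(t: np.ndarray, onset_s: float, offset_s: float, amp: float):
    """OFF-paradigm learned POR: slow rise late in the stimulus, peak after
    odor termination."""
    peak_t = offset_s + 1.2
    y = amp * np.exp(-0.5 * ((t - peak_t) / 1.5) ** 2)
    y[t < onset_s + 0.5] = 0.0
    return y


def generate_por_traces(
    paradigm: str,
    valence_class: str,
    config: SyntheticConfig,
    n_traces: int = 1,
    odor_id: str = "",
    seed: int | None = None,
) -> list[PORTrace]:
    """Palp-separation traces for a trained locust cohort.

    ``paradigm`` is ``"ON"`` or ``"OFF"`` (reward during vs just after the
    stimulus).  Appetitive odors produce learned PORs with paradigm-specific
    dynamics; neutral/unappetitive odors produce baseline noise only.
    """
    if paradigm not in ("ON", "OFF"):
        raise ValueError("paradigm must be 'ON' or 'OFF'")
    if valence_class not in VALENCE_CLASSES:
        raise ValueError(f"unknown valence class {valence_class!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 404])
    )
    w = config.window
    fps = config.trace_fps
    n_frames = int(round(w.duration * fps))
    onset = int(round(w.baseline * fps))
    offset = int(round((w.baseline + w.on) * fps))
    t = np.arange(n_frames) / fps  # trace-local time, 0 at first frame
    onset_s, offset_s = onset / fps, offset / fps
    if valence_class == APPETITIVE:
        profile = (_on_response_profile if paradigm == "ON" else _off_response_profile)(
            t, onset_s, offset_s, config.trace_amplitude
        )
    else:
        profile = np.zeros_like(t)
    traces = []
    for k in range(n_traces):
        noise = rng.normal(0.0, config.trace_noise_sd, n_frames)
        sep = np.clip(config.trace_baseline + profile + noise, 0.0, None)
        traces.append(
            PORTrace(sep, onset, offset, locust_id=f"locust{k:02d}", odor_id=odor_id, fps=fps)
        )
    return traces
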