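import numpy as np
import pytest

import valencemap as vm
from valencemap.datasets import WindowSpec


SMALL_PANEL = tuple(
    vm.synthetic.OdorSpec(o, c, p)
    for o, c, p in [
        ("hexanol", "appetitive", 0.8),
        ("isoamyl_acetate", "appetitive", 0.65),
        ("apple", "neutral", 0.45),
        ("cyclohexanone", "neutral", 0.4),
        ("benzaldehyde", "unappetitive", 0.25),
        ("citral", "unappetitive", 0.2),
        ("linalool", "unappetitive", 0.05),
    ]
)


@pytest.fixture
def small_config():
    """A scaled-down population for fast unit tests."""
    return vm.SyntheticConfig(
        n_pns=24, n_locusts=12, odor_panel=SMALL_PANEL, n_trials=5, seed=11
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale synthetic population shared across tests."""
    cfg = vm.SyntheticConfig(seed=5)
    return cfg, vm.synthetic.generate_pn_population(cfg)


def poisson_dataset(n_pns, n_odors, n_trials, rate, seed, window=None):
    """Pure-Poisson (no-signal) spike dataset used for false-positive tests.

    ``rate`` may be a scalar or a per-PN array of baseline rates (Hz).
    """
    window = window or WindowSpec()
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rate, dtype=float), (n_pns,))
    spikes = {}
    T = window.duration
    for i in range(n_pns):
        for j in range(n_odors):
            for k in range(n_trials):
                n = rng.poisson(rates[i] * T)
                spikes[(f"pn{i:03d}", f"odor{j:02d}", k)] = np.sort(
                    window.t_start + rng.random(n) * T
                )
    return vm.SpikeDataset(spikes, window)
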