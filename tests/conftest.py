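import numpy as np
import pandas as pd
import pytest

from seqrec import layout, synth


def tiny_channels(n_sites: int) -> list[layout.ChannelInfo]:
    """A miniature sensor set (n_sites x [2 grads + 1 mag]) on a 1-row grid."""
    chs = []
    for s in range(n_sites):
        base = 3 * s
        chs.append(layout.ChannelInfo(f"G{s}A", "planar_grad", s, base + 1,
                                      (0, s)))
        chs.append(layout.ChannelInfo(f"G{s}B", "planar_grad", s, base,
                                      (0, s)))
        chs.append(layout.ChannelInfo(f"M{s}", "magnetometer", s, None,
                                      (0, s)))
    return chs


def tiny_epochs(n_trials_per_cond=16, n_sites=2, n_time=10, effect=0.0,
                effect_window=(3, 8), seed=0, sfreq=100.0) -> synth.EpochSet:
    """Small hand-built EpochSet: optional class difference on the first
    site's channels inside a sample window."""
    rng = np.random.default_rng(seed)
    n = 2 * n_trials_per_cond
    chs = tiny_channels(n_sites)
    data = rng.standard_normal((n, len(chs), n_time))
    cond = np.array(["memorized"] * n_trials_per_cond
                    + ["novel"] * n_trials_per_cond)[rng.permutation(n)]
    if effect:
        lo, hi = effect_window
        data[np.ix_(cond == "memorized", np.arange(3),
                    np.arange(lo, hi))] += effect
    trials = pd.DataFrame({
        "condition": cond,
        "correct": np.ones(n, dtype=bool),
        "rt_ms": rng.uniform(1000, 3000, n),
    })
    return synth.EpochSet(data, chs, sfreq, 0.0, trials)


@pytest.fixture(scope="session")
def channels():
    return layout.make_channels()


@pytest.fixture(scope="session")
def null_epochs():
    """One participant, no injected condition difference."""
    return synth.generate_epochs(seed=11)


@pytest.fixture(scope="session")
def melodies():
    return synth.generate_melodies(seed=3)
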