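import numpy as np
import pytest

import hipba as h


@pytest.fixture(scope="session")
def nominal():
    return h.ParameterSet.nominal()


@pytest.fixture(scope="session")
def wt_network():
    return h.build_wild_type()


@pytest.fixture(scope="session")
def wt_equilibrium(wt_network, nominal):
    return h.find_equilibrium(wt_network, nominal)


@pytest.fixture(scope="session")
def wt_ensemble(wt_network, nominal):
    """Six wild-type cells, 300 h each, started at the rounded equilibrium.

    Shared across the persistence and phenomenology tests to keep the suite
    fast; statistics exclude the first 50 h.
    """
    init = h.default_ssa_init(wt_network, nominal)
    return [
        h.gillespie_run(
            wt_network, nominal, init=init, t_end=300.0, seed=seed,
            burn_in=50.0,
        )
        for seed in range(6)
    ]


def dwell_weights(run):
    """Dwell time of each recorded state inside the observation window."""
    t = np.append(run.times, run.t_end)
    lo = np.clip(t[:-1], run.burn_in, run.t_end)
    hi = np.clip(t[1:], run.burn_in, run.t_end)
    return hi - lo


def weighted_corr(run, x, y):
    """Dwell-weighted Pearson correlation of two piecewise-constant paths."""
    w = dwell_weights(run)
    W = w.sum()
    mx = (w * x).sum() / W
    my = (w * y).sum() / W
    cov = (w * (x - mx) * (y - my)).sum() / W
    sx = np.sqrt((w * (x - mx) ** 2).sum() / W)
    sy = np.sqrt((w * (y - my) ** 2).sum() / W)
    return cov / (sx * sy)
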