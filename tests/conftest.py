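import numpy as np
import pandas as pd
import pytest

from finmove import argos, simulate, ssm
from finmove.sampler import MCMCConfig, fit_hssm


def make_fix(ptt="87780", hours=0.0, lon=8.0, lat=42.0, lc="B", day0="2012-09-22"):
    return argos.ArgosFix(
        ptt=ptt,
        time=pd.Timestamp(day0) + pd.Timedelta(hours=hours),
        lon=lon,
        lat=lat,
        lc=lc,
    )


def track_with_duration(ptt, days, n_fixes=None, day0="2012-09-22"):
    """Evenly spaced fixes spanning ``days``; default ~4 fixes/day."""
    n = n_fixes or max(2, int(days * 4))
    hours = np.linspace(0.0, days * 24.0, n)
    return [make_fix(ptt=ptt, hours=h, lon=8.0 + 0.01 * h, lat=42.0, day0=day0) for h in hours]


@pytest.fixture(scope="session")
def pelagos_deployments():
    """The eight 2012 Pelagos deployments: one transmissions-only tag, one
    2-day tag, and six tags tracked well beyond any short-duration cut-off."""
    return {
        "112707": [],  # transmissions received, no locations
        "112697": track_with_duration("112697", 142),  # long track, split in-paper
        "112716": track_with_duration("112716", 83),
        "112709": track_with_duration("112709", 2),  # the short tag
        "112708": track_with_duration("112708", 81),
        "102223": track_with_duration("102223", 18),
        "102221": track_with_duration("102221", 35),
        "102224": track_with_duration("102224", 22),
    }


@pytest.fixture(scope="session")
def sim_segment():
    """One simulated segment (100 steps) with its ground truth."""
    params = simulate.default_params()
    truth = simulate.simulate_dcrws(params, n_steps=100, seed=7)
    fixes = simulate.observe_argos(truth, seed=17, ptt="SIM001")
    seg = argos.split_on_gaps("SIM001", fixes)[0]
    return truth, seg


@pytest.fixture(scope="session")
def small_fit(sim_segment):
    """A deliberately short MCMC fit shared across sampler tests."""
    _, seg = sim_segment
    reg = ssm.regularise(seg, step_hours=12.0)
    return fit_hssm([reg], mcmc=MCMCConfig(chains=2, iters=600, burn=300, thin=3, seed=5))
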