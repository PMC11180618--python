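"""Shared fixtures: small ground-truthed simulations, one per scenario.

All fixtures are generated programmatically at session scope so the
expensive renders (simulate -> detect boundaries) run once.
"""

import numpy as np
import pytest

import myowave as mw


@pytest.fixture(scope="session")
def clean_params() -> mw.SimulationParams:
    """A short, clean recording at reduced frame size."""
    return mw.SimulationParams(width=400, height=120, duration_s=10.0,
                               r0=30.0, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_sim(clean_params):
    return mw.simulate_video(clean_params)


@pytest.fixture(scope="session")
def clean_boundaries(clean_sim):
    stack, _ = clean_sim
    return mw.find_boundaries(stack)


@pytest.fixture(scope="session")
def noisy_sim():
    params = mw.SimulationParams(width=400, height=120, duration_s=10.0,
                                 r0=30.0, noise_sd=5.0, artifact_count=3,
                                 seed=11)
    return mw.simulate_video(params)


def boundary_mae(stack, gt, b) -> float:
    """Mean absolute boundary error over valid cells, against ground truth."""
    errs = []
    for t in range(stack.n_frames):
        tu, tl = gt.boundary_truth(t)
        v = b.valid[t]
        if v.any():
            errs.append(np.abs(b.upper[t, v] - tu[v]).mean())
            errs.append(np.abs(b.lower[t, v] - tl[v]).mean())
    return float(np.mean(errs))
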