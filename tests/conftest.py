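"""Shared fixtures: benchmark ensembles simulated once per session."""

import pytest

import wildmoments as wm


@pytest.fixture(scope="session")
def system_P():
    return wm.build_system("P")


@pytest.fixture(scope="session")
def system_W():
    return wm.build_system("W")


@pytest.fixture(scope="session")
def ensemble_P(system_P):
    """Immigration-death ensemble: n=5000 to t=5 s (never hits the cap)."""
    return wm.run_ensemble(system_P, x0=1, t_end=5.0, n=5000, cap=10_000, base_seed=11)


@pytest.fixture(scope="session")
def ensemble_W(system_W):
    """Fat-tailed quadratic birth-death ensemble: n=2000, 5000-reaction cap."""
    return wm.run_ensemble(system_W, x0=1, t_end=5.0, n=2000, cap=5000, base_seed=23)
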