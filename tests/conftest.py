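"""Shared fixtures: expensive end-to-end runs are session-scoped so multiple
tests can interrogate the same trajectory."""

from __future__ import annotations

import pytest

import ltpsim as L
from ltpsim.presets import run_preset


@pytest.fixture(scope="session")
def fig2a():
    """Standard no-feedback induction run (forward Euler, dt = 10 ms)."""
    return run_preset("fig2a")


@pytest.fixture(scope="session")
def fig2a_rk4():
    return run_preset("fig2a", integrator="rk4")


@pytest.fixture(scope="session")
def fig2b():
    return run_preset("fig2b")


@pytest.fixture(scope="session")
def fig2c():
    return run_preset("fig2c")


@pytest.fixture(scope="session")
def fig3a():
    return run_preset("fig3a")


@pytest.fixture(scope="session")
def fig3b():
    return run_preset("fig3b", seed=3)


@pytest.fixture(scope="session")
def fig5a():
    return run_preset("fig5a", seed=3)


@pytest.fixture(scope="session")
def fig5b():
    return run_preset("fig5b", seed=3)


@pytest.fixture(scope="session")
def fig4a():
    return run_preset("fig4a", seed=3)


@pytest.fixture(scope="session")
def synergy_maintained():
    """Variant IV with both feedback loops left on through 50 h."""
    variant = L.VariantId.SYNERGY
    p = L.load_preset(variant)
    basal = L.equilibrate(L.initialize(p, variant), p, variant)
    proto = L.Protocol(tetani=L.standard_induction(), reactivation=True,
                       reactivation_seed=3)
    cfg = L.SimulationConfig(t_end=3050.0, record_stride=600, seed=3)
    return basal, L.run(basal, proto, p, variant, cfg)


@pytest.fixture(scope="session")
def nofb_basal():
    """Equilibrated basal state of the no-feedback preset."""
    variant = L.VariantId.NO_FEEDBACK
    p = L.load_preset(variant)
    state = L.equilibrate(L.initialize(p, variant), p, variant)
    return p, state
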