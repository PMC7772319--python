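"""Integration driver: initialization, equilibration, determinism,
conservation, recording invariants, scheduled changes, and upper-state
snapshots."""

import numpy as np
import pytest

import ltpsim as L
from ltpsim.dynamics import STATE_FIELDS, basal_forcing, derivatives
from ltpsim.params import ScheduledChange, VariantId, load_preset
from ltpsim.simulate import (DT_STANDARD, EquilibrationError, SimulationConfig,
                             UpperStateError, equilibrate, initialize, run,
                             snapshot_upper_state)
from ltpsim.stimulation import Protocol, tetanus_train


def test_initialize_values_and_conservation():
    p = load_preset(VariantId.NO_FEEDBACK)
    s = initialize(p, VariantId.NO_FEEDBACK)
    assert all(getattr(s, f) == 1e-4 for f in STATE_FIELDS)
    assert s.RAF(p) == pytest.approx(0.2499)
    assert s.MEKP(p) == pytest.approx(0.25 - 2e-4)
    assert initialize(p, VariantId.NO_FEEDBACK) == s  # repeatable


def test_equilibrated_basal_fixed_points(nofb_basal):
    """Closed-form basal fixed points reproduced within 0.1%."""
    p, s = nofb_basal
    assert s.RAFP == pytest.approx(0.25 * 0.0075 / 0.1275, rel=1e-3)
    pkm_closed = (p.k_transpkm * s.P_CK2 * s.P_ERK + p.k_transbaspkm) / p.k_dpkm
    assert s.PKM_act == pytest.approx(pkm_closed, rel=1e-3)
    tag = s.Tag1 * s.Tag2 * s.Tag3
    sat = s.P_lim / (s.P_lim + p.K_lim)
    w_closed = p.tau_ltp * (p.k_ltp * tag * p.PRP * s.PKM_act * sat + p.k_ltpbas)
    assert s.W == pytest.approx(w_closed, rel=1e-3)
    assert s.W == pytest.approx(3.0, rel=0.05)  # ~k_ltpbas*tau_ltp + correction


def test_equilibrated_derivatives_vanish(nofb_basal):
    """At the equilibrated basal state all derivatives are ~0 relative to
    each variable's basal magnitude."""
    p, s = nofb_basal
    d = derivatives(s, basal_forcing(p), p)
    y = s.to_array()
    rel = np.abs(d) / np.maximum(np.abs(y), 1e-9)
    assert np.all(rel < 1e-5)


def test_equilibrate_rejects_short_duration():
    p = load_preset(VariantId.NO_FEEDBACK)
    with pytest.raises(ValueError):
        equilibrate(initialize(p, VariantId.NO_FEEDBACK), p,
                    VariantId.NO_FEEDBACK, duration=100.0)


def test_run_deterministic_and_recording_invariants(nofb_basal):
    p, basal = nofb_basal
    proto = Protocol(tetani=tetanus_train(3, 5.0, 10.0))
    cfg = SimulationConfig(t_end=60.0, record_stride=100)
    t1 = run(basal, proto, p, VariantId.NO_FEEDBACK, cfg)
    t2 = run(basal, proto, p, VariantId.NO_FEEDBACK, cfg)
    assert np.array_equal(t1.states, t2.states)
    assert np.array_equal(t1.times, t2.times)
    # sample count = steps/stride + 1; strictly increasing times
    n_steps = int(round(60.0 / cfg.dt))
    assert t1.times.size == n_steps // cfg.record_stride + 1
    assert np.all(np.diff(t1.times) > 0)


def test_stochastic_run_reproducible_per_seed():
    p = load_preset(VariantId.REACTIVATION)
    basal = equilibrate(initialize(p, VariantId.REACTIVATION), p,
                        VariantId.REACTIVATION)
    cfg = SimulationConfig(t_end=1500.0, record_stride=600)
    a = run(basal, Protocol(reactivation=True, reactivation_seed=9), p,
            VariantId.REACTIVATION, cfg)
    b = run(basal, Protocol(reactivation=True, reactivation_seed=9), p,
            VariantId.REACTIVATION, cfg)
    c = run(basal, Protocol(reactivation=True, reactivation_seed=10), p,
            VariantId.REACTIVATION, cfg)
    assert np.array_equal(a.states, b.states)
    assert a.events.onsets().tolist() == b.events.onsets().tolist()
    assert a.events.onsets().tolist() != c.events.onsets().tolist()


def test_mass_conservation_and_bounds(fig2a):
    """Conserved pools nonnegative and fractional variables within [0,1] at
    every recorded step; concentrations nonnegative; zero clamps."""
    traj = fig2a.trajectory
    p = load_preset(VariantId.NO_FEEDBACK)
    for name in ("RAFP", "MEK", "MEKPP", "ERK", "ERKPP", "CaMKII_act",
                 "PKM_act", "W", "P_lim"):
        assert traj.series(name).min() >= 0.0
    assert np.all(traj.series("RAFP") <= p.RAF_TOT + 1e-12)
    mekp = p.MEK_TOT - traj.series("MEK") - traj.series("MEKPP")
    erkp = p.ERK_TOT - traj.series("ERK") - traj.series("ERKPP")
    assert mekp.min() >= -1e-12 and erkp.min() >= -1e-12
    for name in ("PKA_act", "Tag1", "Tag2", "Tag3", "P_CK2", "P_ERK"):
        x = traj.series(name)
        assert x.min() >= 0.0 and x.max() <= 1.0
    assert traj.clamp_count == 0


def test_peak_tag_monotone_in_stimulus_amplitudes(nofb_basal):
    """Peak TAG during induction is nondecreasing in each stimulus amplitude
    (spot-check at +/-15%)."""
    p0, basal = nofb_basal
    proto = Protocol(tetani=tetanus_train(3, 5.0, 10.0))
    cfg = SimulationConfig(t_end=40.0, record_stride=100)

    def peak_tag(p):
        return run(basal, proto, p, VariantId.NO_FEEDBACK, cfg).tag.max()

    for name in ("A_Casyn", "A_cAMP", "A_STIM"):
        lo, hi = p0.copy(), p0.copy()
        setattr(lo, name, getattr(p0, name) * 0.85)
        setattr(hi, name, getattr(p0, name) * 1.15)
        assert peak_tag(lo) <= peak_tag(p0) <= peak_tag(hi)


def test_single_kinase_block_abolishes_tagging(nofb_basal):
    """Zeroing any one tag-site phosphorylation rate keeps TAG within 1% of
    basal through induction (multiplicative necessity of each kinase)."""
    p0, basal = nofb_basal
    proto = Protocol(tetani=tetanus_train(3, 5.0, 10.0))
    cfg = SimulationConfig(t_end=60.0, record_stride=100)
    tag_bas = run(basal, Protocol(), p0, VariantId.NO_FEEDBACK,
                  SimulationConfig(t_end=10.0, record_stride=100)).tag[0]
    for name in ("k_phos1", "k_phos2", "k_phos3"):
        p = p0.copy()
        setattr(p, name, 0.0)
        # re-equilibrate so the blocked site relaxes to zero
        s = equilibrate(initialize(p, VariantId.NO_FEEDBACK), p,
                        VariantId.NO_FEEDBACK)
        traj = run(s, proto, p, VariantId.NO_FEEDBACK, cfg)
        assert traj.tag.max() <= 0.01 * tag_bas


def test_scheduled_change_segmentation_is_seamless(nofb_basal):
    """A scheduled change that re-asserts the current value reproduces the
    unsegmented trajectory exactly."""
    p, basal = nofb_basal
    tet = tetanus_train(3, 5.0, 10.0)
    cfg = SimulationConfig(t_end=60.0, record_stride=100)
    plain = run(basal, Protocol(tetani=tet), p, VariantId.NO_FEEDBACK, cfg)
    seg = run(basal, Protocol(tetani=tet,
                              changes=(ScheduledChange(30.0, "k_ltp", 500.0),)),
              p, VariantId.NO_FEEDBACK, cfg)
    assert np.array_equal(plain.states, seg.states)
    assert np.array_equal(plain.times, seg.times)


def test_scheduled_change_takes_effect(nofb_basal):
    p, basal = nofb_basal
    cfg = SimulationConfig(t_end=120.0, record_stride=100)
    off = run(basal, Protocol(changes=(ScheduledChange(30.0, "k_ltpbas", 0.0),)),
              p, VariantId.NO_FEEDBACK, cfg)
    # with basal weight production off, W decays from its basal value
    assert off.final_state.W < 0.9 * basal.W


def test_rk4_matches_linear_raf_closed_form():
    """On the linear Raf subsystem the RK4 path reproduces the exponential
    closed form to 1e-8 relative."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s0 = initialize(p, VariantId.NO_FEEDBACK)
    cfg = SimulationConfig(t_end=30.0, record_stride=100, integrator="rk4")
    traj = run(s0, Protocol(), p, VariantId.NO_FEEDBACK, cfg)
    k = p.k_fbasRaf + p.k_bRaf
    ss = p.RAF_TOT * p.k_fbasRaf / k
    expected = ss + (1e-4 - ss) * np.exp(-k * traj.times)
    assert np.allclose(traj.series("RAFP"), expected, rtol=1e-8, atol=1e-12)


def test_snapshot_upper_state_camkii():
    p = load_preset(VariantId.CAMKII_AUTONOMOUS)
    snap = snapshot_upper_state(p, VariantId.CAMKII_AUTONOMOUS)
    assert snap.W > 4.5          # potentiated (basal ~3)
    assert snap.CaMKII_act > 1.0  # far above basal ~2e-3


def test_snapshot_upper_state_rejects_monostable():
    p = load_preset(VariantId.NO_FEEDBACK)
    with pytest.raises(UpperStateError):
        snapshot_upper_state(p, VariantId.NO_FEEDBACK)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(t_end=10.0, dt=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(t_end=10.0, integrator="midpoint")
    with pytest.raises(ValueError):
        SimulationConfig(t_end=10.0, equilibration=100.0)
    cfg = SimulationConfig(t_end=10.0, dt=0.007)  # 3 s pulse not on grid
    p = load_preset(VariantId.NO_FEEDBACK)
    with pytest.raises(ValueError):
        cfg.validate_grid(p)
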