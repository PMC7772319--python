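"""Right-hand sides: Hill kinetics, per-pathway rates, closed-form balances,
and agreement between the reference implementation and the compiled kernel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ltpsim.dynamics as dyn
from ltpsim import _kernel
from ltpsim.dynamics import (Forcing, ModelState, STATE_FIELDS, derivatives,
                             hill, tag_level)
from ltpsim.params import VariantId, load_preset
from ltpsim.simulate import _pack


def _basal_state(p):
    return ModelState(CaMKII_act=1.9e-3, PKA_act=3.6e-3, RAFP=0.0147,
                      MEK=0.19, MEKPP=0.014, ERK=0.20, ERKPP=0.010,
                      Tag1=0.035, Tag2=0.014, Tag3=0.012,
                      P_CK2=1.9e-3, P_ERK=0.17, PKM_act=0.078,
                      W=3.04, P_lim=0.348)


def test_hill_examples():
    assert hill(0.7, 0.7, 4) == pytest.approx(0.5)
    assert hill(0.0, 0.7, 4) == 0.0
    assert hill(0.8, 0.7, 4) == pytest.approx(0.4096 / (0.4096 + 0.2401))


@given(x=st.floats(0, 100), K=st.floats(0.01, 100), n=st.integers(1, 6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hill_bounded_and_monotone(x, K, n):
    # strictly below 1 in exact arithmetic; float rounding can saturate to 1.0
    h = hill(x, K, n)
    assert 0.0 <= h <= 1.0
    assert hill(x * 1.5 + 0.01, K, n) >= h


def test_camkii_basal_rate():
    """At basal Ca (0.04 uM) and zero CaMKII the activation rate is
    k_fck2 * Hill4(0.04) ~= 1.92e-3 uM/min."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s = ModelState()
    f = Forcing(Ca_syn=0.04, cAMP=0.06, k_fRaf=p.k_fbasRaf)
    f1 = 0.04 ** 4 / (0.04 ** 4 + 0.7 ** 4)
    assert dyn.camkii_rate(s, f, p) == pytest.approx(180.0 * f1)
    assert dyn.camkii_rate(s, f, p) == pytest.approx(1.92e-3, rel=1e-2)


def test_camkii_autoactivation_half_saturation():
    """The autoactivation term contributes k_CaMKII/2 at its Hill constant."""
    p = load_preset(VariantId.CAMKII_AUTONOMOUS)
    s = ModelState(CaMKII_act=p.K_CaMKII)
    f = Forcing(Ca_syn=p.Ca_bas, cAMP=p.cAMP_bas, k_fRaf=p.k_fbasRaf)
    base = 180.0 * hill(p.Ca_bas, p.K_Casyn, 4) - p.K_CaMKII / p.tau_ck2
    assert dyn.camkii_rate(s, f, p) == pytest.approx(base + p.k_CaMKII / 2)


def test_pka_hill_values():
    p = load_preset(VariantId.NO_FEEDBACK)
    assert hill(1.0, p.K_cAMP, 2) == pytest.approx(0.5)
    assert hill(0.06, p.K_cAMP, 2) == pytest.approx(0.0036 / 1.0036)


def test_raf_basal_steady_state():
    """Linear Raf balance: RAFP* = RAF_TOT * k_fbas / (k_fbas + k_b)."""
    p = load_preset(VariantId.NO_FEEDBACK)
    rafp_ss = 0.25 * 0.0075 / (0.0075 + 0.12)
    s = ModelState(RAFP=rafp_ss, MEK=0.1, MEKPP=0.05, ERK=0.1, ERKPP=0.05)
    f = Forcing(Ca_syn=p.Ca_bas, cAMP=p.cAMP_bas, k_fRaf=p.k_fbasRaf)
    d_rafp = dyn.raf_mek_erk_rates(s, f, p)[0]
    assert rafp_ss == pytest.approx(0.014706, rel=1e-4)
    assert d_rafp == pytest.approx(0.0, abs=1e-12)


def test_mek_rate_zero_without_kinase_or_substrate():
    """All MEK mass unphosphorylated and no active Raf: nothing moves."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s = ModelState(MEK=p.MEK_TOT, MEKPP=0.0, RAFP=0.0, ERK=p.ERK_TOT)
    f = Forcing(Ca_syn=p.Ca_bas, cAMP=p.cAMP_bas, k_fRaf=p.k_fbasRaf)
    _, d_mek, d_mekpp, _, _ = dyn.raf_mek_erk_rates(s, f, p)
    assert d_mek == 0.0 and d_mekpp == 0.0


def test_tag_steady_state_logistic_balance():
    """At fixed kinase activity C, Tag1* = k_phos1*C / (k_phos1*C + k_deph1)."""
    p = load_preset(VariantId.NO_FEEDBACK)
    C = 0.5
    tag_ss = p.k_phos1 * C / (p.k_phos1 * C + p.k_deph1)
    s = ModelState(CaMKII_act=C, Tag1=tag_ss)
    assert dyn.tag_rates(s, p)[0] == pytest.approx(0.0, abs=1e-15)
    # and with no kinase the site decays at k_deph1
    s2 = ModelState(CaMKII_act=0.0, Tag1=0.5)
    assert dyn.tag_rates(s2, p)[0] == pytest.approx(-p.k_deph1 * 0.5)


def test_tag_level_product_and_coupling():
    p0 = load_preset(VariantId.NO_FEEDBACK)
    s = ModelState(Tag1=0.5, Tag2=0.5, Tag3=0.5)
    assert tag_level(s, p0) == pytest.approx(0.125)
    s.Tag2 = 0.0
    assert tag_level(s, p0) == 0.0  # multiplicative necessity
    p1 = load_preset(VariantId.PKM_TAG_COUPLED)
    s2 = ModelState(PKM_act=1.0)
    assert tag_level(s2, p1) == pytest.approx(1e-4)


def test_pkm_basal_balance():
    """Basal PKM* ~= k_transbaspkm / k_dpkm when the synthesis product term
    is negligible (0.075 uM standard; same ratio for the synergy preset)."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s = ModelState(PKM_act=p.k_transbaspkm / p.k_dpkm)
    assert dyn.pkm_rates(s, p)[2] == pytest.approx(0.0, abs=1e-15)
    assert p.k_transbaspkm / p.k_dpkm == pytest.approx(0.075)
    p4 = load_preset(VariantId.SYNERGY)
    assert p4.k_transbaspkm / p4.k_dpkm == pytest.approx(0.075)


def test_pkm_autoactivation_half_saturation():
    p = load_preset(VariantId.PKM_AUTONOMOUS)
    s = ModelState(PKM_act=p.K_PKM)
    d_noauto = (p.k_transbaspkm - p.k_dpkm * p.K_PKM)
    assert dyn.pkm_rates(s, p)[2] == pytest.approx(d_noauto + p.k_PKM / 2)
    assert p.k_PKM / 2 == pytest.approx(0.014)


def test_weight_basal_balance():
    """With TAG = 0 the weight balance is W* = k_ltpbas * tau_ltp = 3.0, and
    basal P_lim* = k_Plbas * tau_Pl = 0.35 uM (decay reading)."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s = ModelState(W=p.k_ltpbas * p.tau_ltp, P_lim=p.k_Plbas * p.tau_Pl)
    d_W, d_Plim = dyn.weight_rates(s, p, effective_pkm=0.5)
    assert p.k_ltpbas * p.tau_ltp == pytest.approx(3.0)
    assert p.k_Plbas * p.tau_Pl == pytest.approx(0.35)
    assert d_W == pytest.approx(0.0, abs=1e-15)
    assert d_Plim == pytest.approx(0.0, abs=1e-15)


def test_plim_alternative_decay_reading():
    """The flagged -W/tau_Pl reading changes only the P_lim equation."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s = _basal_state(p)
    d0 = derivatives(s, dyn.basal_forcing(p), p, plim_weight_decay=False)
    d1 = derivatives(s, dyn.basal_forcing(p), p, plim_weight_decay=True)
    i_plim = STATE_FIELDS.index("P_lim")
    same = np.delete(np.arange(len(STATE_FIELDS)), i_plim)
    assert np.array_equal(d0[same], d1[same])
    assert d1[i_plim] - d0[i_plim] == pytest.approx(
        s.P_lim / p.tau_Pl - s.W / p.tau_Pl)


def test_derivatives_structural_independence():
    """Doubling Ca changes only the CaMKII-path entries."""
    p = load_preset(VariantId.NO_FEEDBACK)
    s = _basal_state(p)
    f1 = Forcing(Ca_syn=0.04, cAMP=0.06, k_fRaf=p.k_fbasRaf)
    f2 = Forcing(Ca_syn=0.08, cAMP=0.06, k_fRaf=p.k_fbasRaf)
    d1, d2 = derivatives(s, f1, p), derivatives(s, f2, p)
    changed = {STATE_FIELDS[i] for i in np.flatnonzero(d1 != d2)}
    assert changed == {"CaMKII_act"}


def test_derivatives_deterministic():
    p = load_preset(VariantId.SYNERGY)
    s = _basal_state(p)
    f = Forcing(Ca_syn=0.5, cAMP=0.2, k_fRaf=0.1)
    a, b = derivatives(s, f, p), derivatives(s, f, p)
    assert np.array_equal(a, b)


@pytest.mark.parametrize("variant", [VariantId.NO_FEEDBACK,
                                     VariantId.PKM_TAG_COUPLED,
                                     VariantId.CAMKII_AUTONOMOUS,
                                     VariantId.SYNERGY])
def test_kernel_matches_reference_derivatives(variant):
    """The compiled kernel's RHS equals the reference implementation on a
    batch of randomized admissible states (bit-level agreement not required:
    both are float64 expression-for-expression, so exact equality holds)."""
    p = load_preset(variant)
    pv = _pack(p)
    rng = np.random.default_rng(7)
    for _ in range(25):
        s = ModelState(
            CaMKII_act=rng.uniform(0, 5), PKA_act=rng.uniform(0, 1),
            RAFP=rng.uniform(0, 0.25),
            MEK=rng.uniform(0, 0.12), MEKPP=rng.uniform(0, 0.12),
            ERK=rng.uniform(0, 0.12), ERKPP=rng.uniform(0, 0.12),
            Tag1=rng.uniform(0, 1), Tag2=rng.uniform(0, 1),
            Tag3=rng.uniform(0, 1), P_CK2=rng.uniform(0, 1),
            P_ERK=rng.uniform(0, 1), PKM_act=rng.uniform(0, 2),
            W=rng.uniform(0, 10), P_lim=rng.uniform(0.01, 0.5))
        ca, camp, kfraf = rng.uniform(0.04, 0.8), rng.uniform(0.06, 0.25), \
            rng.uniform(0.0075, 0.14)
        inh = rng.uniform(0.1, 1.0)
        ref = derivatives(s, Forcing(ca, camp, kfraf), p,
                          effective_pkm=inh * s.PKM_act)
        out = np.empty(len(STATE_FIELDS))
        tag = _kernel._rhs(s.to_array(), ca, camp, kfraf, inh, pv, False, out)
        assert np.allclose(out, ref, rtol=1e-13, atol=1e-15)
        assert tag == pytest.approx(
            tag_level(s, p, effective_pkm=inh * s.PKM_act), rel=1e-13)


def test_state_invariant_checks():
    p = load_preset(VariantId.NO_FEEDBACK)
    s = _basal_state(p)
    s.check_invariants(p)
    s.Tag1 = 1.2
    with pytest.raises(ValueError):
        s.check_invariants(p)
    s2 = _basal_state(p)
    s2.MEK = 0.3
    s2.MEKPP = 0.2  # exceeds MEK_TOT
    with pytest.raises(ValueError):
        s2.check_invariants(p)
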