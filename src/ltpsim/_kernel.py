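"""Compiled fixed-step integration kernels (forward Euler and classical RK4).

The hot loop follows a strict update order per step: evaluate forcing ->
evaluate derivatives -> Euler (or RK4) update -> clamp/log.  Square-wave
stimulus channels are aligned to the step grid by the driver, so channel
on/off never needs partial-step handling.  State layout and equations mirror
:mod:`ltpsim.dynamics`; a unit test pins the two implementations together.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dynamics import STATE_FIELDS
from .params import PARAM_NAMES

# Parameter-vector indices (frozen into the compiled kernels as constants).
_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}
I_CA_BAS = _IDX["Ca_bas"]
I_CAMP_BAS = _IDX["cAMP_bas"]
I_CA_DUR = _IDX["Ca_dur"]
I_D_CAMP = _IDX["d_cAMP"]
I_A_CASYN = _IDX["A_Casyn"]
I_A_CAMP = _IDX["A_cAMP"]
I_A_STIM = _IDX["A_STIM"]
I_K_CASYN = _IDX["K_Casyn"]
I_K_FCK2 = _IDX["k_fck2"]
I_TAU_CK2 = _IDX["tau_ck2"]
I_K_CAMP = _IDX["K_cAMP"]
I_TAU_PKA = _IDX["tau_PKA"]
I_RAF_TOT = _IDX["RAF_TOT"]
I_MEK_TOT = _IDX["MEK_TOT"]
I_ERK_TOT = _IDX["ERK_TOT"]
I_K_FBASRAF = _IDX["k_fbasRaf"]
I_K_BRAF = _IDX["k_bRaf"]
I_K_FMEK = _IDX["k_fMEK"]
I_K_BMEK = _IDX["k_bMEK"]
I_K_MEK = _IDX["K_MEK"]
I_K_FERK = _IDX["k_fERK"]
I_K_BERK = _IDX["k_bERK"]
I_K_ERK = _IDX["K_ERK"]
I_K_TRANSPKM = _IDX["k_transpkm"]
I_K_TRANSBASPKM = _IDX["k_transbaspkm"]
I_K_DPKM = _IDX["k_dpkm"]
I_K_PHOS1 = _IDX["k_phos1"]
I_K_DEPH1 = _IDX["k_deph1"]
I_K_PHOS2 = _IDX["k_phos2"]
I_K_DEPH2 = _IDX["k_deph2"]
I_K_PHOS3 = _IDX["k_phos3"]
I_K_DEPH3 = _IDX["k_deph3"]
I_K_PHOS4 = _IDX["k_phos4"]
I_K_DEPH4 = _IDX["k_deph4"]
I_K_PHOS5 = _IDX["k_phos5"]
I_K_DEPH5 = _IDX["k_deph5"]
I_PRP = _IDX["PRP"]
I_K_LTP = _IDX["k_ltp"]
I_K_LTPBAS = _IDX["k_ltpbas"]
I_TAU_LTP = _IDX["tau_ltp"]
I_K_LIM = _IDX["K_lim"]
I_K_PL = _IDX["k_Pl"]
I_K_PLBAS = _IDX["k_Plbas"]
I_TAU_PL = _IDX["tau_Pl"]
I_K_CAMKII = _IDX["k_CaMKII"]
I_K_K_CAMKII = _IDX["K_CaMKII"]
I_K_PKM = _IDX["k_PKM"]
I_K_K_PKM = _IDX["K_PKM"]
I_K_TPKM = _IDX["k_TPKM"]
I_K_W = _IDX["K_W"]
I_REACT_AMP_SCALE = _IDX["react_amp_scale"]

N_STATE = len(STATE_FIELDS)

# State indices.
S_CAMKII, S_PKA, S_RAFP, S_MEK, S_MEKPP, S_ERK, S_ERKPP = 0, 1, 2, 3, 4, 5, 6
S_TAG1, S_TAG2, S_TAG3, S_PCK2, S_PERK, S_PKM, S_W, S_PLIM = 7, 8, 9, 10, 11, 12, 13, 14

_FRAC_MASK = np.zeros(N_STATE, dtype=np.bool_)
for _f in ("PKA_act", "Tag1", "Tag2", "Tag3", "P_CK2", "P_ERK"):
    _FRAC_MASK[STATE_FIELDS.index(_f)] = True

EV_TETANUS = 0
EV_REACTIVATION = 1


@njit(cache=True)
def _rhs(y, ca, camp, kfraf, inh_fac, pv, plim_w_decay, dy):
    """Derivatives of the 15 state variables into ``dy``; returns TAG."""
    # CaMKII: 4th-power Hill of Ca, first-order deactivation, autoactivation.
    ca4 = ca * ca * ca * ca
    K4 = pv[I_K_CASYN] ** 4
    f1 = ca4 / (ca4 + K4)
    ck = y[S_CAMKII]
    d_ck = pv[I_K_FCK2] * f1 - ck / pv[I_TAU_CK2]
    if pv[I_K_CAMKII] != 0.0:
        ck2 = ck * ck
        d_ck += pv[I_K_CAMKII] * ck2 / (ck2 + pv[I_K_K_CAMKII] ** 2)
    dy[S_CAMKII] = d_ck

    # PKA: relaxation toward a 2nd-power Hill of cAMP.
    c2 = camp * camp
    f3 = c2 / (c2 + pv[I_K_CAMP] ** 2)
    dy[S_PKA] = (f3 - y[S_PKA]) / pv[I_TAU_PKA]

    # Raf-MEK-ERK cascade with conservation-derived pools.
    rafp = y[S_RAFP]
    raf = pv[I_RAF_TOT] - rafp
    dy[S_RAFP] = kfraf * raf - pv[I_K_BRAF] * rafp

    mek = y[S_MEK]
    mekpp = y[S_MEKPP]
    mekp = pv[I_MEK_TOT] - mek - mekpp
    Km = pv[I_K_MEK]
    dy[S_MEK] = (- pv[I_K_FMEK] * rafp * mek / (mek + Km)
                 + pv[I_K_BMEK] * mekp / (mekp + Km))
    dy[S_MEKPP] = (pv[I_K_FMEK] * rafp * mekp / (mekp + Km)
                   - pv[I_K_BMEK] * mekpp / (mekpp + Km))

    erk = y[S_ERK]
    erkpp = y[S_ERKPP]
    erkp = pv[I_ERK_TOT] - erk - erkpp
    Ke = pv[I_K_ERK]
    dy[S_ERK] = (- pv[I_K_FERK] * mekpp * erk / (erk + Ke)
                 + pv[I_K_BERK] * erkp / (erkp + Ke))
    dy[S_ERKPP] = (pv[I_K_FERK] * mekpp * erkp / (erkp + Ke)
                   - pv[I_K_BERK] * erkpp / (erkpp + Ke))

    # Tag sites (CaMKII, PKA, ERKPP kinases).
    dy[S_TAG1] = pv[I_K_PHOS1] * ck * (1.0 - y[S_TAG1]) - pv[I_K_DEPH1] * y[S_TAG1]
    dy[S_TAG2] = pv[I_K_PHOS2] * y[S_PKA] * (1.0 - y[S_TAG2]) - pv[I_K_DEPH2] * y[S_TAG2]
    dy[S_TAG3] = pv[I_K_PHOS3] * erkpp * (1.0 - y[S_TAG3]) - pv[I_K_DEPH3] * y[S_TAG3]

    # PKMzeta synthesis sites and activity; autoactivation sees the full
    # PKM_act (inhibition is effector-level only).
    dy[S_PCK2] = pv[I_K_PHOS4] * ck * (1.0 - y[S_PCK2]) - pv[I_K_DEPH4] * y[S_PCK2]
    dy[S_PERK] = pv[I_K_PHOS5] * erkpp * (1.0 - y[S_PERK]) - pv[I_K_DEPH5] * y[S_PERK]
    pkm = y[S_PKM]
    d_pkm = pv[I_K_TRANSPKM] * y[S_PCK2] * y[S_PERK] + pv[I_K_TRANSBASPKM] \
        - pv[I_K_DPKM] * pkm
    if pv[I_K_PKM] != 0.0:
        p2 = pkm * pkm
        d_pkm += pv[I_K_PKM] * p2 / (p2 + pv[I_K_K_PKM] ** 2)
    dy[S_PKM] = d_pkm

    # Weight and limiting protein; TAG gets the additive PKMzeta coupling.
    pkm_eff = inh_fac * pkm
    tag = y[S_TAG1] * y[S_TAG2] * y[S_TAG3] + pv[I_K_TPKM] * pkm_eff
    plim = y[S_PLIM]
    sat = plim / (plim + pv[I_K_LIM])
    dy[S_W] = (pv[I_K_LTP] * tag * pv[I_PRP] * pkm_eff * sat
               + pv[I_K_LTPBAS] - y[S_W] / pv[I_TAU_LTP])
    if plim_w_decay:
        decay = y[S_W] / pv[I_TAU_PL]
    else:
        decay = plim / pv[I_TAU_PL]
    dy[S_PLIM] = - pv[I_K_PL] * tag * pv[I_PRP] * sat + pv[I_K_PLBAS] - decay
    return tag


@njit(cache=True)
def _clamp(y, frac_mask):
    """Clamp discretization-error excursions; return number of clamps."""
    n = 0
    for j in range(y.shape[0]):
        if y[j] < 0.0:
            y[j] = 0.0
            n += 1
        elif frac_mask[j] and y[j] > 1.0:
            y[j] = 1.0
            n += 1
    return n


@njit(cache=True)
def integrate(y0, t0, n_steps, dt, pv, ev_step, ev_kind, tet_amp_scale,
              inh_start, inh_end, inh_frac, record_stride, plim_w_decay,
              use_rk4):
    """Integrate ``n_steps`` of size ``dt`` from ``t0``.

    ``ev_step``/``ev_kind`` are step-grid-aligned stimulus events within this
    segment, sorted by step.  A single inhibition window is supported
    (``inh_start == inh_end`` means none).  Records every ``record_stride``
    steps (state *before* the step, i.e. at the sample time) plus the final
    state; the driver guarantees ``n_steps % record_stride == 0``.

    Returns (times, states, forcing, tag, event_W, clamp_count, y_final).
    """
    n_rec = n_steps // record_stride + 1
    times = np.empty(n_rec)
    Y = np.empty((n_rec, N_STATE))
    F = np.empty((n_rec, 3))
    TAG = np.empty(n_rec)
    ev_W = np.empty(ev_step.shape[0])

    y = y0.copy()
    dy = np.empty(N_STATE)
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    ytmp = np.empty(N_STATE)

    ca_dur_steps = int(round(pv[I_CA_DUR] / dt))
    pulse_steps = int(round(pv[I_D_CAMP] / dt))

    # Active-channel bookkeeping: amplitude + exclusive end step.
    ca_amp = 0.0
    ca_end = -1
    camp_amp = 0.0
    camp_end = -1
    raf_add = 0.0
    raf_end = -1

    clamps = 0
    ev_i = 0
    rec = 0
    for i in range(n_steps + 1):
        t = t0 + i * dt

        # Event onsets at this step.
        while ev_i < ev_step.shape[0] and ev_step[ev_i] == i:
            ev_W[ev_i] = y[S_W]
            if ev_kind[ev_i] == EV_TETANUS:
                ca_amp = tet_amp_scale * pv[I_A_CASYN]
                camp_amp = tet_amp_scale * pv[I_A_CAMP]
                raf_add = tet_amp_scale * pv[I_A_STIM]
            else:
                w5 = y[S_W] ** 5
                h = w5 / (w5 + pv[I_K_W] ** 5)
                s = pv[I_REACT_AMP_SCALE]
                ca_amp = s * pv[I_A_CASYN] * h
                camp_amp = s * pv[I_A_CAMP] * h
                raf_add = s * pv[I_A_STIM] * h
            ca_end = i + ca_dur_steps
            camp_end = i + pulse_steps
            raf_end = i + pulse_steps
            ev_i += 1

        # Forcing with basal floors.
        ca = ca_amp if i < ca_end else 0.0
        if ca < pv[I_CA_BAS]:
            ca = pv[I_CA_BAS]
        camp = camp_amp if i < camp_end else 0.0
        if camp < pv[I_CAMP_BAS]:
            camp = pv[I_CAMP_BAS]
        kfraf = pv[I_K_FBASRAF] + (raf_add if i < raf_end else 0.0)

        inh_fac = 1.0
        if inh_start < inh_end and inh_start <= t < inh_end:
            inh_fac = 1.0 - inh_frac

        if i % record_stride == 0:
            tag_now = _rhs(y, ca, camp, kfraf, inh_fac, pv, plim_w_decay, dy)
            times[rec] = t
            Y[rec] = y
            F[rec, 0] = ca
            F[rec, 1] = camp
            F[rec, 2] = kfraf
            TAG[rec] = tag_now
            rec += 1
        if i == n_steps:
            break

        if use_rk4:
            _rhs(y, ca, camp, kfraf, inh_fac, pv, plim_w_decay, k1)
            for j in range(N_STATE):
                ytmp[j] = y[j] + 0.5 * dt * k1[j]
            _rhs(ytmp, ca, camp, kfraf, inh_fac, pv, plim_w_decay, k2)
            for j in range(N_STATE):
                ytmp[j] = y[j] + 0.5 * dt * k2[j]
            _rhs(ytmp, ca, camp, kfraf, inh_fac, pv, plim_w_decay, k3)
            for j in range(N_STATE):
                ytmp[j] = y[j] + dt * k3[j]
            _rhs(ytmp, ca, camp, kfraf, inh_fac, pv, plim_w_decay, k4)
            for j in range(N_STATE):
                y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        else:
            _rhs(y, ca, camp, kfraf, inh_fac, pv, plim_w_decay, dy)
            for j in range(N_STATE):
                y[j] += dt * dy[j]
        clamps += _clamp(y, _FRAC_MASK)

    return times, Y, F, TAG, ev_W, clamps, y
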