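"""Right-hand sides of the model equations.

This module is the readable reference implementation of the ODE system: the
CaMKII / PKA / Raf-MEK-ERK signaling equations, synaptic-tag phosphorylation,
PKMzeta synthesis, and synaptic-weight dynamics, with the variant-dependent
positive-feedback terms.  The time-stepping hot loop lives in
:mod:`ltpsim._kernel`; a unit test asserts that both evaluate identical
derivatives, so this module doubles as the kernel's oracle.

State variables (15):

====================  =======================================================
``CaMKII_act``        active CaMKII, uM
``PKA_act``           PKA activity fraction (relaxes toward a Hill function
                      of cAMP, hence dimensionless in [0, 1))
``RAFP``              phosphorylated (active) Raf, uM; RAF by conservation
``MEK``, ``MEKPP``    unphosphorylated / doubly phosphorylated MEK, uM;
                      singly phosphorylated MEKP by conservation
``ERK``, ``ERKPP``    likewise for ERK
``Tag1..Tag3``        fractional phosphorylation of the three tag sites
                      (substrates of CaMKII, PKA, ERKPP respectively)
``P_CK2``, ``P_ERK``  fractional phosphorylation of the two translation-
                      regulatory sites driving PKMzeta synthesis
``PKM_act``           active PKMzeta, uM
``W``                 synaptic weight, arbitrary units
``P_lim``             limiting synaptic protein, uM
====================  =======================================================

Mass conservation is exact by construction: RAF = RAF_TOT - RAFP,
MEKP = MEK_TOT - MEK - MEKPP, ERKP = ERK_TOT - ERK - ERKPP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet

__all__ = [
    "STATE_FIELDS",
    "ModelState",
    "Forcing",
    "hill",
    "derivatives",
    "tag_level",
]

STATE_FIELDS: tuple[str, ...] = (
    "CaMKII_act", "PKA_act",
    "RAFP", "MEK", "MEKPP", "ERK", "ERKPP",
    "Tag1", "Tag2", "Tag3",
    "P_CK2", "P_ERK", "PKM_act",
    "W", "P_lim",
)

_FRACTIONAL = ("PKA_act", "Tag1", "Tag2", "Tag3", "P_CK2", "P_ERK")


@dataclass
class ModelState:
    """The 15 dynamic variables at one instant (units in the module docstring)."""

    CaMKII_act: float = 0.0
    PKA_act: float = 0.0
    RAFP: float = 0.0
    MEK: float = 0.0
    MEKPP: float = 0.0
    ERK: float = 0.0
    ERKPP: float = 0.0
    Tag1: float = 0.0
    Tag2: float = 0.0
    Tag3: float = 0.0
    P_CK2: float = 0.0
    P_ERK: float = 0.0
    PKM_act: float = 0.0
    W: float = 0.0
    P_lim: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_FIELDS),):
            raise ValueError(f"expected shape ({len(STATE_FIELDS)},), got {y.shape}")
        return cls(**dict(zip(STATE_FIELDS, y)))

    # conservation-derived pools -------------------------------------------
    def RAF(self, p: ParameterSet) -> float:
        return p.RAF_TOT - self.RAFP

    def MEKP(self, p: ParameterSet) -> float:
        return p.MEK_TOT - self.MEK - self.MEKPP

    def ERKP(self, p: ParameterSet) -> float:
        return p.ERK_TOT - self.ERK - self.ERKPP

    def check_invariants(self, p: ParameterSet, tol: float = 1e-9) -> None:
        for f in _FRACTIONAL:
            v = getattr(self, f)
            if not -tol <= v <= 1.0 + tol:
                raise ValueError(f"{f} = {v} outside [0, 1]")
        for f in ("CaMKII_act", "RAFP", "MEK", "MEKPP", "ERK", "ERKPP",
                  "PKM_act", "W", "P_lim"):
            if getattr(self, f) < -tol:
                raise ValueError(f"{f} = {getattr(self, f)} negative")
        for name, pool in (("RAF", self.RAF(p)), ("MEKP", self.MEKP(p)),
                           ("ERKP", self.ERKP(p))):
            if pool < -tol:
                raise ValueError(f"conserved pool {name} = {pool} negative")


@dataclass
class Forcing:
    """Externally driven quantities: synaptic Ca2+, cAMP, and the Raf
    activation rate constant.  Floors are the basal values."""

    Ca_syn: float
    cAMP: float
    k_fRaf: float


def hill(x: float, K: float, n: int) -> float:
    """Hill function ``x**n / (x**n + K**n)``, in [0, 1), increasing in x."""
    if K <= 0:
        raise ValueError("Hill constant K must be > 0")
    if x < 0:
        raise ValueError("Hill input x must be >= 0")
    xn = x ** n
    return xn / (xn + K ** n)


def basal_forcing(p: ParameterSet) -> Forcing:
    return Forcing(Ca_syn=p.Ca_bas, cAMP=p.cAMP_bas, k_fRaf=p.k_fbasRaf)


def camkii_rate(s: ModelState, f: Forcing, p: ParameterSet) -> float:
    """d[CaMKII_act]/dt: Ca-driven activation (4th-power Hill of Ca, the
    minimal stand-in for cooperative CaM-Ca4 binding), first-order
    deactivation, plus quadratic-Hill autoactivation when k_CaMKII > 0."""
    f1 = hill(f.Ca_syn, p.K_Casyn, 4)
    rate = p.k_fck2 * f1 - s.CaMKII_act / p.tau_ck2
    if p.k_CaMKII != 0.0:
        rate += p.k_CaMKII * hill(s.CaMKII_act, p.K_CaMKII, 2)
    return rate


def pka_rate(s: ModelState, f: Forcing, p: ParameterSet) -> float:
    """d[PKA_act]/dt: relaxation toward a second-power Hill of cAMP with time
    constant tau_PKA (two cAMP molecules bind a PKA regulatory subunit)."""
    f3 = hill(f.cAMP, p.K_cAMP, 2)
    return (f3 - s.PKA_act) / p.tau_PKA


def raf_mek_erk_rates(s: ModelState, f: Forcing, p: ParameterSet
                      ) -> tuple[float, float, float, float, float]:
    """Rates for (RAFP, MEK, MEKPP, ERK, ERKPP).

    Raf activation is first-order in the conserved inactive pool; the MEK and
    ERK double-phosphorylation cycles use saturable Michaelis-Menten terms
    with only the doubly phosphorylated forms active.  Phosphatases are not
    modeled explicitly (first-order-in-substrate saturable back reactions).
    """
    RAF = s.RAF(p)
    MEKP = s.MEKP(p)
    ERKP = s.ERKP(p)
    if min(RAF, MEKP, ERKP) < -1e-9:
        raise ValueError("conserved pool went negative")
    d_RAFP = f.k_fRaf * RAF - p.k_bRaf * s.RAFP
    d_MEK = (- p.k_fMEK * s.RAFP * s.MEK / (s.MEK + p.K_MEK)
             + p.k_bMEK * MEKP / (MEKP + p.K_MEK))
    d_MEKPP = (p.k_fMEK * s.RAFP * MEKP / (MEKP + p.K_MEK)
               - p.k_bMEK * s.MEKPP / (s.MEKPP + p.K_MEK))
    d_ERK = (- p.k_fERK * s.MEKPP * s.ERK / (s.ERK + p.K_ERK)
             + p.k_bERK * ERKP / (ERKP + p.K_ERK))
    d_ERKPP = (p.k_fERK * s.MEKPP * ERKP / (ERKP + p.K_ERK)
               - p.k_bERK * s.ERKPP / (s.ERKPP + p.K_ERK))
    return d_RAFP, d_MEK, d_MEKPP, d_ERK, d_ERKPP


def tag_rates(s: ModelState, p: ParameterSet) -> tuple[float, float, float]:
    """Rates for the three tag sites: kinase-driven phosphorylation of the
    free fraction, first-order dephosphorylation."""
    d1 = p.k_phos1 * s.CaMKII_act * (1.0 - s.Tag1) - p.k_deph1 * s.Tag1
    d2 = p.k_phos2 * s.PKA_act * (1.0 - s.Tag2) - p.k_deph2 * s.Tag2
    d3 = p.k_phos3 * s.ERKPP * (1.0 - s.Tag3) - p.k_deph3 * s.Tag3
    return d1, d2, d3


def tag_level(s: ModelState, p: ParameterSet, effective_pkm: float | None = None
              ) -> float:
    """TAG = Tag1 * Tag2 * Tag3, plus the additive PKMzeta coupling term
    k_TPKM * PKM when the tag-coupled variant enables it.  ``effective_pkm``
    is PKM_act after any pharmacological inhibition scaling."""
    if effective_pkm is None:
        effective_pkm = s.PKM_act
    return s.Tag1 * s.Tag2 * s.Tag3 + p.k_TPKM * effective_pkm


def pkm_rates(s: ModelState, p: ParameterSet) -> tuple[float, float, float]:
    """Rates for (P_CK2, P_ERK, PKM_act).

    PKMzeta synthesis is proportional to the product of the two
    translation-site phosphorylations (CaMKII- and ERK-dependent), plus basal
    synthesis and first-order deactivation; autoactivation (quadratic Hill)
    is added when k_PKM > 0.  Autoactivation always sees the full PKM_act:
    pharmacological inhibition blocks effector action, not translation.
    """
    d4 = p.k_phos4 * s.CaMKII_act * (1.0 - s.P_CK2) - p.k_deph4 * s.P_CK2
    d5 = p.k_phos5 * s.ERKPP * (1.0 - s.P_ERK) - p.k_deph5 * s.P_ERK
    d_pkm = (p.k_transpkm * s.P_CK2 * s.P_ERK + p.k_transbaspkm
             - p.k_dpkm * s.PKM_act)
    if p.k_PKM != 0.0:
        d_pkm += p.k_PKM * hill(s.PKM_act, p.K_PKM, 2)
    return d4, d5, d_pkm


def weight_rates(s: ModelState, p: ParameterSet, effective_pkm: float,
                 plim_weight_decay: bool = False) -> tuple[float, float]:
    """Rates for (W, P_lim).

    dW/dt multiplies TAG, PRP, effective PKMzeta activity and a saturable
    function of the limiting protein, plus basal production and first-order
    decay.  P_lim is consumed by the same TAG*PRP drive (PKMzeta excluded:
    it acts on AMPAR incorporation, and P_lim is not AMPAR) and replenished
    at a basal rate.  The last P_lim term is -P_lim/tau_Pl by default (the
    decay reading; the alternative -W/tau_Pl reading is behind the
    ``plim_weight_decay`` flag and leaves basal P_lim unconstrained).
    """
    if effective_pkm < 0:
        raise ValueError("effective_pkm must be >= 0")
    TAG = tag_level(s, p, effective_pkm)
    sat = s.P_lim / (s.P_lim + p.K_lim)
    d_W = (p.k_ltp * TAG * p.PRP * effective_pkm * sat
           + p.k_ltpbas - s.W / p.tau_ltp)
    decay = s.W / p.tau_Pl if plim_weight_decay else s.P_lim / p.tau_Pl
    d_Plim = - p.k_Pl * TAG * p.PRP * sat + p.k_Plbas - decay
    return d_W, d_Plim


def derivatives(s: ModelState, f: Forcing, p: ParameterSet,
                effective_pkm: float | None = None,
                plim_weight_decay: bool = False) -> np.ndarray:
    """One consistent derivative evaluation of the full state, in
    :data:`STATE_FIELDS` order (units per minute).  Pure function."""
    if effective_pkm is None:
        effective_pkm = s.PKM_act
    d = np.empty(len(STATE_FIELDS))
    d[0] = camkii_rate(s, f, p)
    d[1] = pka_rate(s, f, p)
    d[2:7] = raf_mek_erk_rates(s, f, p)
    d[7:10] = tag_rates(s, p)
    d[10:13] = pkm_rates(s, p)
    d[13:15] = weight_rates(s, p, effective_pkm, plim_weight_decay)
    return d
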