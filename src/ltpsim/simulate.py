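"""Time-stepping driver: initialization, equilibration, protocol runs, and
trajectory recording.

The reference integration scheme is forward Euler at dt = 10 ms
(1/6000 min); classical RK4 is available as a numerical oracle through
``SimulationConfig.integrator = "rk4"``.  Scheduled parameter changes split a
run into segments integrated back-to-back with an updated parameter vector;
everything else (events, inhibition windows) is handled inside the compiled
kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernel
from .dynamics import STATE_FIELDS, Forcing, ModelState, derivatives, basal_forcing
from .params import ParameterSet, VariantId, check_variant_consistency
from .stimulation import (EventTrain, Protocol, StimEvent, TETANUS,
                          REACTIVATION_EVENT, tetanus_train)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "initialize",
    "equilibrate",
    "run",
    "snapshot_upper_state",
]

DT_STANDARD = 1.0 / 6000.0  # 10 ms in minutes

_FORCING_FIELDS = ("Ca_syn", "cAMP", "k_fRaf")


class EquilibrationError(RuntimeError):
    """Raised when basal equilibration has not converged."""


class UpperStateError(RuntimeError):
    """Raised when a variant fails to reach a potentiated state."""


@dataclass
class SimulationConfig:
    """Integrator settings.

    ``record_stride`` counts steps between recorded samples; the default
    resolves 1 s of model time at the standard dt, fine enough for the 3-s Ca
    pulses.  ``equilibration`` must cover at least two simulated days.
    """

    t_end: float = 720.0
    dt: float = DT_STANDARD
    record_stride: int = 100
    integrator: str = "euler"
    seed: int = 0
    equilibration: float = 2880.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError("integrator must be 'euler' or 'rk4'")
        if self.equilibration < 2880.0:
            raise ValueError("equilibration must be >= 2880 min (two days)")

    def validate_grid(self, p: ParameterSet) -> None:
        """Square-wave channel durations must sit exactly on the step grid."""
        for name, dur in (("Ca_dur", p.Ca_dur), ("d_cAMP", p.d_cAMP)):
            steps = dur / self.dt
            if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
                raise ValueError(
                    f"{name} = {dur} min is not an integer number of steps at dt = {self.dt}"
                )


@dataclass
class Trajectory:
    """Recorded time series of one simulation.

    ``states`` has one row per recorded time, columns in
    :data:`~ltpsim.dynamics.STATE_FIELDS` order; ``forcing`` columns are
    (Ca_syn, cAMP, k_fRaf); ``tag`` is the derived TAG level.  ``events``
    logs every stimulus delivered, with ``event_W`` the synaptic weight at
    each event's onset (the quantity that sets reactivation amplitudes).
    """

    times: np.ndarray
    states: np.ndarray
    forcing: np.ndarray
    tag: np.ndarray
    events: EventTrain
    event_W: np.ndarray
    clamp_count: int
    final_state: ModelState
    metadata: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        """Time series of a state field, forcing field, or ``"TAG"``."""
        if name == "TAG":
            return self.tag
        if name in STATE_FIELDS:
            return self.states[:, STATE_FIELDS.index(name)]
        if name in _FORCING_FIELDS:
            return self.forcing[:, _FORCING_FIELDS.index(name)]
        raise KeyError(f"unknown series {name!r}")

    def at(self, name: str, t: float) -> float:
        """Value of a series at the recorded time nearest ``t``."""
        if not self.times[0] <= t <= self.times[-1]:
            raise ValueError(f"t = {t} outside trajectory [{self.times[0]}, {self.times[-1]}]")
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.series(name)[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        for j, name in enumerate(_FORCING_FIELDS):
            df[name] = self.forcing[:, j]
        df["TAG"] = self.tag
        return df


def initialize(p: ParameterSet, variant: VariantId) -> ModelState:
    """All dynamic variables at 1e-4 (uM or arbitrary units); the
    conservation pools then hold RAF_TOT - 1e-4 etc., all nonnegative."""
    check_variant_consistency(p, variant)
    return ModelState(**{f: 1e-4 for f in STATE_FIELDS})


def _pack(p: ParameterSet) -> np.ndarray:
    from .params import PARAM_NAMES
    return np.array([getattr(p, n) for n in PARAM_NAMES], dtype=float)


def _segment_run(y, t0, n_steps, dt, pv, ev_step, ev_kind, tet_scale,
                 inh, record_stride, plim_w_decay, use_rk4):
    inh_s, inh_e, inh_f = (inh.start, inh.end, inh.fraction) if inh else (0.0, 0.0, 0.0)
    return _kernel.integrate(
        y, t0, n_steps, dt, pv,
        ev_step.astype(np.int64), ev_kind.astype(np.int64), tet_scale,
        inh_s, inh_e, inh_f, record_stride, plim_w_decay, use_rk4,
    )


def run(initial: ModelState, protocol: Protocol, p: ParameterSet,
        variant: VariantId, cfg: SimulationConfig) -> Trajectory:
    """Integrate a protocol from ``initial`` over [0, cfg.t_end].

    Deterministic: identical (initial, protocol, parameters, variant, cfg)
    give bit-identical trajectories.  Reactivation randomness is controlled
    entirely by ``protocol.reactivation_seed``.
    """
    check_variant_consistency(p, variant)
    cfg.validate_grid(p)
    p = p.copy()
    dt = cfg.dt
    stride = cfg.record_stride
    use_rk4 = cfg.integrator == "rk4"

    # Align the horizon to the record grid.
    n_total = int(round(cfg.t_end / dt))
    n_total -= n_total % stride
    if n_total <= 0:
        raise ValueError("t_end too short for one record stride")
    t_end = n_total * dt

    events = protocol.all_events(p, t_end)
    ev_onsets = np.array([e.onset for e in events.events], dtype=float)
    ev_kinds = np.array([e.kind for e in events.events], dtype=np.int64)
    # Snap onsets to the step grid once; segment membership uses the snapped
    # step so boundary events land in the segment that integrates them.
    ev_steps_abs = np.round(ev_onsets / dt).astype(np.int64)

    # Segment boundaries at scheduled parameter changes, snapped to the
    # record grid so every segment records a whole number of strides.
    changes = sorted(protocol.changes, key=lambda c: c.time)
    block = stride * dt
    bounds = [0]
    for c in changes:
        b = int(round(c.time / block)) * stride
        if not 0 < b < n_total:
            raise ValueError(f"scheduled change at t = {c.time} outside the run")
        bounds.append(b)
    bounds.append(n_total)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("scheduled changes must be strictly ordered within the run")

    times_l, Y_l, F_l, TAG_l = [], [], [], []
    ev_W = np.full(ev_onsets.shape[0], np.nan)
    clamps = 0
    y = initial.to_array()
    for k, (b1, b2) in enumerate(zip(bounds, bounds[1:])):
        if k > 0:
            setattr(p, changes[k - 1].target, changes[k - 1].new_value)
        pv = _pack(p)
        seg_t0 = b1 * dt
        sel = np.flatnonzero((ev_steps_abs >= b1) & (ev_steps_abs < b2))
        seg_steps = ev_steps_abs[sel] - b1
        order = np.argsort(seg_steps, kind="stable")
        sel = sel[order]
        t_s, Y_s, F_s, TAG_s, evW_s, c_s, y = _segment_run(
            y, seg_t0, b2 - b1, dt, pv, seg_steps[order], ev_kinds[sel],
            protocol.tetanus_amp_scale, protocol.inhibition, stride,
            protocol.plim_weight_decay, use_rk4)
        ev_W[sel] = evW_s
        clamps += int(c_s)
        drop = 1 if k > 0 else 0  # boundary sample already recorded
        times_l.append(t_s[drop:])
        Y_l.append(Y_s[drop:])
        F_l.append(F_s[drop:])
        TAG_l.append(TAG_s[drop:])

    # Recorded times on the exact global grid (bit-identical whether or not
    # scheduled changes split the run into segments).
    times = np.arange(n_total // stride + 1, dtype=float) * (stride * dt)
    traj = Trajectory(
        times=times,
        states=np.vstack(Y_l),
        forcing=np.vstack(F_l),
        tag=np.concatenate(TAG_l),
        events=events,
        event_W=ev_W,
        clamp_count=clamps,
        final_state=ModelState.from_array(y),
        metadata={
            "variant": variant.value,
            "dt": dt,
            "record_stride": stride,
            "integrator": cfg.integrator,
            "seed": cfg.seed,
            "t_end": t_end,
        },
    )
    return traj


def _basal_pkm_fixed_point(s: ModelState, p: ParameterSet) -> float:
    """Smallest nonnegative root of the PKMzeta synthesis balance, given the
    equilibrated translation-site phosphorylations."""
    prod = p.k_transpkm * s.P_CK2 * s.P_ERK + p.k_transbaspkm

    def g(x: float) -> float:
        fb = p.k_PKM * x * x / (x * x + p.K_PKM ** 2) if p.k_PKM else 0.0
        return prod + fb - p.k_dpkm * x

    x0 = prod / p.k_dpkm  # feedback-free balance
    # March upward from 0 until the balance changes sign, then bisect; the
    # first crossing is the basal (lowest) fixed point even when the
    # autoactivation term makes the balance bistable.
    step = max(x0 * 0.25, 1e-6)
    a, b = 0.0, step
    while g(b) > 0:
        a, b = b, b + step
        if b > 1e4:
            raise EquilibrationError("no basal PKM fixed point found")
    return float(brentq(g, a, b, xtol=1e-14, rtol=1e-14))


def _basal_w_fixed_point(s: ModelState, p: ParameterSet, pkm: float) -> float:
    tag = s.Tag1 * s.Tag2 * s.Tag3 + p.k_TPKM * pkm
    sat = s.P_lim / (s.P_lim + p.K_lim)
    return p.tau_ltp * (p.k_ltp * tag * p.PRP * pkm * sat + p.k_ltpbas)


def equilibrate(state: ModelState, p: ParameterSet, variant: VariantId,
                duration: float = 2880.0, dt: float = DT_STANDARD,
                drift_tol: float = 1e-6) -> ModelState:
    """Relax to the basal state under basal forcing with no stimulus events.

    Integrates for ``duration`` (>= two simulated days), checks that every
    fast variable's relative drift over the last simulated hour is below
    ``drift_tol``, then overwrites the two slowest variables -- W and
    PKM_act -- with their closed-form basal fixed points determined by the
    equilibrated fast variables (synthesis balance for PKMzeta, then
    production/decay balance for W).
    """
    if duration < 2880.0:
        raise ValueError("equilibration must last >= 2880 min")
    check_variant_consistency(p, variant)
    pv = _pack(p)
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(1.0 / dt)))  # 1-min samples
    n_steps -= n_steps % stride
    t_s, Y_s, _, _, _, _, y = _segment_run(
        state.to_array(), 0.0, n_steps, dt, pv,
        np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 1.0,
        None, stride, False, False)

    slow = {STATE_FIELDS.index("W"), STATE_FIELDS.index("PKM_act")}
    i_hour = int(np.argmin(np.abs(t_s - (t_s[-1] - 60.0))))
    for j, name in enumerate(STATE_FIELDS):
        if j in slow:
            continue
        # Floor the reference at the 1e-4 initialization scale: a variable
        # decaying toward exactly zero never converges relative to itself.
        ref = max(abs(Y_s[-1, j]), 1e-4)
        drift = abs(Y_s[-1, j] - Y_s[i_hour, j]) / ref
        if drift > drift_tol:
            raise EquilibrationError(
                f"{name} still drifting after {duration} min "
                f"(relative drift {drift:.2e} over the last hour)")

    out = ModelState.from_array(y)
    out.PKM_act = _basal_pkm_fixed_point(out, p)
    out.W = _basal_w_fixed_point(out, p, out.PKM_act)
    return out


def standard_induction(t0: float = 10.0) -> EventTrain:
    """The standard induction protocol: three tetani, 5-min ISI."""
    return tetanus_train(3, 5.0, t0)


def snapshot_upper_state(p: ParameterSet, variant: VariantId,
                         cfg: SimulationConfig | None = None,
                         settle: float = 2000.0) -> ModelState:
    """Equilibrate, induce L-LTP, and let the variant settle into its
    maintained upper state; the returned state seeds inhibition experiments.

    Raises :class:`UpperStateError` if the weight at the settle time is not
    at least 1.5x basal (no upper state -- e.g. the no-feedback variant).
    """
    if cfg is None:
        cfg = SimulationConfig()
    basal = equilibrate(initialize(p, variant), p, variant,
                        duration=cfg.equilibration, dt=cfg.dt)
    tet = standard_induction()
    proto = Protocol(tetani=tet, reactivation=variant.has_reactivation,
                     reactivation_seed=cfg.seed)
    t_last = tet.onsets()[-1]
    run_cfg = SimulationConfig(t_end=t_last + settle, dt=cfg.dt,
                               record_stride=cfg.record_stride, seed=cfg.seed,
                               equilibration=cfg.equilibration)
    traj = run(basal, proto, p, variant, run_cfg)
    W_end = traj.final_state.W
    if W_end < 1.5 * basal.W:
        raise UpperStateError(
            f"variant {variant.value}: W = {W_end:.3g} at settle time is not "
            f">= 1.5x basal ({basal.W:.3g}); no upper state reached")
    return traj.final_state


def reference_derivatives(state: ModelState, forcing: Forcing, p: ParameterSet,
                          effective_pkm: float | None = None,
                          plim_weight_decay: bool = False) -> np.ndarray:
    """Pure-Python derivative evaluation (oracle for the compiled kernel)."""
    return derivatives(state, forcing, p, effective_pkm, plim_weight_decay)
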