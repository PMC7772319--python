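"""Summary quantities: L-LTP magnitude, one-at-a-time relative sensitivities,
kinetic time-course summaries, and bistable-state classification.

The response measure R throughout is the percent increase of synaptic weight
over its pre-stimulus baseline, assessed 2 h after the last tetanus for
non-bistable runs and 50 h post-stimulus for bistable ones.  The relative
sensitivity of R to a parameter p_i perturbed by a fraction (standard +/-15%)
is S_i = |dR/R| / |dp_i/p_i|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import ParameterSet, VariantId, perturb, sensitivity_registry
from .simulate import SimulationConfig, Trajectory, equilibrate, initialize, run
from .stimulation import Protocol, TETANUS

__all__ = [
    "LtpMeasurement",
    "ScanJob",
    "ltp_magnitude",
    "sensitivity",
    "sensitivity_scan",
    "decay_time_constant",
    "elevation_duration",
    "classify_state",
    "minimum_inhibition_duration",
]


@dataclass(frozen=True)
class LtpMeasurement:
    """L-LTP magnitude: percent increase of W over its pre-stimulus value."""

    W_pre: float
    W_assess: float
    t_assess: float
    percent: float


def ltp_magnitude(traj: Trajectory, t_last_tetanus: float | None = None,
                  delay: float = 120.0) -> LtpMeasurement:
    """Percent increase of W at ``t_last_tetanus + delay`` over the value
    sampled immediately before the first tetanus.

    ``t_last_tetanus`` defaults to the last tetanus logged in the trajectory;
    for an unstimulated trajectory both reference times fall at the start and
    the measurement is ~0%.
    """
    tets = traj.events.onsets(TETANUS)
    if t_last_tetanus is None:
        t_last_tetanus = float(tets[-1]) if tets.size else 0.0
    t_first = float(tets[0]) if tets.size else traj.times[0]
    pre_idx = np.searchsorted(traj.times, t_first) - 1
    W = traj.series("W")
    W_pre = float(W[max(pre_idx, 0)])
    t_assess = t_last_tetanus + delay
    if not traj.times[0] <= t_assess <= traj.times[-1]:
        raise ValueError(f"assessment time {t_assess} outside trajectory")
    W_assess = traj.at("W", t_assess)
    if W_pre <= 0:
        raise ValueError("pre-stimulus W must be positive")
    return LtpMeasurement(W_pre, W_assess, t_assess,
                          100.0 * (W_assess - W_pre) / W_pre)


def sensitivity(R_base: float, R_pert: float, fraction: float) -> float:
    """Relative sensitivity |(R_pert - R_base)/R_base| / |fraction|."""
    if R_base == 0:
        raise ZeroDivisionError("sensitivity undefined for zero baseline response")
    if fraction == 0:
        raise ZeroDivisionError("sensitivity undefined for zero perturbation")
    return abs((R_pert - R_base) / R_base) / abs(fraction)


@dataclass
class ScanJob:
    """One assessed simulation of the sensitivity scan."""

    label: str
    variant: VariantId
    params: ParameterSet
    protocol: Protocol
    cfg: SimulationConfig
    delay: float  # assessment delay after the last tetanus, min


def _job_response(job: ScanJob, p: ParameterSet) -> float:
    from .simulate import EquilibrationError

    # A perturbed parameter set can lose its basal fixed point (e.g. a Hill
    # constant lowered enough that the feedback switch turns on by itself);
    # the pre-stimulus state then converges on a slower time scale, so extend
    # the equilibration rather than fail the row.
    duration = job.cfg.equilibration
    while True:
        try:
            basal = equilibrate(initialize(p, job.variant), p, job.variant,
                                duration=duration, dt=job.cfg.dt)
            break
        except EquilibrationError:
            duration *= 2
            if duration > 16 * job.cfg.equilibration:
                raise
    traj = run(basal, job.protocol, p, job.variant, job.cfg)
    return ltp_magnitude(traj, delay=job.delay).percent


def sensitivity_scan(jobs: list[ScanJob], names: list[str] | None = None,
                     fraction: float = 0.15) -> pd.DataFrame:
    """One-at-a-time +/-``fraction`` scan over each job's registry.

    Every perturbed run repeats the full pipeline (equilibration, induction,
    assessment) with the perturbed parameter set and the *same* reactivation
    seed as the baseline, so S_i reflects the parameter change rather than
    event noise.  A zero-valued parameter is unchanged by a multiplicative
    perturbation, so its S_i is 0 without a rerun.  Individual run failures
    are recorded per-row (NaN S_i), not fatal.

    Returns a table with columns (simulation, parameter, direction, R_base,
    R_pert, S).
    """
    rows = []
    for job in jobs:
        registry = names if names is not None else sensitivity_registry(job.variant)
        R_base = _job_response(job, job.params)
        for name in registry:
            for frac in (+fraction, -fraction):
                direction = f"{'+' if frac > 0 else '-'}{abs(fraction):g}"
                if getattr(job.params, name) == 0.0:
                    rows.append((job.label, name, direction, R_base, R_base, 0.0))
                    continue
                try:
                    R_pert = _job_response(job, perturb(job.params, name, frac))
                    S = sensitivity(R_base, R_pert, frac)
                except Exception:
                    R_pert, S = np.nan, np.nan
                rows.append((job.label, name, direction, R_base, R_pert, S))
    return pd.DataFrame(rows, columns=["simulation", "parameter", "direction",
                                       "R_base", "R_pert", "S"])


def scan_exceptions(report: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Distinct (parameter, direction) variations whose S meets ``threshold``
    in at least one assessed simulation, with the count of simulations in
    which each exceeds it."""
    hits = report[report["S"] >= threshold]
    grouped = (hits.groupby(["parameter", "direction"])
               .agg(n_simulations=("simulation", "nunique"),
                    S_max=("S", "max"))
               .reset_index())
    return grouped.sort_values("S_max", ascending=False).reset_index(drop=True)


def decay_time_constant(traj: Trajectory, variable: str, t_start: float,
                        t_end: float | None = None) -> float:
    """Exponential decay time constant (min) of ``variable`` after ``t_start``.

    Fits baseline + amplitude * exp(-(t - t_start)/tau) to the post-``t_start``
    segment.  The segment must decay monotonically toward a plateau (small
    discretization ripple tolerated).
    """
    t = traj.times
    y = traj.series(variable)
    mask = t >= t_start
    if t_end is not None:
        mask &= t <= t_end
    ts, ys = t[mask] - t_start, y[mask]
    if ts.size < 10:
        raise ValueError("too few samples after t_start")
    amp0 = ys[0] - ys[-1]
    if amp0 <= 0:
        raise ValueError(f"{variable} does not decay after t = {t_start}")
    ripple = 1e-3 * amp0
    if np.any(np.diff(ys) > ripple):
        raise ValueError(f"{variable} is not monotone decreasing after t = {t_start}")

    def model(tt, base, amp, tau):
        return base + amp * np.exp(-tt / tau)

    tau0 = max((ts[-1] - ts[0]) / 5.0, 1e-3)
    popt, _ = curve_fit(model, ts, ys, p0=[ys[-1], amp0, tau0],
                        maxfev=20000)
    tau = float(popt[2])
    if tau <= 0:
        raise RuntimeError("fit returned a nonpositive time constant")
    return tau


def elevation_duration(traj: Trajectory, variable: str, t_ref: float,
                       recovery_fraction: float = 0.9,
                       baseline: float | None = None) -> float:
    """Time from ``t_ref`` until ``variable`` has recovered
    ``recovery_fraction`` of its peak elevation back toward baseline.

    ``baseline`` defaults to the value sampled immediately before the first
    stimulus event (or the first sample of the trajectory if unstimulated).
    """
    t = traj.times
    y = traj.series(variable)
    if baseline is None:
        onsets = traj.events.onsets()
        t0 = float(onsets[0]) if onsets.size else t[0]
        baseline = float(y[max(np.searchsorted(t, t0) - 1, 0)])
    after = t >= t_ref
    i_peak = int(np.flatnonzero(after)[np.argmax(y[after])])
    peak = float(y[i_peak])
    if peak <= baseline:
        raise ValueError(f"{variable} shows no elevation above baseline after t_ref")
    thresh = baseline + (1.0 - recovery_fraction) * (peak - baseline)
    below = np.flatnonzero((t > t[i_peak]) & (y <= thresh))
    if below.size == 0:
        raise ValueError(f"{variable} never recovers {recovery_fraction:.0%} "
                         "of its elevation within the trajectory")
    return float(t[below[0]] - t_ref)


def classify_state(traj: Trajectory, t: float, basal_W: float,
                   upper_W: float) -> str:
    """``"potentiated"`` iff W(t) exceeds the midpoint between the variant's
    basal and maintained upper-state weights (both from reference runs)."""
    if not upper_W > basal_W > 0:
        raise ValueError("need reference weights with upper_W > basal_W > 0")
    return "potentiated" if traj.at("W", t) > 0.5 * (basal_W + upper_W) else "basal"


def minimum_inhibition_duration(p: ParameterSet, variant: VariantId,
                                durations: list[float], seeds: list[int],
                                fraction: float = 0.9, start: float = 60.0,
                                post: float = 4000.0,
                                cfg: SimulationConfig | None = None
                                ) -> pd.DataFrame:
    """Minimum PKMzeta-inhibition duration that permanently switches the
    reactivation-maintained synapse back to basal, per seed.

    For each seed the synapse is brought to its upper state, then inhibition
    windows of each duration are applied and the state classified ``post``
    minutes after washout.  Returns one row per (seed, duration) with the
    classification, from which the per-seed minimum effective duration and
    its median over seeds can be read.
    """
    from .simulate import snapshot_upper_state
    from .stimulation import InhibitionSchedule

    if cfg is None:
        cfg = SimulationConfig()
    basal = equilibrate(initialize(p, variant), p, variant,
                        duration=cfg.equilibration, dt=cfg.dt)
    rows = []
    for seed in seeds:
        snap_cfg = SimulationConfig(t_end=cfg.t_end, dt=cfg.dt,
                                    record_stride=cfg.record_stride, seed=seed,
                                    equilibration=cfg.equilibration)
        upper = snapshot_upper_state(p, variant, snap_cfg)
        for dur in durations:
            t_end = start + dur + post
            proto = Protocol(reactivation=variant.has_reactivation,
                             reactivation_seed=seed + 10_000,
                             inhibition=InhibitionSchedule(start, start + dur, fraction))
            run_cfg = SimulationConfig(t_end=t_end, dt=cfg.dt,
                                       record_stride=cfg.record_stride,
                                       seed=seed, equilibration=cfg.equilibration)
            traj = run(upper, proto, p, variant, run_cfg)
            state = classify_state(traj, traj.times[-1], basal.W, upper.W)
            rows.append((seed, dur, state))
    return pd.DataFrame(rows, columns=["seed", "duration", "state"])
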