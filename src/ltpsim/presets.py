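"""Figure-protocol presets: fully specified (variant, parameters, protocol,
integrator settings, display scalings) for each canonical simulation of the
model: induction, maintenance by each feedback variant, inhibition, and
feedback switch-off experiments.

Times inside a preset are minutes of simulation time, with t = 0 at the end
of basal equilibration; the standard induction train starts at t = 10 min so
every trajectory carries a pre-stimulus baseline.  The two inhibition
presets start from the maintained upper state instead of the basal state.

The switch-off presets turn one feedback loop off 33 h after tetanus onset
(the documented origin choice); pass a different ``switch_off`` to move it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from .analysis import LtpMeasurement, ltp_magnitude
from .params import ParameterSet, ScheduledChange, VariantId, load_preset
from .simulate import (SimulationConfig, Trajectory, equilibrate, initialize,
                       run, snapshot_upper_state, standard_induction)
from .stimulation import EventTrain, InhibitionSchedule, Protocol

__all__ = ["ProtocolPreset", "PRESETS", "load_figure_preset", "run_preset",
           "PresetResult"]

_T_TETANUS = 10.0                 # min, onset of the first tetanus
_T_LAST = _T_TETANUS + 10.0       # min, onset of the third tetanus
_SWITCH_OFF = _T_TETANUS + 33.0 * 60.0  # 33 h post-tetanus-onset

_SCALE_2A = {"CaMKII_act": 0.12, "ERKPP": 7.0, "PKA_act": 50.0,
             "W": 0.1, "TAG": 700.0, "PKM_act": 2.0}
_SCALE_3B = {"CaMKII_act": 0.12, "ERKPP": 11.0, "PKA_act": 50.0,
             "W": 0.1, "TAG": 1000.0, "PKM_act": 1.5}


@dataclass(frozen=True)
class ProtocolPreset:
    """A named, fully resolved figure protocol."""

    name: str
    variant: VariantId
    description: str
    t_end: float
    assess_delay: float                  # min after the last tetanus
    record_stride: int
    upper_state: bool = False            # start from the maintained state
    inhibition: InhibitionSchedule | None = None
    switch_off: str | None = None        # "k_PKM" or "reactivation"
    scale_factors: dict = field(default_factory=dict)

    def params(self) -> ParameterSet:
        return load_preset(self.variant)

    def protocol(self, seed: int = 0) -> Protocol:
        changes: tuple[ScheduledChange, ...] = ()
        react_stop = None
        if self.switch_off == "k_PKM":
            changes = (ScheduledChange(_SWITCH_OFF, "k_PKM", 0.0),)
        elif self.switch_off == "reactivation":
            react_stop = _SWITCH_OFF
        return Protocol(
            tetani=EventTrain() if self.upper_state
            else standard_induction(_T_TETANUS),
            reactivation=self.variant.has_reactivation,
            reactivation_seed=seed,
            reactivation_stop=react_stop,
            inhibition=self.inhibition,
            changes=changes,
        )

    def config(self, seed: int = 0, dt: float | None = None,
               integrator: str = "euler") -> SimulationConfig:
        from .simulate import DT_STANDARD
        return SimulationConfig(t_end=self.t_end, dt=dt or DT_STANDARD,
                                record_stride=self.record_stride,
                                integrator=integrator, seed=seed)


PRESETS: dict[str, ProtocolPreset] = {
    "fig2a": ProtocolPreset(
        "fig2a", VariantId.NO_FEEDBACK,
        "Induction only: three tetani, L-LTP of ~131% at 2 h, decays over ~10 h.",
        t_end=1280.0, assess_delay=120.0, record_stride=100,
        scale_factors=_SCALE_2A),
    "fig2b": ProtocolPreset(
        "fig2b", VariantId.PKM_AUTONOMOUS,
        "Autonomous PKMzeta synthesis: PKMzeta switches on persistently, W decays.",
        t_end=3050.0, assess_delay=120.0, record_stride=600,
        scale_factors={**_SCALE_2A, "PKM_act": 0.6}),
    "fig2c": ProtocolPreset(
        "fig2c", VariantId.PKM_TAG_COUPLED,
        "PKMzeta autoactivation coupled into the tag: W maintained at 50 h.",
        t_end=3050.0, assess_delay=3000.0, record_stride=600,
        scale_factors={**_SCALE_2A, "PKM_act": 0.6}),
    "fig3a": ProtocolPreset(
        "fig3a", VariantId.CAMKII_AUTONOMOUS,
        "CaMKII autoactivation: CaMKII, TAG, PKMzeta and W maintained.",
        t_end=3050.0, assess_delay=3000.0, record_stride=600,
        scale_factors={**_SCALE_2A, "PKM_act": 0.3}),
    "fig3b": ProtocolPreset(
        "fig3b", VariantId.REACTIVATION,
        "Weight-dependent reactivation: fluctuating maintained state.",
        t_end=3050.0, assess_delay=3000.0, record_stride=600,
        scale_factors=_SCALE_3B),
    "fig4a": ProtocolPreset(
        "fig4a", VariantId.CAMKII_AUTONOMOUS,
        "Transient PKMzeta inhibition of the CaMKII-maintained state: "
        "W dips and repotentiates after washout.",
        t_end=1500.0, assess_delay=0.0, record_stride=600, upper_state=True,
        inhibition=InhibitionSchedule(60.0, 60.0 + 120.0, 0.9),
        scale_factors={**_SCALE_2A, "PKM_act": 0.3}),
    "fig4b": ProtocolPreset(
        "fig4b", VariantId.REACTIVATION,
        "90% PKMzeta inhibition for 50 h of the reactivation-maintained "
        "state: permanent transition to basal.",
        t_end=9000.0, assess_delay=0.0, record_stride=3000, upper_state=True,
        inhibition=InhibitionSchedule(60.0, 60.0 + 3000.0, 0.9),
        scale_factors=_SCALE_3B),
    "fig5a": ProtocolPreset(
        "fig5a", VariantId.SYNERGY,
        "Synergy variant; PKMzeta feedback switched off (k_PKM -> 0) at "
        "33 h post-tetanus: PKMzeta and W decline to basal.",
        t_end=5000.0, assess_delay=0.0, record_stride=600,
        switch_off="k_PKM",
        scale_factors={**_SCALE_3B, "PKM_act": 0.75}),
    "fig5b": ProtocolPreset(
        "fig5b", VariantId.SYNERGY,
        "Synergy variant; reactivation switched off at 33 h post-tetanus: "
        "slow decline of PKMzeta and W.",
        t_end=6000.0, assess_delay=0.0, record_stride=600,
        switch_off="reactivation",
        scale_factors={**_SCALE_3B, "PKM_act": 0.75}),
}


def load_figure_preset(name: str) -> ProtocolPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass
class PresetResult:
    preset: ProtocolPreset
    trajectory: Trajectory
    basal_W: float
    measurement: LtpMeasurement | None


def run_preset(name: str, seed: int = 0, dt: float | None = None,
               integrator: str = "euler",
               params: ParameterSet | None = None) -> PresetResult:
    """Run a figure preset end-to-end (equilibration or upper-state snapshot,
    protocol, and — for induction presets — the L-LTP measurement)."""
    preset = load_figure_preset(name)
    p = params if params is not None else preset.params()
    cfg = preset.config(seed=seed, dt=dt, integrator=integrator)
    basal = equilibrate(initialize(p, preset.variant), p, preset.variant,
                        duration=cfg.equilibration, dt=cfg.dt)
    if preset.upper_state:
        initial = snapshot_upper_state(p, preset.variant, cfg)
    else:
        initial = basal
    traj = run(initial, preset.protocol(seed), p, preset.variant, cfg)
    traj.metadata["preset"] = name
    measurement = None
    if not preset.upper_state:
        measurement = ltp_magnitude(traj, t_last_tetanus=_T_LAST,
                                    delay=preset.assess_delay)
    return PresetResult(preset, traj, basal.W, measurement)
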