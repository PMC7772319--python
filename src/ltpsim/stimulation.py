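"""Stimulation protocols: tetanus trains, stochastic synaptic reactivation,
and PKMzeta inhibition schedules.

A stimulus event drives three square-wave channels starting simultaneously at
its onset: synaptic Ca2+ (duration ``Ca_dur``, 3 s standard), cAMP and the Raf
activation rate constant (duration ``d_cAMP``, 1 min standard).  A tetanus
uses the fixed amplitudes (A_Casyn, A_cAMP, A_STIM); a reactivation event
scales them by a steep (5th-power) Hill function of the synaptic weight at
event onset, so only potentiated synapses are meaningfully reactivated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Forcing, hill
from .params import ParameterSet, ScheduledChange

__all__ = [
    "StimEvent",
    "EventTrain",
    "InhibitionSchedule",
    "ReactivationGenerator",
    "Protocol",
    "tetanus_train",
    "draw_reactivation_times",
    "reactivation_forcing",
    "effective_pkm",
]

TETANUS = 0
REACTIVATION_EVENT = 1


@dataclass(frozen=True)
class StimEvent:
    onset: float  # min
    kind: int     # TETANUS or REACTIVATION_EVENT


@dataclass
class EventTrain:
    """Onset-sorted stimulus events (tetani and/or reactivations)."""

    events: list[StimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events.sort(key=lambda e: e.onset)

    def onsets(self, kind: int | None = None) -> np.ndarray:
        return np.array([e.onset for e in self.events
                         if kind is None or e.kind == kind])

    def merged(self, other: "EventTrain") -> "EventTrain":
        return EventTrain(self.events + other.events)


@dataclass(frozen=True)
class InhibitionSchedule:
    """A window during which a fraction of PKMzeta activity is blocked.

    Inhibition is effector-level: PKM_act itself keeps evolving, and only its
    downstream action (weight production and the tag-coupling term) is scaled
    by ``1 - fraction`` inside [start, end).
    """

    start: float     # min
    end: float       # min
    fraction: float  # in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("inhibition fraction must be in [0, 1]")
        if not self.start < self.end:
            raise ValueError("inhibition window requires start < end")


def effective_pkm(PKM_act: float, sched: InhibitionSchedule | None, t: float) -> float:
    """PKMzeta activity available to effectors at time ``t``."""
    if sched is not None and sched.start <= t < sched.end:
        return PKM_act * (1.0 - sched.fraction)
    return PKM_act


def tetanus_train(n: int, isi: float, t0: float = 0.0) -> EventTrain:
    """``n`` tetani with onset-to-onset interval ``isi`` min, first at ``t0``.

    The standard induction protocol is three 1-s tetani with 5-min ISI; since
    the driven channel elevations last at most 1 min, 5-min spacing never
    overlaps.
    """
    if n < 1:
        raise ValueError("need at least one tetanus")
    if n > 1 and isi <= 0:
        raise ValueError("ISI must be > 0")
    return EventTrain([StimEvent(t0 + i * isi, TETANUS) for i in range(n)])


@dataclass
class ReactivationGenerator:
    """Gaussian inter-reactivation intervals via the Box-Muller transform.

    Successive intervals are N(mean, sd) draws computed with the classical
    Box-Muller algorithm from a seeded uniform stream (one fresh pair of
    uniforms per interval, cosine branch), clamped below at ``min_interval``.
    The clamp is a floor, not a resample; at the standard (500, 150) settings
    it shifts the mean by well under 0.1%.
    """

    mean: float = 500.0
    sd: float = 150.0
    min_interval: float = 10.0
    seed: int = 0

    def intervals(self, n: int) -> np.ndarray:
        """Draw ``n`` successive intervals (min); deterministic per seed."""
        rng = np.random.default_rng(self.seed)
        # One consecutive (u1, u2) pair per interval, so the interval stream
        # is a fixed function of the seed regardless of how many intervals
        # are drawn (truncating a protocol preserves earlier event times).
        us = rng.random(2 * n)
        u1, u2 = us[0::2], us[1::2]
        # Box-Muller: guard u1 = 0 (log singularity) with the smallest
        # representable positive uniform.
        u1 = np.maximum(u1, np.finfo(float).tiny)
        z = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * math.pi * u2)
        return np.maximum(self.mean + self.sd * z, self.min_interval)

    def times(self, t_start: float, t_end: float) -> np.ndarray:
        """Event onsets in [t_start, t_end): cumulative sums of intervals."""
        if not t_start < t_end:
            raise ValueError("need t_start < t_end")
        # Draw in blocks until the horizon is covered.
        n_guess = max(16, int(2 * (t_end - t_start) / max(self.mean, 1e-9)))
        while True:
            onsets = t_start + np.cumsum(self.intervals(n_guess))
            if onsets[-1] >= t_end:
                return onsets[onsets < t_end]
            n_guess *= 2


def draw_reactivation_times(gen: ReactivationGenerator, t_start: float,
                            t_end: float) -> np.ndarray:
    """Reactivation onsets in [t_start, t_end) for a seeded generator."""
    return gen.times(t_start, t_end)


def reactivation_forcing(W: float, p: ParameterSet,
                         amp_scale: float | None = None) -> Forcing:
    """Channel amplitudes during a reactivation event at weight ``W``.

    Each channel is the tetanus amplitude scaled by ``amp_scale`` (1 for the
    reactivation variant, 0.8 for the synergy variant) times a 5th-power Hill
    function of W, floored at the basal values.
    """
    if W < 0:
        raise ValueError("W must be >= 0")
    scale = p.react_amp_scale if amp_scale is None else amp_scale
    h = hill(W, p.K_W, 5)
    return Forcing(
        Ca_syn=max(scale * p.A_Casyn * h, p.Ca_bas),
        cAMP=max(scale * p.A_cAMP * h, p.cAMP_bas),
        k_fRaf=p.k_fbasRaf + scale * p.A_STIM * h,
    )


@dataclass
class Protocol:
    """A full stimulation protocol for one simulation.

    ``tetani`` are fixed-amplitude induction events (optionally scaled by
    ``tetanus_amp_scale``, e.g. 0.25 for a "weak stimulus" probe of
    bistability).  Reactivation events are generated from the parameter set's
    interval statistics with ``reactivation_seed`` when ``reactivation`` is
    on; ``reactivation_stop`` suppresses events from that time on (how the
    synergy experiment switches the reactivation loop off).  ``changes``
    apply scheduled parameter changes (e.g. k_PKM -> 0).
    """

    tetani: EventTrain = field(default_factory=EventTrain)
    tetanus_amp_scale: float = 1.0
    reactivation: bool = False
    reactivation_seed: int = 0
    reactivation_start: float = 0.0
    reactivation_stop: float | None = None
    inhibition: InhibitionSchedule | None = None
    changes: tuple[ScheduledChange, ...] = ()
    plim_weight_decay: bool = False

    def reactivation_events(self, p: ParameterSet, t_end: float) -> EventTrain:
        if not self.reactivation:
            return EventTrain()
        stop = t_end if self.reactivation_stop is None else min(self.reactivation_stop, t_end)
        if stop <= self.reactivation_start:
            return EventTrain()
        gen = ReactivationGenerator(p.react_mean, p.react_sd, p.react_min,
                                    self.reactivation_seed)
        onsets = draw_reactivation_times(gen, self.reactivation_start, stop)
        return EventTrain([StimEvent(float(t), REACTIVATION_EVENT) for t in onsets])

    def all_events(self, p: ParameterSet, t_end: float) -> EventTrain:
        return self.tetani.merged(self.reactivation_events(p, t_end))
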