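"""Model parameters, variant presets, perturbation, and the sensitivity registry.

The model of late-LTP maintenance is a single-synapse ODE system driven by
square-wave stimulus events.  Every rate constant, Hill constant, amplitude and
time constant lives in :class:`ParameterSet`.  The six named variants differ
only in which positive-feedback constants are nonzero (plus a handful of
standard per-variant overrides), so a variant is fully described by a
:class:`VariantId` together with its preset :class:`ParameterSet`.

Units: all times and time constants are minutes, all concentrations are uM.
The 3-s Ca pulse duration is stored as 0.05 min.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "ParameterSet",
    "VariantId",
    "ScheduledChange",
    "load_preset",
    "perturb",
    "sensitivity_registry",
    "PARAM_NAMES",
]


class VariantId(enum.Enum):
    """The model variants: which positive-feedback loop maintains L-LTP.

    NO_FEEDBACK       induction only; L-LTP decays over hours.
    PKM_AUTONOMOUS    variant Ia: self-sustaining PKMzeta synthesis.
    PKM_TAG_COUPLED   variant Ib: PKMzeta autoactivation, and PKMzeta
                      additionally contributes to the synaptic tag.
    CAMKII_AUTONOMOUS variant II: self-sustaining CaMKII autoactivation.
    REACTIVATION      variant III: weight-dependent synaptic reactivation.
    SYNERGY           variant IV: weakened reactivation plus weakened PKMzeta
                      autoactivation, neither sufficient alone.
    """

    NO_FEEDBACK = "no_feedback"
    PKM_AUTONOMOUS = "pkm_autonomous"
    PKM_TAG_COUPLED = "pkm_tag_coupled"
    CAMKII_AUTONOMOUS = "camkii_autonomous"
    REACTIVATION = "reactivation"
    SYNERGY = "synergy"

    @property
    def has_reactivation(self) -> bool:
        return self in (VariantId.REACTIVATION, VariantId.SYNERGY)

    @property
    def is_bistable(self) -> bool:
        """Variants whose synaptic weight has a maintained upper state."""
        return self in (
            VariantId.PKM_TAG_COUPLED,
            VariantId.CAMKII_AUTONOMOUS,
            VariantId.REACTIVATION,
            VariantId.SYNERGY,
        )


@dataclass
class ParameterSet:
    """All constants of the model equations (standard values as defaults).

    Positive-feedback strength constants (``k_CaMKII``, ``k_PKM``, ``k_TPKM``)
    default to zero; :func:`load_preset` switches them on per variant.  A
    feedback term with zero strength is mathematically absent, so the variant
    identity is fully encoded in the parameter values plus the reactivation
    on/off flag carried by the protocol.
    """

    # -- stimulus shape ----------------------------------------------------
    Ca_bas: float = 0.04        # uM, basal synaptic Ca2+
    cAMP_bas: float = 0.06      # uM, basal cAMP
    Ca_dur: float = 0.05        # min (3 s), Ca pulse duration
    d_cAMP: float = 1.0         # min, cAMP and Raf-rate pulse duration
    A_Casyn: float = 0.8        # uM, Ca amplitude during a tetanus
    A_cAMP: float = 0.25        # uM, cAMP amplitude during a tetanus
    A_STIM: float = 0.13        # 1/min, added Raf activation rate during a tetanus

    # -- CaMKII and PKA ----------------------------------------------------
    K_Casyn: float = 0.7        # uM, Hill constant of Ca -> CaMKII (n = 4)
    k_fck2: float = 180.0       # uM/min, CaMKII activation rate scale
    tau_ck2: float = 1.0        # min, CaMKII deactivation time constant
    K_cAMP: float = 1.0         # uM, Hill constant of cAMP -> PKA (n = 2)
    tau_PKA: float = 15.0       # min, PKA relaxation time constant

    # -- Raf-MEK-ERK cascade ----------------------------------------------
    RAF_TOT: float = 0.25       # uM
    MEK_TOT: float = 0.25       # uM
    ERK_TOT: float = 0.25       # uM
    k_fbasRaf: float = 0.0075   # 1/min, basal Raf activation rate constant
    k_bRaf: float = 0.12        # 1/min
    k_fMEK: float = 0.6         # 1/min (per uM active Raf)
    k_bMEK: float = 0.025       # uM/min
    K_MEK: float = 0.25         # uM, Michaelis constant
    k_fERK: float = 0.52        # 1/min (per uM active MEK)
    k_bERK: float = 0.025       # uM/min
    K_ERK: float = 0.25         # uM, Michaelis constant

    # -- PKMzeta synthesis -------------------------------------------------
    k_transpkm: float = 0.2         # uM/min
    k_transbaspkm: float = 0.0015   # uM/min, basal synthesis
    k_dpkm: float = 0.02            # 1/min, deactivation/degradation

    # -- tag and translation-site phosphorylation --------------------------
    k_phos1: float = 0.15       # 1/(uM min), CaMKII -> Tag-1
    k_deph1: float = 0.008      # 1/min
    k_phos2: float = 0.8        # 1/(uM min), PKA -> Tag-2
    k_deph2: float = 0.2        # 1/min
    k_phos3: float = 0.06       # 1/(uM min), ERKPP -> Tag-3
    k_deph3: float = 0.05       # 1/min
    k_phos4: float = 0.1        # 1/(uM min), CaMKII -> P_CK2
    k_deph4: float = 0.1        # 1/min
    k_phos5: float = 2.0        # 1/(uM min), ERKPP -> P_ERK
    k_deph5: float = 0.1        # 1/min

    # -- synaptic weight and limiting protein ------------------------------
    PRP: float = 1.0            # uM, plasticity-related protein (constant)
    k_ltp: float = 500.0        # 1/(uM^2 min)
    k_ltpbas: float = 0.01      # 1/min, basal weight production
    tau_ltp: float = 300.0      # min, weight decay time constant
    K_lim: float = 0.2          # uM
    k_Pl: float = 6.0           # 1/min
    k_Plbas: float = 0.0035     # uM/min
    tau_Pl: float = 100.0       # min

    # -- positive-feedback loops (zero unless the variant enables them) ----
    k_CaMKII: float = 0.0       # uM/min, CaMKII autoactivation strength
    K_CaMKII: float = 1.0       # uM, Hill constant (n = 2)
    k_PKM: float = 0.0          # uM/min, PKMzeta autoactivation strength
    K_PKM: float = 0.75         # uM, Hill constant (n = 2)
    k_TPKM: float = 0.0         # 1/uM, PKMzeta -> TAG coupling coefficient
    K_W: float = 4.0            # weight units, Hill constant of reactivation (n = 5)

    # -- reactivation interval statistics ----------------------------------
    react_mean: float = 500.0       # min, mean inter-reactivation interval
    react_sd: float = 150.0         # min, standard deviation
    react_min: float = 10.0         # min, imposed floor on intervals
    react_amp_scale: float = 1.0    # dimensionless scale of reactivation amplitudes

    def copy(self) -> "ParameterSet":
        return dataclasses.replace(self)

    def validate(self) -> None:
        """Raise ``ValueError`` on a physically meaningless parameter set."""
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        for name in ("tau_ck2", "tau_PKA", "tau_ltp", "tau_Pl", "k_dpkm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(ParameterSet))


@dataclass(frozen=True)
class ScheduledChange:
    """A parameter value change at a fixed simulation time (e.g. switching a
    feedback loop off by setting its strength constant to zero)."""

    time: float          # min, simulation time of the change
    target: str          # parameter name
    new_value: float

    def __post_init__(self) -> None:
        if self.target not in PARAM_NAMES:
            raise KeyError(f"unknown parameter name: {self.target}")


# Per-variant overrides of the standard values.
_VARIANT_OVERRIDES: dict[VariantId, dict[str, float]] = {
    VariantId.NO_FEEDBACK: {"k_ltp": 500.0},
    VariantId.PKM_AUTONOMOUS: {"k_ltp": 300.0, "k_PKM": 0.028},
    VariantId.PKM_TAG_COUPLED: {"k_ltp": 240.0, "k_PKM": 0.028, "k_TPKM": 0.0001},
    VariantId.CAMKII_AUTONOMOUS: {"k_ltp": 70.0, "k_CaMKII": 4.0},
    VariantId.REACTIVATION: {
        "k_ltp": 480.0,
        "tau_ltp": 3200.0,
        "k_ltpbas": 0.00086,
    },
    VariantId.SYNERGY: {
        # reactivation base ...
        "tau_ltp": 800.0,
        # ... with weakened reactivation and weakened PKMzeta autoactivation
        "k_ltp": 180.0,
        "k_ltpbas": 0.003,
        "k_PKM": 0.0078,
        "k_transbaspkm": 0.00045,
        "k_dpkm": 0.006,
        "react_mean": 200.0,
        "react_sd": 50.0,
        "react_amp_scale": 0.8,
    },
}

# Feedback-loop strength constants that must be zero when the loop is absent.
_FEEDBACK_STRENGTHS = ("k_CaMKII", "k_PKM", "k_TPKM")


def load_preset(variant: VariantId) -> ParameterSet:
    """Return the standard parameter set for a model variant.

    Raises
    ------
    KeyError
        If ``variant`` is not a defined :class:`VariantId`.
    """
    variant = VariantId(variant)
    p = ParameterSet()
    for name, value in _VARIANT_OVERRIDES[variant].items():
        setattr(p, name, value)
    p.validate()
    return p


def perturb(p: ParameterSet, name: str, fraction: float) -> ParameterSet:
    """Return a copy of ``p`` with ``name`` multiplied by ``(1 + fraction)``.

    Only names in the union of sensitivity registries are accepted; a
    perturbation that would make a parameter negative is an error.
    """
    if name not in _REGISTRY_UNION:
        raise KeyError(f"parameter {name!r} is not in the sensitivity registry")
    new = getattr(p, name) * (1.0 + fraction)
    if new < 0:
        raise ValueError(f"perturbing {name} by {fraction:+g} gives a negative value")
    q = p.copy()
    setattr(q, name, new)
    return q


# The 40 parameters perturbed in every variant's one-at-a-time scan: every
# standard constants except the two square-pulse durations (Ca_dur,
# d_cAMP; stimulus shape, constrained by data) and the two basal floors
# (Ca_bas, cAMP_bas).  Each variant adds its own 3 feedback parameters,
# giving exactly 43 names and hence 86 +/-15% variations per variant.
# Changing membership is a breaking change.
_COMMON_REGISTRY: tuple[str, ...] = (
    "A_Casyn", "A_cAMP", "A_STIM",
    "K_Casyn", "k_fck2", "tau_ck2", "K_cAMP", "tau_PKA",
    "RAF_TOT", "MEK_TOT", "ERK_TOT",
    "k_fbasRaf", "k_bRaf", "k_fMEK", "k_bMEK", "K_MEK",
    "k_fERK", "k_bERK", "K_ERK",
    "k_transpkm", "k_transbaspkm", "k_dpkm",
    "k_phos1", "k_deph1", "k_phos2", "k_deph2", "k_phos3", "k_deph3",
    "k_phos4", "k_deph4", "k_phos5", "k_deph5",
    "PRP", "k_ltp", "k_ltpbas", "tau_ltp", "K_lim", "k_Pl", "k_Plbas", "tau_Pl",
)

_VARIANT_REGISTRY_EXTRAS: dict[VariantId, tuple[str, str, str]] = {
    # Zero-valued strength constants are retained so every variant has 43
    # entries; their variations are identically zero.
    VariantId.NO_FEEDBACK: ("k_PKM", "k_CaMKII", "k_TPKM"),
    VariantId.PKM_AUTONOMOUS: ("k_PKM", "K_PKM", "k_CaMKII"),
    VariantId.PKM_TAG_COUPLED: ("k_PKM", "K_PKM", "k_TPKM"),
    VariantId.CAMKII_AUTONOMOUS: ("k_CaMKII", "K_CaMKII", "k_PKM"),
    VariantId.REACTIVATION: ("K_W", "k_PKM", "k_CaMKII"),
    VariantId.SYNERGY: ("k_PKM", "K_PKM", "K_W"),
}

_REGISTRY_UNION = frozenset(_COMMON_REGISTRY) | {
    n for extras in _VARIANT_REGISTRY_EXTRAS.values() for n in extras
}


def sensitivity_registry(variant: VariantId) -> tuple[str, ...]:
    """The ordered 43 parameter names perturbed in the variant's scan."""
    variant = VariantId(variant)
    return _COMMON_REGISTRY + _VARIANT_REGISTRY_EXTRAS[variant]


def check_variant_consistency(p: ParameterSet, variant: VariantId) -> None:
    """Assert that feedback strengths absent from ``variant`` are zero."""
    active: set[str] = set()
    if variant in (VariantId.PKM_AUTONOMOUS, VariantId.PKM_TAG_COUPLED, VariantId.SYNERGY):
        active.add("k_PKM")
    if variant is VariantId.PKM_TAG_COUPLED:
        active.add("k_TPKM")
    if variant is VariantId.CAMKII_AUTONOMOUS:
        active.add("k_CaMKII")
    for name in _FEEDBACK_STRENGTHS:
        if name not in active and getattr(p, name) != 0.0:
            raise ValueError(
                f"variant {variant.value} does not include the {name} feedback loop; "
                f"its strength must be 0, got {getattr(p, name)}"
            )
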