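"""Figure rendering with the per-preset display scale factors.

Each preset carries vertical scale factors (e.g. TAG multiplied by 700 in
the induction figure) so overlaid time courses of very different magnitudes
share one axis; the time axis is hours.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .presets import ProtocolPreset
from .simulate import Trajectory

__all__ = ["render_figure"]

_KINASE_VARS = ("CaMKII_act", "PKA_act", "ERKPP")
_SLOW_VARS = ("W", "TAG", "PKM_act")


def render_figure(traj: Trajectory, preset: ProtocolPreset,
                  path: str | Path) -> Path:
    """Render the preset's overlaid, vertically scaled time courses.

    Raises ``ValueError`` if the trajectory was produced by a different
    preset (when the trajectory records one).
    """
    recorded = traj.metadata.get("preset")
    if recorded is not None and recorded != preset.name:
        raise ValueError(f"trajectory is from preset {recorded!r}, not {preset.name!r}")
    hours = traj.times / 60.0
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, group in zip(axes, (_KINASE_VARS, _SLOW_VARS)):
        for name in group:
            scale = preset.scale_factors.get(name, 1.0)
            label = name if scale == 1.0 else f"{name} x{scale:g}"
            ax.plot(hours, scale * traj.series(name), label=label, lw=0.9)
        ax.legend(loc="upper right", fontsize=8)
        ax.set_ylabel("scaled value")
    axes[1].set_xlabel("time (h)")
    axes[0].set_title(f"{preset.name}: {preset.description}", fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
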