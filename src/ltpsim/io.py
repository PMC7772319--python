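"""Configuration files, trajectory tables, and regression fixtures.

Configurations are flat YAML: a variant name, parameter overrides, a protocol
block and integrator settings, all in minutes/uM.  Trajectories are written
as tab-separated tables (one row per recorded time, columns named exactly as
the state/forcing fields plus TAG) with a ``#``-prefixed metadata header for
provenance (variant, seed, dt, parameter overrides, event log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ParameterSet, ScheduledChange, VariantId, load_preset
from .simulate import SimulationConfig, Trajectory
from .stimulation import EventTrain, InhibitionSchedule, Protocol, StimEvent, tetanus_train

__all__ = [
    "RunConfig",
    "save_config",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "make_fixtures",
]


@dataclasses.dataclass
class RunConfig:
    """A fully resolved simulation configuration (variant + parameters +
    protocol + integrator settings)."""

    variant: VariantId
    params: ParameterSet
    protocol: Protocol
    sim: SimulationConfig

    def to_dict(self) -> dict:
        proto = self.protocol
        d: dict = {
            "variant": self.variant.value,
            "parameters": self.params.to_dict(),
            "protocol": {
                "tetani": [e.onset for e in proto.tetani.events],
                "tetanus_amp_scale": proto.tetanus_amp_scale,
                "reactivation": proto.reactivation,
                "reactivation_seed": proto.reactivation_seed,
                "reactivation_start": proto.reactivation_start,
                "reactivation_stop": proto.reactivation_stop,
                "plim_weight_decay": proto.plim_weight_decay,
                "changes": [[c.time, c.target, c.new_value] for c in proto.changes],
            },
            "simulation": {
                "t_end": self.sim.t_end,
                "dt": self.sim.dt,
                "record_stride": self.sim.record_stride,
                "integrator": self.sim.integrator,
                "seed": self.sim.seed,
                "equilibration": self.sim.equilibration,
            },
        }
        if proto.inhibition is not None:
            d["protocol"]["inhibition"] = {
                "start": proto.inhibition.start,
                "end": proto.inhibition.end,
                "fraction": proto.inhibition.fraction,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        variant = VariantId(d["variant"])
        params = ParameterSet.from_dict(d["parameters"])
        pr = d["protocol"]
        inh = None
        if "inhibition" in pr and pr["inhibition"] is not None:
            i = pr["inhibition"]
            inh = InhibitionSchedule(i["start"], i["end"], i["fraction"])
        from .stimulation import TETANUS
        protocol = Protocol(
            tetani=EventTrain([StimEvent(t, TETANUS) for t in pr["tetani"]]),
            tetanus_amp_scale=pr.get("tetanus_amp_scale", 1.0),
            reactivation=pr.get("reactivation", False),
            reactivation_seed=pr.get("reactivation_seed", 0),
            reactivation_start=pr.get("reactivation_start", 0.0),
            reactivation_stop=pr.get("reactivation_stop"),
            inhibition=inh,
            changes=tuple(ScheduledChange(t, n, v) for t, n, v in pr.get("changes", [])),
            plim_weight_decay=pr.get("plim_weight_decay", False),
        )
        s = d["simulation"]
        sim = SimulationConfig(t_end=s["t_end"], dt=s["dt"],
                               record_stride=s["record_stride"],
                               integrator=s["integrator"], seed=s["seed"],
                               equilibration=s["equilibration"])
        return cls(variant, params, protocol, sim)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    df = traj.to_frame()
    lines = ["# ltpsim trajectory"]
    for key, val in traj.metadata.items():
        lines.append(f"# {key}: {val}")
    lines.append(f"# clamp_count: {traj.clamp_count}")
    ev = "; ".join(f"{e.onset:g}:{'tet' if e.kind == 0 else 'react'}"
                   for e in traj.events.events)
    lines.append(f"# events: {ev}")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_trajectory(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a trajectory table; returns (data frame, metadata dict)."""
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def _traj_hash(traj: Trajectory) -> str:
    h = hashlib.sha256()
    for arr in (traj.times, traj.states, traj.forcing, traj.tag):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Deterministic short-run regression fixtures for every variant.

    Each fixture is a 60-min induction run at coarse recording from the
    equilibrated basal state; the manifest stores per-variant trajectory
    hashes so regressions are bit-exact to detect.  Purely local, no network.
    """
    from .simulate import equilibrate, initialize, run

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "dt": 1.0 / 6000.0, "fixtures": {}}
    for variant in VariantId:
        p = load_preset(variant)
        basal = equilibrate(initialize(p, variant), p, variant)
        proto = Protocol(tetani=tetanus_train(3, 5.0, 10.0),
                         reactivation=variant.has_reactivation,
                         reactivation_seed=seed)
        cfg = SimulationConfig(t_end=60.0, record_stride=600, seed=seed)
        traj = run(basal, proto, p, variant, cfg)
        name = f"{variant.value}.tsv"
        write_trajectory(traj, out_dir / name)
        manifest["fixtures"][variant.value] = {
            "file": name,
            "sha256": _traj_hash(traj),
            "pkm_bistable": variant in (VariantId.PKM_AUTONOMOUS,
                                        VariantId.PKM_TAG_COUPLED,
                                        VariantId.SYNERGY),
            "w_bistable": variant.is_bistable,
            "final_W": float(traj.final_state.W),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
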