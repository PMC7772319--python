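"""L-LTP induction without positive feedback.

Three 1-s tetani (5-min ISI) drive CaMKII, PKA and ERK, which set the synaptic
tag; tag + PKMzeta + plasticity-related protein raise the synaptic weight W.
Without a feedback loop the potentiation decays over hours.
"""

from ltpsim import run_preset
from ltpsim.analysis import decay_time_constant, elevation_duration

res = run_preset("fig2a")
traj = res.trajectory
m = res.measurement

print(f"pre-stimulus W:      {m.W_pre:.3f}")
print(f"W at 2 h post-tetanus: {m.W_assess:.3f}")
print(f"L-LTP magnitude:     {m.percent:.1f}%  (percent increase over baseline)")

pka = traj.series("PKA_act")
pka_pre = traj.at("PKA_act", 9.9)
print(f"peak PKA rise:       {100 * (pka.max() - pka_pre) / pka_pre:.0f}% over basal")
print(f"PKA decay tau:       {decay_time_constant(traj, 'PKA_act', 21.5, 120.0):.1f} min")
print(f"CaMKII decay tau:    {decay_time_constant(traj, 'CaMKII_act', 20.2, 26.0):.2f} min")
print(f"ERKPP elevated for:  {elevation_duration(traj, 'ERKPP', 20.0):.0f} min after the last tetanus")
print(f"W elevated for:      {elevation_duration(traj, 'W', 20.0) / 60:.1f} h (90% recovery)")
print()
print("The L-LTP magnitude is the standard electrophysiology readout (percent")
print("EPSP increase); the decay constants show which kinase carries which")
print("phase of the induction signal.")
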