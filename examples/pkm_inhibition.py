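"""PKMzeta inhibition as a discriminating experiment.

If CaMKII autoactivation maintains L-LTP (variant II), transiently inhibiting
PKMzeta only dents W: the loop persists and repotentiates the synapse.  If
weight-dependent reactivation maintains L-LTP (variant III), long inhibition
drops W below the reactivation threshold and the switch falls back to basal
permanently — the inhibition must last about two days because W decays with a
3200-min time constant.
"""

from ltpsim import run_preset

res = run_preset("fig4a", seed=3)
tr = res.trajectory
W = tr.series("W")
print("variant II + 90% PKMzeta inhibition for 2 h:")
print(f"  W start {W[0]:.2f} -> minimum {W.min():.2f} -> end {tr.final_state.W:.2f} "
      f"(basal {res.basal_W:.2f})  => repotentiated")

res = run_preset("fig4b", seed=3)
tr = res.trajectory
print("variant III + 90% PKMzeta inhibition for 50 h:")
print(f"  W start {tr.series('W')[0]:.2f} -> end {tr.final_state.W:.2f} "
      f"(basal {res.basal_W:.2f})")
print()
print("Because the transition is stochastic (reactivation timing), the minimum")
print("effective duration is a distribution; sweep it with")
print("  ltpsim inhibition-threshold --durations 2400,3000,3600,4200 --seeds 0,1,2,3,4")
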