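# ltpsim

Simulator of how late long-term potentiation (L-LTP) — and by extension a
long-term memory trace — can be *maintained* at a single synapse despite
ongoing protein turnover and passive decay of synaptic strength.

The package is for computational neuroscientists studying synaptic
positive-feedback hypotheses: autonomous PKMζ synthesis, self-sustaining
CaMKII autoactivation, and recurrent reactivation (replay) of strong
synapses, plus their synergy.

## The model

A single dendritic-spine compartment is driven by square-wave stimulus events
(tetani or spontaneous reactivations) that elevate synaptic Ca²⁺, cAMP, and
the Raf activation rate. Fifteen ODEs (forward Euler, dt = 10 ms) describe:

- **Kinases** — CaMKII activated by a 4th-power Hill function of Ca²⁺
  (deactivation τ ≈ 1 min); PKA relaxing toward a 2nd-power Hill function of
  cAMP (τ = 15 min); and a Raf → MEK → ERK cascade with saturable
  (Michaelis–Menten) phosphorylation cycles and conservation of each kinase
  pool — only doubly phosphorylated MEK/ERK are active.
- **Synaptic tag** — three phosphorylation sites, substrates of CaMKII, PKA
  and ERK; the tag is their product, `TAG = Tag₁·Tag₂·Tag₃`, so blocking any
  one kinase abolishes tagging.
- **PKMζ** — synthesized in proportion to the product of CaMKII- and
  ERK-dependent translation-site phosphorylations, with first-order decay.
- **Synaptic weight** — dW/dt = k_ltp·TAG·[PRP]·[PKMζ]·f(P_lim) + basal −
  W/τ_ltp, where PRP is a plasticity-related protein and P_lim a limiting
  protein that prevents unbounded growth.

Six **variants** differ in which positive-feedback loop is active: none
(`NO_FEEDBACK`), autonomous PKMζ synthesis with (`PKM_TAG_COUPLED`) or
without (`PKM_AUTONOMOUS`) PKMζ coupling into the tag, CaMKII autoactivation
(`CAMKII_AUTONOMOUS`), weight-dependent stochastic reactivation
(`REACTIVATION`; Gaussian inter-event intervals, amplitudes ∝ a 5th-power
Hill function of W), and a synergy variant (`SYNERGY`) in which weakened
reactivation and weakened PKMζ feedback maintain L-LTP only together.

Analysis tools compute L-LTP magnitude (percent increase of W over its
pre-stimulus baseline), one-at-a-time relative sensitivities
S_i = |ΔR/R| / |Δp_i/p_i| for ±15% perturbations of the 43 registered
parameters, kinetic summaries (decay constants, elevation durations), and
bistable-state classification for PKMζ-inhibition experiments.

## Worked example

```python
from ltpsim import run_preset
from ltpsim.analysis import elevation_duration

res = run_preset("fig2a")          # no-feedback induction, 3 tetani
m = res.measurement
print(f"L-LTP: {m.percent:.1f}%")  # -> L-LTP: 132.2%
print(f"ERKPP elevated {elevation_duration(res.trajectory, 'ERKPP', 20.0):.0f} min")
                                   # -> ERKPP elevated 93 min
```

The first number is the model's readout of potentiation: synaptic weight W
rises from 3.04 to 7.07 two hours after the last tetanus, a 132.2% increase
— the size of a typical empirical L-LTP. The second shows ERK stays active
for ~1.5 h post-tetanus, the slowest of the induction kinases.

More narrative walk-throughs live in `examples/` (induction, maintenance by
each variant, PKMζ-inhibition experiments, synergy switch-offs, sensitivity
scanning, the reactivation interval generator); each prints the quantities
it computes and what they mean.

A thin CLI wraps the same library:

```bash
ltpsim list-presets
ltpsim simulate --preset fig2a --out out/ --plot
ltpsim sensitivity --names RAF_TOT,k_phos1
ltpsim inhibition-threshold --seeds 0,1,2,3,4
```

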