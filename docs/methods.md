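# Methods

## Model structure

The simulator integrates a 15-variable ODE model of one synapse:

| block | variables | notes |
|---|---|---|
| kinases | `CaMKII_act`, `PKA_act`, `RAFP`, `MEK`, `MEKPP`, `ERK`, `ERKPP` | `PKA_act` is a dimensionless activity fraction (it relaxes toward a Hill fraction of cAMP); the inactive Raf pool and the singly phosphorylated MEK/ERK forms follow from conservation of each total (0.25 µM each) and are never integrated |
| tag | `Tag1`, `Tag2`, `Tag3` | fractional phosphorylation of three sites, substrates of CaMKII, PKA, ERKPP; `TAG` is their product |
| PKMζ | `P_CK2`, `P_ERK`, `PKM_act` | synthesis rate ∝ `P_CK2`·`P_ERK` plus a basal term, first-order deactivation (0.02 min⁻¹ standard) |
| weight | `W`, `P_lim` | weight production ∝ `TAG`·PRP·`PKM_act`·`P_lim`/(`P_lim`+K_lim), first-order decay |

All internal times are minutes and concentrations µM; the 3-s Ca²⁺ pulse is
stored as 0.05 min. Stimulus events elevate Ca²⁺ for 0.05 min and cAMP and
the Raf activation rate constant for 1 min, all three channels starting
simultaneously at event onset (durations are specified, relative offsets are
not, so simultaneity is the simplest convention). Tetanus trains use
onset-to-onset inter-stimulus intervals; at the standard 5-min ISI the
1-min channel elevations never overlap.

Positive feedback enters as (i) a quadratic Hill autoactivation term on
CaMKII or PKMζ, (ii) an additive tag-coupling term `k_TPKM·PKM_act` in the
tag-coupled variant, and (iii) weight-dependent reactivation: spontaneous
events whose channel amplitudes are the tetanus amplitudes times a 5th-power
Hill function of W (half-saturation K_W = 4), floored at basal values. A
feedback loop that a variant lacks has its strength constant set to zero, so
the equations are uniform across variants; only the reactivation event
stream is structurally switched. The synergy variant additionally scales
reactivation amplitudes by 0.8 (a separate scale factor that leaves tetanus
amplitudes untouched, since the weakening applies to the reactivation
equations only) — applying it to reactivation only is our resolution of an
ambiguity in whether induction tetani are also weakened.

## Numerical scheme

Forward Euler with dt = 10 ms (1/6000 min) is the reference integrator;
classical RK4 at the same step is built in as an oracle and agrees with
Euler to ≲0.01% on the induction protocol. Square-wave events are aligned to
the step grid (the 3-s and 1-min durations are exact multiples of dt;
validated at configuration time). The update order per step is fixed:
evaluate forcing → evaluate derivatives → update → clamp/log. Any state
pushed out of its admissible range by discretization error is clamped to the
bound and counted; at dt = 10 ms no clamps occur in any shipped protocol,
and the count is recorded in every trajectory. The inner loop is
numba-compiled and advances ≈10⁷ steps/s on one CPU, so the multi-day
protocols below are seconds of wall time.

Before any stimulus the model is equilibrated under basal forcing for at
least two simulated days (2880 min). Fast variables must drift by less than
1 part in 10⁶ over the last simulated hour, or equilibration fails loudly.
The two slowest variables are then overwritten with closed-form basal fixed
points determined by the equilibrated fast variables: `PKM_act` from its
synthesis/decay balance (the smallest nonnegative root when autoactivation
makes the balance bistable, found by bracketing and bisection), then `W`
from its production/decay balance. Inhibition experiments instead start from
an "upper-state" snapshot: equilibration, standard induction, then 2000 min
of maintenance; the snapshot errors out if W has not reached 1.5× basal.

## Parameter conventions

Standard values follow the model's standard constant set; the six variant
presets override only their per-variant constants (e.g. `k_ltp` = 500 / 300 /
240 / 70 / 480 / 180 µM⁻² min⁻¹ across the six variants; the reactivation
variant slows weight decay to τ_ltp = 3200 min with basal production
0.00086 min⁻¹). PRP is a constant 1.0 µM parameter, not a state variable.
Reactivation intervals are Gaussian — mean 500 min, SD 150 min (200/50 in
the synergy variant) — drawn with the classical Box–Muller transform from a
seeded uniform stream, one fresh pair of uniforms per interval (cosine
branch). Intervals below the 10-min floor are clamped to 10 rather than
resampled; at the standard settings this shifts the mean by <0.1%.
Reactivation amplitudes use W sampled at event onset and hold it for the
event's ≤1-min duration, over which W changes negligibly (τ_ltp ≥ 300 min).

Two equation readings were genuinely open and are resolved as follows:

- **PKA relaxation.** The activity equation is read as
  d`PKA_act`/dt = (f₃ − `PKA_act`)/τ_PKA with τ_PKA = 15 min — division by
  the time constant is required for the stated 15-min post-tetanus decay,
  which the simulator reproduces exactly.
- **P_lim decay.** The final term of the P_lim equation is read as
  −`P_lim`/τ_Pl (decay of P_lim, by structural analogy with the weight
  equation); the typographically possible −W/τ_Pl reading leaves basal
  P_lim undetermined and is available behind the documented
  `plim_weight_decay` protocol flag for comparison. Under the default
  reading basal P_lim = k_Plbas·τ_Pl = 0.35 µM.

**PKMζ inhibition is effector-level:** during an inhibition window a
fraction of `PKM_act` is hidden from its downstream actions (weight
production and the tag-coupling term) while the state variable itself keeps
evolving, and the autoactivation term continues to see the full `PKM_act`.
This models a catalytic-site inhibitor and reproduces both repotentiation
after washout in the CaMKII variant and the permanent collapse under long
inhibition in the reactivation variant.

## Sensitivity registry

The one-at-a-time scan perturbs exactly 43 parameters per variant by ±15%
(86 variations). The 43-entry count does not come with a canonical
enumeration, so membership is frozen here as a documented table: 40 shared
parameters (all standard constants except the two square-pulse durations and the
two basal floors, which define the stimulus shape rather than the kinetics)
plus 3 variant-specific feedback parameters. Zero-valued feedback strengths
remain registered; their multiplicative variations are identically zero, as
expected for 2–3 entries per variant. Changing membership is a breaking
change. For stochastic (reactivation) simulations, baseline and perturbed
runs share the reactivation seed so S_i reflects the parameter change, not
event noise. A perturbed parameter set can lose its basal fixed point (e.g.
the PKMζ Hill constant lowered enough for the switch to turn itself on); the
scan then doubles the equilibration window until convergence rather than
failing the row. The four standard assessed simulations are the no-feedback
induction and the PKMζ-autoactivation run (both quantified 2 h
post-stimulus; neither is bistable in W) and the CaMKII and reactivation
runs (quantified 50 h post-stimulus). The "13 exceptions" tally counts
direction-resolved variations reaching S ≥ 3 in at least one assessed
simulation; the report exposes both the per-variation and per-parameter
tallies.

## Measurement conventions

L-LTP magnitude is 100·(W(t_assess) − W_pre)/W_pre with W_pre sampled
immediately before the first tetanus. Elevation durations use a 90%-recovery
criterion: time from a reference point until a variable has recovered 90% of
its peak elevation back toward its pre-stimulus baseline. The criterion is a
convention — the durations the model is known for are approximate — and
the fraction is an explicit argument everywhere. Bistable-state
classification uses the midpoint between a variant's basal W and its
maintained upper-state W, both measured from reference runs of the same
build, never hard-coded.

Under these conventions the build reproduces: 132.2% L-LTP at 2 h
(no feedback), PKA decay τ = 15.0 min, CaMKII decay τ = 1.00 min, ERKPP
elevation 92.7 min, and a median minimum effective duration of 90% PKMζ
inhibition of ~2.5 simulated days (5 seeds, 600-min duration grid) for the
reactivation variant. Two summary figures commonly quoted for this model do
not follow from its own equations and standard parameters in this build: the
peak PKA rise during induction computes to ~221% (not ~150%; a three-pulse
accumulation with τ = 15 min and the standard amplitudes cannot stay near
150%), and the post-tetanus weight recovery takes ~13.6 h at the 90%
criterion (not ~10 h; with τ_ltp = 300 min and the weight peaking ~2.5–4 h
post-tetanus, 90% recovery necessarily exceeds 11 h). Both computed values
are reported as-is.

With the standard per-variant constants, the tag-coupled PKMζ variant's
maintained state is robust to ±15% Raf-ERK perturbations (S ≈ 0.2–0.4 at
the 50-h assessment) while the no-feedback, PKMζ-autoactivation, CaMKII and
reactivation simulations show the expected strong Raf-ERK sensitivities
(S ≈ 3–10); the S ≈ 7 response of the PKMζ-autoactivation simulation to a
15% decrease of its Hill constant arises because the perturbed model loses
its basal PKMζ fixed point and the response measure collapses.

## What the protocols do and do not emulate

The stimulus protocols emulate tetanic induction and spontaneous replay as
idealized square waves with fixed amplitudes; they do not model Ca²⁺/
calmodulin binding kinetics, Ras activation, phosphatase dynamics, spatial
compartments, stochastic chemistry at small copy number, protein turnover of
the kinases themselves, transcriptional feedback, or the network origin of
reactivation frequency (interval statistics are fixed inputs, not derived
from an engram model). Passing tests therefore show that the implemented
equations reproduce the reported dynamics under these idealizations — not
that the biological mechanisms behave this way in tissue.

## Problem sizes used in the shipped checks

Test and acceptance runs use the standard dt = 10 ms throughout: the
induction protocol runs 1280 min of model time, maintenance and bistability
checks run 50–100 h, the inhibition-duration sweep covers four durations ×
five seeds (~8000 min each), and the sensitivity subset scans four
simulations × three to four parameters. The full 86-variation × 4-simulation
scan is exposed through the library and CLI; at roughly 5 s per variation
run it takes a few hours on one CPU and is not part of the test suite.
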