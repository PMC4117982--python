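# Model and methods

## The model

`axonwave` simulates the central, myelinated axon of an auditory-nerve
fiber as a one-dimensional chain of isopotential compartments. Seven nodes
of Ranvier alternate with six internodal regions (INR) of 100 um; each INR
is subdivided symmetrically into paranode (PN), juxtaparanode (JP) and a
central axonal stretch:

    node | PN JP axon JP PN | node | ... | node      (7 nodes, 6 INRs)

Membrane potential obeys the cable equation with Hodgkin–Huxley-style
currents,

    C_m dV/dt = -I_Na - I_HT - I_LT - I_L + I_axial + I_stim

    I_Na = g_Na m^3 h (V - V_Na)                    (nodes)
    I_HT = g_HT n^3 (1 - γ + γp) (V - V_HT)         (nodes, Kv3.1-type)
    I_LT = g_LT l r (V - V_LT)                      (juxtaparanodes, Kv1.1-type)
    I_L  = g_L (V - V_L)                            (everywhere)

Every gate `j ∈ {m,h,n,p,l,r}` follows `dj/dt = α_j(V)(1−j) − β_j(V) j`
with purely exponential rate laws `α = k_α exp(η_α V)`,
`β = k_β exp(η_β V)` (V in mV, rates in 1/ms).

Dysmyelination after acoustic overexposure (AOE) is modelled in two
scenarios built from the same measured post-exposure geometry:

* **AOE1** — channels spread evenly over the remodeled subdomains. Every
  region takes its AOE dimensions and channel densities are rescaled by
  the control/AOE area ratio, so the *number* of channels per region is
  conserved exactly (verified to machine precision in the tests).
* **AOE2** — channels stay put. The node keeps its original 1.3 um length
  (at the enlarged 1.28 um diameter) flanked by passive bare-membrane
  inserts `n1`; the JP keeps its original extent, with myelinated passive
  inserts `j1` absorbing the elongation. Densities are unchanged.

## Parameters and units

Internal units are chosen so that uS·mV = nA and nF·mV/ms = nA: potentials
in mV, time in ms, current in nA, conductance in uS, capacitance in nF,
axial resistance in MOhm; densities are specified in mS/cm² and uF/cm².

| parameter | default | notes |
|---|---|---|
| g_Na, g_HT, g_LT | 50, 15, 2 mS/cm² | preset `equations`; an alternative set (6.6, 1.98, 2.13) ships as preset `capacitance-derived` |
| V_Na, V_HT = V_LT, V_L | +50, −80, −63 mV | |
| nodal g_L | 0.2 mS/cm² | also used for bare `n1` inserts |
| internodal C_m, g_L | 0.0184 uF/cm², 10.89 uS/cm² (control); 0.0290, 20.3 (AOE) | myelin folded into one effective membrane (single-cable model) |
| R_a | 70 Ohm·cm | uniform; extracellular resistance zero; sealed ends |
| γ | 0.1 | the weight of the slow `p` gate in I_HT is not constrained by the source data set; it is exposed in configuration |
| internode length | 100 um | the central `axon` region is stretched so each INR totals exactly this length |

**Sodium activation backward rate.** The parameter tabulation this model
derives from prints `k_β` of the m gate as 0.0381 /ms. Under that value
the Na activation midpoint sits near −95 mV: sodium channels are open at
rest, the axon settles at a depolarized potential (≈ −41 mV) with h ≈
0.04, and no action potential can be evoked or conducted — inconsistent
with every behavior the model is meant to produce. `axonwave` treats the
figure as a decimal transcription error and uses **3.81 /ms**, which
places the midpoint at −37.5 mV with τ_m ≈ 0.03 ms, yields a resting
potential of −68.46 mV (computed by the settle phase and frozen as a
regression value), and recovers conduction at ≈ 6.2 m/s, a ≈ 3-fold
dysmyelination slowing, and conduction block near 34% of control g_Na —
three independent quantitative behaviors from the single-digit
correction. The literal table ships as `RATE_PARAMS_TABULATED`
(configuration `channels.rate_table: tabulated`) for sensitivity analysis.

The gating ODE is the standard form `α(1−j) − βj`; I_LT uses first-power
`l·r` (exponents configurable). I_LT resides in the JP by default, with a
`lt_location: PN` switch.

## Discretization and solver

Each region is split into equal sub-compartments no longer than 0.1 λ of
the local length constant λ = sqrt(rad·R_m/(2·R_a)), with R_m taken from
the region's effective leak. Compartment areas are cylindrical lateral
surfaces; axial resistances sum the two half-compartment terms
4·R_a·(l/2)/(π d²). Under the default geometry this yields 37 compartments;
halving the λ fraction leaves the control conduction velocity within 2%
(and a 0.02 fraction, 49 compartments, within 0.5%).

Time stepping is backward Euler for the voltage — a symmetric tridiagonal
solve per step over the unbranched chain — with a staggered gate update:
rates are frozen at the current voltage and each gate advanced by its
exact exponential relaxation, which keeps gates in [0,1] unconditionally.
Single-compartment trajectories agree with an independent adaptive
stiff-ODE solution of the same equations to better than 1 mV.

Initialization sets all compartments to −63 mV with gates at steady state,
then relaxes stimulus-free for 50 ms (the slowest gate, r, has τ ≈ 10 ms
near rest); the residual max|dV/dt| is checked against 10⁻³ mV/ms.
Settling runs at 0.01 ms; recorded windows use 0.000625 ms for velocity
measurements — the end-to-end conduction delay is only ≈ 0.1 ms, and the
measured velocity changes by < 0.5% on a further halving of the step —
and 0.01 ms for long spike-counting runs.

## Measurement protocols

**Spikes and velocity.** A spike is a local maximum above 0 mV; peak times
are refined by a three-point parabolic fit. Conduction velocity is the
axial center-to-center distance from node 0 to node 6 divided by the delay
between their first spike peaks.

**Orderly-conduction stimulus rule.** The printed passive values give
internodal length constants near 2 mm, so the 0.6 mm cable is
electrotonically compact. Two consequences shape the protocol. First,
injected charge spreads quickly along the whole cable, so overdriving the
stimulus inflates the apparent velocity. Second, near-threshold stimuli
can make the entire cable ignite almost simultaneously after a long
latency — occasionally back-to-front from the sealed distal end — which is
not a traveling wave. A velocity measurement therefore uses the *smallest*
amplitude on a ×1.25 geometric ladder starting at 0.2 nA (0.2 ms pulse at
node 0) whose response is *orderly*: every node spikes, arrival times are
non-decreasing along the cable (1 us slack), and the end-to-end delay is
at least 10 us. Because conduction is partly electrotonic, the measured
velocity still rises with stimulus amplitude above this minimum; the
ladder makes the protocol reproducible and comparable across conditions
rather than amplitude-independent.

**Dysmyelination sweeps.** The k affected internodes are those adjacent
to the distal measurement node, keeping the stimulated node 0 in control
condition; the sweep runs at the fixed 0.2 nA default and flags
configurations whose response fails the orderly gate. Velocity falls
strictly with k over the conducting range (k ≤ 3); beyond it, AOE1
genuinely fails to conduct (mid-cable nodes stay below 0 mV) and AOE2
enters collective ignition.

**Block threshold.** Nodal g_Na is scaled by a fraction and bisected
between 1 (conducting) and 0 (blocked), testing whether an AP evoked with
the fixed default pulse reaches node 6; the bracket midpoint is reported
at 1% resolution. The threshold moves by < 1 percentage point when the
time step is halved.

**Firing rate.** A 200 ms step at node 0, spikes counted at node 3.

## What the model does and does not reproduce

With the corrected β_m the package reproduces: a control velocity of
6.17 m/s; a 3.0-fold slowing when all six internodes are dysmyelinated
(AOE1); conduction block at 34% of control nodal g_Na with monotone
slowing above it; and velocities within 2–12 m/s with a clear plateau over
the 100–300 um internode range. AOE2 conducts ≈ 40% faster than AOE1
rather than equally: its compact full-density nodes regenerate more
strongly than AOE1's diluted ones, with only passive load added.

Two behaviors are *not* attainable under the printed passive parameters,
and the corresponding tests are expected to fail:

* **Repetitive firing.** The 7-node cable's input resistance is of order
  200 MOhm while its total K⁺-plus-leak conductance can repolarize only a
  few hundredths of a nA of sustained drive; any suprathreshold 200 ms
  step therefore produces one spike followed by a depolarized plateau
  (depolarization block), at every amplitude between 0.05 and 1 nA and in
  every condition. Sustained firing at tens to hundreds of Hz would
  require roughly an order of magnitude more membrane conductance.
  Cross-condition rate *equality* still holds (all conditions respond
  identically), but regular inter-spike intervals do not exist.
* **Short-internode velocities.** At a 50 um internode the 7-node cable is
  ≈ 0.3 mm long and nearly isopotential, so end-to-end conduction is
  electrotonic and the measured velocity (~25 m/s) exceeds the
  physiological 2–12 m/s band that holds for 100–300 um.

## Test fixtures

The synthetic miniature axons used by the tests (`make_fixture`) exercise
closed forms rather than emulate data: a single nodal compartment (ODE
oracle), a 6 mm passive cylinder (RC charging, exp(−x/λ) decay, exact
charge bookkeeping), and a 3-node control chain (I/O round trips). They
share no statistics with real recordings; passing tests demonstrate
numerical correctness of the solver and constructors, not physiological
realism of the parameter set.

## Known limitations

Single-cable myelin (no explicit periaxonal space — a double-cable
representation would slow and stabilize conduction), no temperature
scaling, deterministic gating only, uniform unbranched geometry, and no
compound-action-potential population modelling. The `describe`, `cv`,
`*-sweep`, `fi-curve` and `leak-trace` CLI subcommands expose every
protocol; all results are bit-reproducible from the resolved-config
sidecars written next to each output.
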