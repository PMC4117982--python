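# axonwave

Compartmental simulation of saltatory conduction in the central
auditory-nerve axon, and of how noise-induced dysmyelination slows or
blocks it.

Loud-sound exposure that causes hearing loss also remodels the myelin
subdomains of auditory-nerve fibers: nodes of Ranvier elongate,
paranodes retract, juxtaparanodes stretch, and myelin thins. `axonwave`
is a biophysical model for asking *which* of these changes degrades
conduction — the redistribution of voltage-gated channels, or the loss
of sodium-channel density. It is aimed at auditory neuroscientists and
computational neuroscience students who want a small, fully inspectable,
dependency-light cable model rather than a general-purpose simulator.

## The model

A single myelinated axon is built as seven nodes of Ranvier alternating
with six 100 um internodes, each internode subdivided into paranode (PN),
juxtaparanode (JP) and a central axonal stretch. Membrane dynamics follow
the cable equation with Hodgkin–Huxley-style currents

    I_Na = g_Na m³h (V − V_Na)           nodal fast sodium
    I_HT = g_HT n³(1−γ+γp) (V − V_HT)    nodal Kv3.1-type (high threshold)
    I_LT = g_LT l·r (V − V_LT)           juxtaparanodal Kv1.1-type (low threshold)
    I_L  = g_L (V − V_L)                 leak

with exponential rate laws α = k_α e^{η_α V}, β = k_β e^{η_β V} for every
gate, backward-Euler integration of the tridiagonal cable system, and
exact exponential gate updates. Dysmyelination is modelled two ways:
channels redistributed evenly over the enlarged subdomains with total
channel number conserved (**AOE1**), or channels held at their original
positions with passive insert regions taking up the new membrane
(**AOE2**). See `docs/methods.md` for the full parameter tables, the
solver, the measurement protocols, and the package's documented
correction of one transcribed rate constant.

## Worked example

```python
import axonwave as aw

cable = aw.discretize(aw.build_axon("control"))
print(f"compartments: {cable.n_comp}, nodes: {len(cable.node_center_idx)}")

res = aw.measure_cv(cable)
print(f"control CV: {res.velocity_m_per_s:.2f} m/s "
      f"(distance {res.distance_um:.1f} um, delay {res.delay_ms*1e3:.1f} us, "
      f"stimulus {res.stimulus_na:.2f} nA)")

aoe = aw.measure_cv(aw.discretize(aw.build_axon("AOE1")))
print(f"AOE1 CV: {aoe.velocity_m_per_s:.2f} m/s -> "
      f"slowing {res.velocity_m_per_s/aoe.velocity_m_per_s:.2f}-fold")

thr = aw.find_block_threshold()
print(f"conduction block below {100*thr:.1f}% of control gNa")
```

prints

```
compartments: 37, nodes: 7
control CV: 6.17 m/s (distance 607.8 um, delay 98.6 us, stimulus 0.20 nA)
AOE1 CV: 2.03 m/s -> slowing 3.04-fold
conduction block below 34.0% of control gNa
```

Reading: an action potential evoked at node 0 crosses the 0.6 mm cable in
about 0.1 ms (6.17 m/s, measured peak-to-peak between nodes 0 and 6).
Dysmyelinating all six internodes slows conduction three-fold, and
reducing nodal sodium-channel density below about a third of control
blocks propagation outright — the two headline effects the model
quantifies.

The same experiments are available from the shell:

```sh
axonwave cv --out out/                 # conduction velocity, control
axonwave aoe-sweep --set condition=AOE1 --out out/
axonwave gna-sweep --out out/
axonwave fi-curve --out out/
axonwave describe --out out/           # one CSV row per compartment
```

Each command writes tidy CSV tables plus a resolved-configuration YAML
sidecar that reproduces the result byte-for-byte.

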