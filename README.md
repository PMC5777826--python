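# microcirc

A toolbox for the canonical cortical microcircuit of one excitatory (E)
and three inhibitory interneuron populations — parvalbumin (PV),
somatostatin (SST) and vasoactive-intestinal-peptide (VIP) expressing
cells — modelled with nonlinear firing-rate dynamics.  It is aimed at
computational neuroscientists studying state-dependent, seemingly
paradoxical circuit responses: in mouse V1, the SST population's
response to the same top-down (locomotion) signal onto VIP cells flips
sign depending on the visual input.

## Model

Each population's rate follows

    tau_r dr_i/dt = -r_i + f_i(V_i),
    V_i = V_l + (sum_j W_ij r_j + I_i + I_bkg,i) / g_l,i

with a smoothed threshold-linear f-I curve

    f(V) = (V - V_th) / (tau_m (V_th - V_r)) * 1 / (1 - e^{-(V - V_th)/v}).

`W` (pA·s) is the signed population connectivity, `I_bkg` the background
current calibrated so the circuit sits at a chosen spontaneous baseline.
At a stable fixed point the steady-state sensitivity of rates to small
external currents is the response matrix

    M = (D - W)^{-1},   D_ii = g_l,i / f'(V_i),

whose entries can take either sign regardless of the sign of the direct
connection.  The inverse gain d_i = D_ii falls from very large values
below threshold to d_i∞ = g_l,i tau_m,i (V_th - V_r) at high input; the
sign of M_SV separates the **disinhibition** regime (exciting VIP
suppresses SST) from **response reversal** (the same input ultimately
raises SST), and w_EE > d_E is simultaneously the
inhibition-stabilized-network (ISN) condition.

The package covers: background-current calibration and fixed-point
analysis, analytic step-onset transients (the universal initial SST
dip), the published closed forms of the 16 response-matrix entries with
a numeric oracle that localizes their misprints, random unit-network
expansions (quenched Bernoulli wiring, identical units), a mouse-V1
stimulus × behavioral-state condition battery with surround-suppression
size tuning and ±10% connectivity-robustness sweeps, and rejection
sampling of connectivities with the two-regime phenomenology.

## Worked example

```python
import numpy as np
import microcirc as mc

c = mc.generic_circuit("low")            # calibrated to (1, 10, 3, 2) Hz
print("background (pA):", np.round(c.i_bkg, 1))
for name in ("low", "high"):
    c = mc.generic_circuit(name)
    r = mc.steady_state(c, 0.0, r0=np.array(mc.LOW_RATES if name == "low" else mc.HIGH_RATES))
    reg = mc.classify_regime(c, r)
    rep = mc.verify_onset_against_simulation(c, r, [0, 0, 0, 10.0])
    print(f"{name:5s} baseline: M_SV = {reg.m_sv:+.3f}  regime = {reg.regime:17s} "
          f"ISN = {reg.isn}  SST: {r[2]:.1f} -> min {rep.minimum[2]:.1f} -> {rep.final[2]:.1f} Hz")
```

prints

```
background (pA): [114.7 233.6  94.3  89.9]
low   baseline: M_SV = -0.242  regime = disinhibition     ISN = False  SST: 3.0 -> min 0.6 -> 0.6 Hz
high  baseline: M_SV = +0.971  regime = response_reversal ISN = True  SST: 30.0 -> min 17.2 -> 41.3 Hz
```

The background currents hold the four populations at their spontaneous
baseline.  At the low baseline, a 10 pA top-down step onto VIP
suppresses SST monotonically from 3.0 to 0.6 Hz (M_SV < 0,
disinhibition).  At the high baseline the same step first dips SST from
30.0 down to 17.2 Hz — the initial dip is analytically universal — before
recurrent excitation reverses it to a plateau of 41.3 Hz above baseline
(M_SV > 0, response reversal); the network is then inhibition-stabilized.

A command-line interface mirrors the library
(`microcirc calibrate|simulate|respmat|onset|random-net|v1-battery|
v1-robustness|v1-size-tuning|sample-connectivity`); circuit definitions
are YAML files, with the generic and V1 circuits packaged
(`--circuit generic`, `--circuit v1`).

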