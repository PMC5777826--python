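# Methods

## Model and assumptions

The circuit is a deterministic firing-rate model: four homogeneous
populations (E, PV, SST, VIP) whose scalar rates relax with a single
rate constant `tau_r = 2 ms` towards a static f-I nonlinearity of the
population's net input.  There are no synaptic delays, conductance-based
synapses, short-term plasticity or spiking; all state dependence comes
from the curvature of the f-I curve and the signed connectivity.

The f-I curve

    f(V) = (V - V_th) / (tau_m (V_th - V_r)) * 1/(1 - e^{-(V - V_th)/v})

is smooth, strictly increasing and non-negative, with a removable
singularity at `V = V_th` where it equals `v / (tau_m (V_th - V_r))`.
Far below threshold it is exponentially flat (changes of input barely
move the rate); far above it is linear with slope
`1/(tau_m (V_th - V_r))`.  This flat-to-linear transition is the load-
bearing nonlinearity: the inverse gain `d_i(V) = g_l,i / f'(V_i)`
decreases monotonically from arbitrarily large sub-threshold values to

    d_i_inf = g_l,i tau_m,i (V_th - V_r),

and every regime statement in the package is a comparison of connection
weights against these operating-point-dependent `d_i`.  (Note the
high-input limit: since `f'` saturates at `1/(tau_m (V_th - V_r))` and
`d = g_l / f'`, the limit carries a factor `g_l`, not its reciprocal;
for the E parameters `d_E_inf = 6.25 nS * 0.028 s * 10 mV = 1.75 pA·s`.
This is the only reading under which the ISN bookkeeping is consistent:
at the low baseline `d_E = 9.36 > w_EE = 2.42` (not inhibition-
stabilized, M_SV < 0) while at the high baseline
`d_E = 1.753 < 2.42` (ISN, M_SV > 0).)

### Units

Potentials in mV, conductances in nS, currents in pA, weights in pA·s,
rates in Hz, times in seconds.  With these choices
`(pA·s)·Hz = pA` and `pA/nS = mV`, so no hidden factors of 1000 appear
anywhere; membrane time constants are stored in seconds even though the
source tables print milliseconds.  The zero-activity, zero-current input
is exactly the leak potential (−70 mV), which the test suite asserts.

## Parameters

| quantity | value | notes |
|---|---|---|
| V_th, V_r, v, V_l | −50, −60, 1, −70 mV | shared by all populations |
| g_l | 6.25, 10, 5, 5 nS | E, PV, SST, VIP |
| tau_m | 28, 8, 16, 16 ms | E, PV, SST, VIP |
| tau_r | 2 ms | rate relaxation |
| W (generic / V1) | packaged | pA·s, rows = targets |
| low / high baseline | (1, 10, 3, 2) / (30, 50, 30, 20) Hz | spontaneous rates |
| top-down current | 10 pA onto VIP | behavioral state / locomotion |

Background currents are never free parameters: they are computed from
target baseline rates by the closed-form calibration
`I_bkg = g_l (f^-1(r_t) - V_l) - W r_t - I_ext`, which is exact because
the targets pin every membrane potential.  For the generic circuit at
the low baseline this yields (114.7, 233.6, 94.3, 89.9) pA.

## Numerical choices

- **f-I evaluation.**  `u/(1 - e^{-u})` and its derivative switch to a
  Bernoulli series for `|u| < 0.25` (truncation error below 1e-12) and
  to an `e^{u}`-based form for large negative `u`, so the curve is
  smooth through threshold and overflow-free at any input.
- **f-I inversion** uses bracketed Brent root finding (`xtol = 1e-12`);
  the bracket exploits `f(V) > slope·(V - V_th)` above threshold.
- **Fixed points**: damped Newton on `g(r) = r - f(V(r))` with
  backtracking line search (residual tolerance 1e-10 Hz), falling back
  once to a 2 s simulated relaxation before retrying; non-convergence
  raises rather than returning silently.  Callers that sweep conditions
  (the V1 battery, robustness draws) catch the failure and flag the row.
- **Integration**: explicit Euler with `dt = 0.1 ms` by default
  (`dt <= tau_r/4` enforced; classical RK4 available).  The dt-halving
  endpoint change and agreement with the Newton fixed point are both
  tested below 1e-4 Hz.
- **Response matrices** are always the numeric inverse of `(D - W)`.
  The published closed forms of the 16 entries are implemented verbatim
  as a validation layer; comparing them against the inverse over random
  stable parameter draws flags exactly three entries (M_PP, M_VS, M_VV)
  as misprints — in M_PP and M_VS one product group enters with the
  wrong sign, in M_VV an outer `w_ES` should read `w_SE`.  The package
  reports, and does not silently correct, these entries.
- **Onset derivatives** are exact for a current step (the potential
  jumps by `dI/g_l` instantly), not linearized; the "initial direction"
  of a population is the sign of its first non-vanishing derivative with
  a 1e-6 dead band absorbing the solver residual, and trajectory dips
  smaller than 1e-3 Hz are ignored.
- **Empirical validation of M** uses ±0.01 pA two-sided perturbations
  with one Richardson extrapolation step.

## Random unit networks

Each population is expanded into identical rate units (800, 100, 50, 50
by default) wired by independent Bernoulli draws with population-block
probabilities; nonzero connections carry `W_ij / m_ij` with `m_ij` the
expected in-degree, so the mean total input per target unit equals the
population weight.  The published probability table carries an
inhibitory minus sign on the SST←VIP entry; its magnitude (0.55) is
used, and the normalization is surfaced wherever the table is consumed.
Self-connections are excluded; diagonal blocks therefore normalize by
`p (N - 1)` instead of `p N`, an `O(1/N)` refinement that makes the
all-to-all network reproduce the population model exactly, unit by unit
(a test asserts this to 1e-10).  Units are identical by construction, so
all response heterogeneity — including opposite-sign modulations inside
one population — is attributable to the quenched wiring alone.  What the
generator deliberately omits from real cortex: intrinsic cell-to-cell
parameter variability, weight jitter, correlated (non-Bernoulli) wiring
and spiking noise; passing tests therefore speak to connectivity-induced
diversity only, not to the full biological variance.

Modulation experiments run 0.3 s of baseline and 0.3 s of stimulation
(initialized at the population fixed point so the pre-epoch only absorbs
the quenched transient) and average the last 100 ms of each epoch;
window drift above 1e-3 Hz triggers a non-stationarity warning.

## Mouse-V1 battery

Visual input enters as currents: darkness is zero; a gray screen is
50 pA to E; a grating of diameter θ drives
`I_i(θ) = a_i/(1 + e^{-θ/b_i}) + 5 pA` with a center channel to E
(a_E = 100 pA, b_E = 2°, saturating by ~20°) and a surround channel to
SST (a_S = 20 pA, b_S = 6°, saturating by ~60°); the scale mismatch
yields the non-monotone E size-tuning curve (surround suppression).
The +5 pA offset applies to gratings only — darkness and gray screen
use their explicit constants.  Locomotion adds the 10 pA VIP current.
The pre-stimulus immobility baseline is not uniquely fixed by the
published rate figures; the package defaults to the generic low baseline
(1, 10, 3, 2) Hz, configurable, and the default grating diameter is 25°
(past E-input saturation, below SST saturation) — both recorded in every
report as assumptions.  Qualitative claims are codified as sign
predicates with a 1e-2 Hz dead band.

Robustness sweeps multiply every nonzero weight by an independent
uniform factor in [0.9, 1.1], recalibrate the background to the same
baseline, rerun the battery and score the sign pattern; unstable draws
are counted and reported, and the preservation rate among stable draws
carries an exact binomial 95% CI.  Structural variants (PV→VIP, PV→SST
projections; thalamic input to PV) are supported with explicit extra
weights — the sources disagree on these projections and print no
magnitudes, so the 0.1 pA·s default is a placeholder that must be set
deliberately for any scientific use.

At the grating operating point the local diagnostic M_SV is marginally
negative under immobility yet the finite 10 pA locomotion step ends in
the reversal regime and raises SST: near the regime boundary the sign
of a finite response is decided along the path, not by the
infinitesimal derivative at the start.  The coherence test encodes
exactly this.

## Rejection sampling

Connectivity fixtures are drawn with log-uniform magnitudes in
[0.1, 5] pA·s on the microcircuit sign pattern and accepted by a
composable predicate (default: stable fixed points at both baselines,
disinhibition at low, reversal at high).  The packaged generic matrix
itself passes the full predicate.  Draw counts and per-stage attrition
are reported; all randomness flows through explicit seeds.

## Problem sizes used in the checks

The shipped test suite runs the unit-network consistency check at the
full published counts over 10 seeds, the robustness sweep at 100 draws,
and the closed-form/inversion comparison over 100 stable parameter
draws; module-level unit tests use reduced networks (tens of units) for
the same properties.  The acceptance script recomputes only the
deterministic calibration, which needs no sampling.

## Known limitations

- Population-level results assume a unique relevant fixed point per
  condition; the solver seeds Newton from the intended baseline and
  would need basin analysis to rule out multistability in general.
- The high-baseline background currents, the V1 pre-stimulus rates and
  the exhibited grating diameter are not pinned by published numbers;
  only the low-baseline calibration is quantitatively verifiable.
- Comparisons to calcium-fluorescence measurements are sign/ordering
  only; no fluorescence-to-rate mapping is attempted.
- Euler integration is first order; the RK4 option exists for stiff
  parameter explorations but the default dt already resolves `tau_r`
  by a factor 20.
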