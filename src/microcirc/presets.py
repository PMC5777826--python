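"""Published parameter sets for the E/PV/SST/VIP microcircuit.

Two connectivity matrices are packaged: the generic microcircuit used for
the regime analysis, and the mouse-V1 variant used for the
locomotion/visual-stimulation battery.  Connection weights are in pA·s
(total charge per presynaptic spike delivered to the population), rows
are targets, columns sources, population order (E, P, S, V).

The random unit-network connection probabilities carry one documented
quirk: the published SST<-VIP entry is printed with a minus sign even
though it is a probability.  Its magnitude (0.55) is used here — the
inhibitory sign lives in the weight matrix, not in the wiring
probability — and the normalization is surfaced whenever the table is
used (see :data:`TABLE_P_SIGN_NOTE`).
"""

from __future__ import annotations

import numpy as np

from .circuit import Circuit, calibrated
from .fi import FICurve

__all__ = [
    "POPULATIONS",
    "FI_PARAMS",
    "W_GENERIC",
    "W_V1",
    "CONNECTION_PROBS",
    "UNIT_COUNTS",
    "LOW_RATES",
    "HIGH_RATES",
    "TOP_DOWN_PA",
    "generic_circuit",
    "v1_circuit",
]

POPULATIONS = ("E", "P", "S", "V")

#: f-I parameters per population: leak conductance g_l (nS) and membrane
#: time constant tau_m (s); threshold/reset/leak potentials are shared.
FI_PARAMS = {
    "E": FICurve(tau_m=0.028, g_l=6.25),
    "P": FICurve(tau_m=0.008, g_l=10.0),
    "S": FICurve(tau_m=0.016, g_l=5.0),
    "V": FICurve(tau_m=0.016, g_l=5.0),
}

#: Generic microcircuit connectivity (pA·s); rows targets, cols sources.
W_GENERIC = np.array(
    [
        [2.42, -0.33, -0.80, 0.00],
        [2.97, -3.45, -2.13, 0.00],
        [4.64, 0.00, 0.00, -2.79],
        [0.71, 0.00, -0.16, 0.00],
    ]
)

#: Mouse-V1 connectivity (pA·s).
W_V1 = np.array(
    [
        [3.30, -3.48, -2.98, 0.00],
        [1.73, -4.25, -1.07, 0.00],
        [3.50, 0.00, 0.00, -4.51],
        [0.53, 0.00, -0.13, 0.00],
    ]
)

#: Unit-to-unit connection probabilities for the random network model.
CONNECTION_PROBS = np.array(
    [
        [0.02, 1.00, 1.00, 0.00],
        [0.01, 1.00, 0.85, 0.00],
        [0.01, 0.00, 0.00, 0.55],
        [0.01, 0.00, 0.50, 0.00],
    ]
)

TABLE_P_SIGN_NOTE = (
    "the published SST<-VIP connection probability is printed as -0.55; "
    "its magnitude 0.55 is used (probabilities are non-negative; the "
    "inhibitory sign belongs to the weight matrix)"
)

#: Units per population in the random network model.
UNIT_COUNTS = (800, 100, 50, 50)

#: Spontaneous baseline rates (Hz) defining the two operating regimes.
LOW_RATES = (1.0, 10.0, 3.0, 2.0)
HIGH_RATES = (30.0, 50.0, 30.0, 20.0)

#: Top-down (behavioral-state) modulatory current onto VIP cells (pA).
TOP_DOWN_PA = 10.0

_BASELINES = {"low": LOW_RATES, "high": HIGH_RATES}


def _build(W: np.ndarray, baseline) -> Circuit:
    c = Circuit(populations=POPULATIONS, fi=tuple(FI_PARAMS[p] for p in POPULATIONS), W=W)
    if baseline is None:
        return c
    if isinstance(baseline, str):
        baseline = _BASELINES[baseline]
    return calibrated(c, baseline)


def generic_circuit(baseline: str | tuple | None = "low") -> Circuit:
    """Generic microcircuit, background-calibrated to ``baseline``.

    ``baseline`` is "low" (1, 10, 3, 2 Hz), "high" (30, 50, 30, 20 Hz),
    an explicit rate tuple, or None for an uncalibrated circuit.
    """
    return _build(W_GENERIC, baseline)


def v1_circuit(baseline: str | tuple | None = "low") -> Circuit:
    """Mouse-V1 circuit; the default baseline is the pre-stimulus,
    immobility condition (low spontaneous rates)."""
    return _build(W_V1, baseline)
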