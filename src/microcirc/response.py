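"""Steady-state linear response of the microcircuit: M = (D - W)^-1.

At a stable fixed point, a small change dI_j of the external current to
population j shifts the rates by dr_i = M_ij dI_j with

    M = (D - W)^-1,   D_ii = g_l,i / f'(V_i)   [pA·s]

The diagonal "inverse gain" d_i = g_l,i/f'(V_i) is the state-dependent
quantity: it diverges far below threshold and decreases monotonically to
d_i_inf = g_l,i tau_m,i (V_th - V_r) at high input.  Whether recurrent
excitation exceeds the inverse E gain (w_EE > d_E) separates the
disinhibition regime (M_SV < 0: exciting VIP suppresses SST) from the
response-reversal regime (M_SV > 0), and is also the
inhibition-stabilized-network (ISN) condition.

The 16 entries of M for the 4-population microcircuit also have published
closed forms in terms of w = |W| and d.  They are implemented verbatim in
:func:`response_matrix_symbolic`; three of them disagree with the direct
matrix inverse and are documented in :data:`KNOWN_TYPO_ENTRIES`.  The
numeric inverse is canonical throughout; the closed forms are a
validation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit, net_input
from .fi import FICurve

__all__ = [
    "ResponseMatrix",
    "CriticalPointError",
    "response_matrix_numeric",
    "response_matrix_symbolic",
    "symbolic_numeric_report",
    "KNOWN_TYPO_ENTRIES",
    "MICROCIRCUIT_ZERO_PATTERN",
    "d_infinity",
    "classify_regime",
    "RegimeReport",
    "ei_response_matrix",
]


class CriticalPointError(RuntimeError):
    """D - W is singular: the operating point sits at a critical point."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Gain matrix M (Hz/pA) with its D-matrix provenance.

    ``d`` holds the diagonal inverse gains (pA·s), ``C`` = 1/det(D - W),
    and ``rates``/``V`` record the operating point.
    """

    M: np.ndarray
    d: np.ndarray
    C: float
    rates: np.ndarray
    V: np.ndarray
    populations: tuple[str, ...]

    def entry(self, target: str, source: str) -> float:
        return float(self.M[self.populations.index(target), self.populations.index(source)])


def response_matrix_numeric(
    c: Circuit, r_star: np.ndarray, i_ext=0.0, residual_tol: float = 1e-6
) -> ResponseMatrix:
    """Response matrix at the fixed point ``r_star`` by direct inversion."""
    r_star = np.asarray(r_star, dtype=float)
    V = net_input(c, r_star, i_ext)
    res = np.linalg.norm(r_star - c.rates_of(V), np.inf)
    if res > residual_tol:
        raise ValueError(f"r_star is not a fixed point (residual {res:.3g} Hz)")
    d = c.g_l / c.gains_of(V)
    A = np.diag(d) - c.W
    det = np.linalg.det(A)
    if abs(det) < 1e-12 * np.linalg.norm(A, ord="fro") ** c.n_pop:
        raise CriticalPointError("D - W is singular at this operating point")
    return ResponseMatrix(
        M=np.linalg.inv(A), d=d, C=1.0 / det, rates=r_star, V=V,
        populations=c.populations,
    )


# ---------------------------------------------------------------------------
# Published closed forms for the 4-population microcircuit
# ---------------------------------------------------------------------------

#: Entries (target, source) that must vanish in the microcircuit wiring:
#: VIP projects only to SST; PV projects to E and PV; SST receives no
#: inhibition except from VIP.
MICROCIRCUIT_ZERO_PATTERN = (
    ("E", "V"), ("P", "V"), ("S", "P"), ("S", "S"), ("V", "P"), ("V", "V"),
)

#: Closed-form entries whose published expressions disagree with the
#: direct inverse of (D - W) (established symbolically and confirmed by
#: the numeric oracle): in M_PP the w_ES(w_SE d_V - w_SV w_VE) group
#: enters with the wrong sign; in M_VS the w_VS((w_EE-d_E)(w_PP+d_P) -
#: w_EP w_PE) group enters with the wrong sign; in M_VV the outer w_ES
#: factor should read w_SE.
KNOWN_TYPO_ENTRIES = frozenset({("P", "P"), ("V", "S"), ("V", "V")})

_POPS = ("E", "P", "S", "V")


def _closed_forms(w, d):
    """The 16 published entries (divided by C), implemented as printed."""
    wEE, wEP, wES = w[0, 0], w[0, 1], w[0, 2]
    wPE, wPP, wPS = w[1, 0], w[1, 1], w[1, 2]
    wSE, wSV = w[2, 0], w[2, 3]
    wVE, wVS = w[3, 0], w[3, 2]
    dE, dP, dS, dV = d
    return {
        ("E", "E"): (wPP + dP) * (dS * dV - wSV * wVS),
        ("P", "E"): wPE * (dS * dV - wSV * wVS) - wPS * (wSE * dV - wSV * wVE),
        ("S", "E"): (wPP + dP) * (wSE * dV - wSV * wVE),
        ("V", "E"): (wPP + dP) * (wVE * dS - wSE * wVS),
        ("E", "P"): -wEP * (dS * dV - wSV * wVS),
        ("P", "P"): -((wEE - dE) * (dS * dV - wSV * wVS) + wES * (wSE * dV - wSV * wVE)),
        ("S", "P"): -wEP * (wSE * dV - wSV * wVE),
        ("V", "P"): -wEP * (wVE * dS - wSE * wVS),
        ("E", "S"): -dV * (wES * (wPP + dP) - wEP * wPS),
        ("P", "S"): -dV * (wES * wPE - (wEE - dE) * wPS),
        ("S", "S"): -dV * ((wEE - dE) * (wPP + dP) - wEP * wPE),
        ("V", "S"): -(
            wVE * (wES * (wPP + dP) - wEP * wPS)
            + wVS * ((wEE - dE) * (wPP + dP) - wEP * wPE)
        ),
        ("E", "V"): wSV * (wES * (wPP + dP) - wEP * wPS),
        ("P", "V"): wSV * (wES * wPE - (wEE - dE) * wPS),
        ("S", "V"): wSV * ((wEE - dE) * (wPP + dP) - wEP * wPE),
        ("V", "V"): wES * (wES * (wPP + dP) - wEP * wPS)
        - dS * ((wEE - dE) * (wPP + dP) - wEP * wPE),
    }


def _check_zero_pattern(W: np.ndarray) -> None:
    for tgt, src in MICROCIRCUIT_ZERO_PATTERN:
        i, j = _POPS.index(tgt), _POPS.index(src)
        if W[i, j] != 0:
            raise ValueError(
                f"W[{tgt},{src}] = {W[i, j]} violates the microcircuit zero "
                "pattern assumed by the closed forms"
            )


def response_matrix_symbolic(W: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Evaluate the published closed forms of M on the microcircuit pattern.

    ``W`` is the signed connectivity (its zero pattern is enforced) and
    ``d`` the diagonal inverse gains.  The expressions are evaluated as
    printed, including the three entries listed in
    :data:`KNOWN_TYPO_ENTRIES` — use :func:`symbolic_numeric_report` to
    localize the discrepancies against the direct inverse.
    """
    W = np.asarray(W, dtype=float)
    d = np.asarray(d, dtype=float)
    _check_zero_pattern(W)
    w = np.abs(W)
    C = 1.0 / np.linalg.det(np.diag(d) - W)
    forms = _closed_forms(w, d)
    M = np.empty((4, 4))
    for i, tgt in enumerate(_POPS):
        for j, src in enumerate(_POPS):
            M[i, j] = C * forms[(tgt, src)]
    return M


def symbolic_numeric_report(W: np.ndarray, d: np.ndarray) -> dict:
    """Compare the published closed forms against direct inversion.

    Returns per-entry relative errors (scale set by the largest |M|
    entry) and the set of discrepant entries; for the published table
    the discrepant set equals :data:`KNOWN_TYPO_ENTRIES` on any generic
    parameter draw.
    """
    W = np.asarray(W, dtype=float)
    d = np.asarray(d, dtype=float)
    M_num = np.linalg.inv(np.diag(d) - W)
    M_sym = response_matrix_symbolic(W, d)
    scale = np.max(np.abs(M_num))
    rel = np.abs(M_sym - M_num) / scale
    discrepant = {
        (tgt, src)
        for i, tgt in enumerate(_POPS)
        for j, src in enumerate(_POPS)
        if rel[i, j] > 1e-8
    }
    return {
        "numeric": M_num,
        "symbolic": M_sym,
        "rel_error": rel,
        "discrepant": discrepant,
        "known_typos": set(KNOWN_TYPO_ENTRIES),
    }


def d_infinity(p: FICurve) -> float:
    """High-input limit of the inverse gain, g_l tau_m (V_th - V_r) (pA·s)."""
    return p.d_infinity


@dataclass(frozen=True)
class RegimeReport:
    regime: str  # "disinhibition" | "response_reversal" | "indeterminate"
    isn: bool
    m_sv: float
    w_ee: float
    d_e: float
    reversal_components: dict


def classify_regime(c: Circuit, r_star: np.ndarray, i_ext=0.0) -> RegimeReport:
    """Label the operating point by the sign of M_SV and the ISN condition.

    M_SV < 0: disinhibition (VIP excitation suppresses SST);
    M_SV > 0: response reversal.  ISN iff w_EE > d_E at the operating
    point.  The reported components (w_EE - d_E) and w_EP*w_PE are the
    two competing terms in the closed form of M_SV.
    """
    rm = response_matrix_numeric(c, r_star, i_ext)
    iE, iP = c.index("E"), c.index("P")
    iS, iV = c.index("S"), c.index("V")
    m_sv = rm.M[iS, iV]
    w = np.abs(c.W)
    w_ee, d_e = w[iE, iE], rm.d[iE]
    if abs(m_sv) < 1e-12:
        regime = "indeterminate"
    elif m_sv < 0:
        regime = "disinhibition"
    else:
        regime = "response_reversal"
    return RegimeReport(
        regime=regime,
        isn=bool(w_ee > d_e),
        m_sv=float(m_sv),
        w_ee=float(w_ee),
        d_e=float(d_e),
        reversal_components={
            "w_EE_minus_d_E": float(w_ee - d_e),
            "w_PP_plus_d_P": float(w[iP, iP] + rm.d[iP]),
            "w_EP_w_PE": float(w[iE, iP] * w[iP, iE]),
        },
    )


def ei_response_matrix(
    w_ee: float, w_ei: float, w_ie: float, w_ii: float, d_e: float, d_i: float
) -> np.ndarray:
    """Closed-form 2x2 response matrix of a fully connected E-I network.

        M = C [[w_II + d_I, -w_EI], [w_IE, d_E - w_EE]],
        C = 1 / ((d_E - w_EE)(w_II + d_I) + w_EI w_IE)

    Valid at stable operating points, where C > 0; then M_EE and M_IE
    are always positive, M_EI always negative, and M_II changes sign
    exactly at w_EE = d_E — the paradoxical (ISN) regime is w_EE > d_E.
    """
    if min(w_ee, w_ei, w_ie, w_ii) < 0:
        raise ValueError("weight magnitudes must be non-negative")
    if d_e <= 0 or d_i <= 0:
        raise ValueError("inverse gains must be positive")
    denom = (d_e - w_ee) * (w_ii + d_i) + w_ei * w_ie
    if denom <= 0:
        raise ValueError("unstable/invalid operating point (C <= 0)")
    C = 1.0 / denom
    return C * np.array([[w_ii + d_i, -w_ei], [w_ie, d_e - w_ee]])
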