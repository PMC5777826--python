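"""Rejection sampling of sign-structured connectivity matrices.

Candidate matrices are drawn with log-uniform magnitudes on a fixed sign
pattern (the microcircuit wiring diagram) and kept only if they satisfy
an acceptance predicate — typically "both baselines calibrate to stable
fixed points, the low baseline is in the disinhibition regime and the
high baseline in the response-reversal regime", which is how the
packaged generic connectivity was originally selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .circuit import Circuit, ConvergenceError, calibrated, jacobian_stability, steady_state
from .presets import FI_PARAMS, HIGH_RATES, LOW_RATES, POPULATIONS, W_GENERIC
from .response import classify_regime

__all__ = [
    "sign_pattern",
    "GENERIC_SIGN_PATTERN",
    "SampleResult",
    "sample_connectivity",
    "always_accept",
    "phenomenology_predicate",
]


def sign_pattern(W: np.ndarray) -> np.ndarray:
    """Entrywise sign of a connectivity matrix, as an int matrix in {-1,0,1}."""
    return np.sign(np.asarray(W)).astype(int)


#: Wiring diagram of the generic microcircuit (signs of the packaged W).
GENERIC_SIGN_PATTERN = sign_pattern(W_GENERIC)


@dataclass(frozen=True)
class SampleResult:
    W: np.ndarray
    n_tries: int
    rejections: dict  # reason -> count


class SamplingError(RuntimeError):
    """Rejection sampling exhausted its trial budget."""

    def __init__(self, message: str, rejections: dict):
        super().__init__(message)
        self.rejections = rejections


def always_accept(W: np.ndarray) -> bool:
    return True


def _circuit_from_W(W: np.ndarray) -> Circuit:
    return Circuit(populations=POPULATIONS, fi=tuple(FI_PARAMS[p] for p in POPULATIONS), W=W)


def phenomenology_predicate(
    low=LOW_RATES, high=HIGH_RATES
) -> Callable[[np.ndarray], bool]:
    """Acceptance predicate for the two-regime phenomenology.

    Requires that background calibration to the low and high baselines
    yields stable fixed points with M_SV < 0 (disinhibition) at the low
    baseline and M_SV > 0 (response reversal) at the high baseline.
    """

    def accept(W: np.ndarray) -> bool:
        base = _circuit_from_W(W)
        try:
            for targets, want in ((low, "disinhibition"), (high, "response_reversal")):
                c = calibrated(base, targets)
                r = steady_state(c, 0.0, r0=np.asarray(targets, dtype=float))
                if not jacobian_stability(c, r).is_stable:
                    return False
                if classify_regime(c, r).regime != want:
                    return False
        except (ConvergenceError, ValueError):
            return False
        return True

    return accept


def sample_connectivity(
    pattern: np.ndarray = GENERIC_SIGN_PATTERN,
    acceptance: Callable[[np.ndarray], bool] = always_accept,
    seed: int = 0,
    max_tries: int = 1000,
    mag_range: tuple[float, float] = (0.1, 5.0),
) -> SampleResult:
    """Draw sign-structured random connectivities until one is accepted.

    Magnitudes are log-uniform in ``mag_range`` (pA·s) on the nonzero
    entries of ``pattern``; zeros are preserved exactly.  Returns the
    accepted matrix with the number of draws used; raises
    :class:`SamplingError` with per-reason attrition counts when
    ``max_tries`` is exhausted.
    """
    pattern = np.asarray(pattern)
    lo, hi = mag_range
    if not (0 < lo < hi):
        raise ValueError("mag_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    rejections: dict[str, int] = {"predicate": 0, "error": 0}
    for k in range(1, max_tries + 1):
        mags = np.exp(rng.uniform(np.log(lo), np.log(hi), size=pattern.shape))
        W = pattern * mags
        try:
            ok = acceptance(W)
        except Exception:
            rejections["error"] += 1
            continue
        if ok:
            return SampleResult(W=W, n_tries=k, rejections=rejections)
        rejections["predicate"] += 1
    raise SamplingError(
        f"no acceptable connectivity in {max_tries} draws", rejections
    )
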