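"""Nonlinear population rate dynamics for the cortical microcircuit.

A :class:`Circuit` couples n populations through a signed connectivity
matrix ``W`` (pA·s, rows = targets, columns = sources).  The input to
population i is

    V_i = V_l + (sum_j W_ij r_j + I_i + I_bkg,i) / g_l,i        [mV]

and the rates relax towards the f-I curve output with time constant
``tau_r``:

    tau_r dr_i/dt = -r_i + f_i(V_i).

Unit convention: W in pA·s and rates in Hz give currents in pA; dividing
by g_l in nS gives mV.  Membrane time constants are stored in seconds so
rates come out in Hz with no hidden conversion factors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fi import FICurve

__all__ = [
    "Circuit",
    "InputSchedule",
    "Trajectory",
    "ConvergenceError",
    "SimulationError",
    "net_input",
    "steady_state",
    "calibrate_background",
    "calibrated",
    "simulate",
    "jacobian_stability",
    "StabilityReport",
]

DEFAULT_POPULATIONS = ("E", "P", "S", "V")


class ConvergenceError(RuntimeError):
    """Fixed-point solver failed to converge within its iteration budget."""


class SimulationError(RuntimeError):
    """Integration produced non-finite rates; carries the blow-up time."""

    def __init__(self, message: str, t_blowup: float | None = None):
        super().__init__(message)
        self.t_blowup = t_blowup


@dataclass(frozen=True)
class Circuit:
    """Populations, f-I curves, connectivity and background drive.

    ``excitatory`` marks the cell class of each (source) population; the
    sign structure of ``W`` must respect it: columns of excitatory sources
    are >= 0, columns of inhibitory sources are <= 0.  By default the
    label "E" marks the excitatory population.
    """

    populations: tuple[str, ...]
    fi: tuple[FICurve, ...]
    W: np.ndarray
    i_bkg: np.ndarray | None = None
    tau_r: float = 0.002
    excitatory: tuple[bool, ...] | None = None

    def __post_init__(self):
        n = len(self.populations)
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {W.shape}")
        if len(self.fi) != n:
            raise ValueError("need one FICurve per population")
        exc = self.excitatory
        if exc is None:
            exc = tuple(lbl == "E" for lbl in self.populations)
        object.__setattr__(self, "excitatory", tuple(exc))
        for j, is_exc in enumerate(self.excitatory):
            col = W[:, j]
            if is_exc and np.any(col < 0):
                raise ValueError(
                    f"column {self.populations[j]} is excitatory but has negative entries"
                )
            if not is_exc and np.any(col > 0):
                raise ValueError(
                    f"column {self.populations[j]} is inhibitory but has positive entries"
                )
        if self.i_bkg is not None:
            b = np.asarray(self.i_bkg, dtype=float)
            if b.shape != (n,):
                raise ValueError("i_bkg length must match populations")
            object.__setattr__(self, "i_bkg", b)
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")

    # -- vectorized per-population parameter views ---------------------------
    @property
    def n_pop(self) -> int:
        return len(self.populations)

    @property
    def g_l(self) -> np.ndarray:
        return np.array([p.g_l for p in self.fi])

    @property
    def tau_m(self) -> np.ndarray:
        return np.array([p.tau_m for p in self.fi])

    @property
    def v_l(self) -> np.ndarray:
        return np.array([p.v_l for p in self.fi])

    @property
    def background(self) -> np.ndarray:
        if self.i_bkg is None:
            return np.zeros(self.n_pop)
        return self.i_bkg

    def rates_of(self, V: np.ndarray) -> np.ndarray:
        return np.array([p.rate(V[i]) for i, p in enumerate(self.fi)])

    def gains_of(self, V: np.ndarray) -> np.ndarray:
        """f'(V_i) per population (Hz/mV)."""
        return np.array([p.derivative(V[i]) for i, p in enumerate(self.fi)])

    def index(self, label: str) -> int:
        return self.populations.index(label)

    def with_background(self, i_bkg: np.ndarray) -> "Circuit":
        return dataclasses.replace(self, i_bkg=np.asarray(i_bkg, dtype=float))

    def with_connectivity(self, W: np.ndarray) -> "Circuit":
        return dataclasses.replace(self, W=np.asarray(W, dtype=float))


def net_input(c: Circuit, rates: np.ndarray, i_ext: np.ndarray | float = 0.0) -> np.ndarray:
    """Effective membrane potentials V (mV) given rates (Hz) and external pA."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (c.n_pop,):
        raise ValueError("rates length must match populations")
    i_ext = np.broadcast_to(np.asarray(i_ext, dtype=float), (c.n_pop,))
    return c.v_l + (c.W @ rates + i_ext + c.background) / c.g_l


def _rhs(c: Circuit, rates: np.ndarray, i_ext: np.ndarray) -> np.ndarray:
    V = c.v_l + (c.W @ rates + i_ext + c.background) / c.g_l
    return (-rates + c.rates_of(V)) / c.tau_r


def steady_state(
    c: Circuit,
    i_ext: np.ndarray | float = 0.0,
    r0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Solve the fixed-point system r = f(V(r)).

    Damped Newton iteration on g(r) = r - f(V(r)), initialized at ``r0``
    (zeros by default); if Newton stalls, the state is relaxed by a 2 s
    simulation and Newton is retried once.  Raises
    :class:`ConvergenceError` when no fixed point is found.
    """
    i_ext = np.broadcast_to(np.asarray(i_ext, dtype=float), (c.n_pop,)).copy()
    r = np.zeros(c.n_pop) if r0 is None else np.asarray(r0, dtype=float).copy()

    def residual(r):
        V = net_input(c, r, i_ext)
        return r - c.rates_of(V), V

    for attempt in range(2):
        g, V = residual(r)
        for _ in range(max_iter):
            if np.linalg.norm(g, np.inf) < tol:
                return r
            J = np.eye(c.n_pop) - (c.gains_of(V) / c.g_l)[:, None] * c.W
            try:
                step = np.linalg.solve(J, g)
            except np.linalg.LinAlgError:
                break
            # backtracking line search on the residual norm
            lam, ok = 1.0, False
            norm0 = np.linalg.norm(g)
            for _ in range(30):
                r_new = r - lam * step
                g_new, V_new = residual(r_new)
                if np.all(np.isfinite(g_new)) and np.linalg.norm(g_new) < norm0:
                    r, g, V, ok = r_new, g_new, V_new, True
                    break
                lam *= 0.5
            if not ok:
                break
        else:
            continue
        if np.linalg.norm(g, np.inf) < tol:
            return r
        if attempt == 0:
            # relax towards an attractor, then polish with Newton
            sched = InputSchedule.constant(i_ext)
            traj = simulate(c, sched, r0=np.clip(r, 0, None), T=2.0, dt=1e-4, record_every=1000)
            r = traj.rates[-1]
    g, _ = residual(r)
    if np.linalg.norm(g, np.inf) < tol:
        return r
    raise ConvergenceError(
        f"no fixed point found (residual {np.linalg.norm(g, np.inf):.3g} Hz)"
    )


def calibrate_background(
    c: Circuit,
    target_rates: Sequence[float],
    i_ext: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Background currents (pA) that place the fixed point at ``target_rates``.

    The targets pin every membrane potential through the f-I inverse, so
    the calibration is a direct (non-iterative) formula:

        I_bkg,i = g_l,i (f^-1(r_t,i) - V_l) - sum_j W_ij r_t,j - I_i
    """
    targets = np.asarray(target_rates, dtype=float)
    if targets.shape != (c.n_pop,):
        raise ValueError("target_rates length must match populations")
    if np.any(targets <= 0):
        raise ValueError("target rates must be positive")
    i_ext = np.broadcast_to(np.asarray(i_ext, dtype=float), (c.n_pop,))
    V_t = np.array([p.inverse(targets[i]) for i, p in enumerate(c.fi)])
    return c.g_l * (V_t - c.v_l) - c.W @ targets - i_ext


def calibrated(c: Circuit, target_rates: Sequence[float], i_ext=0.0) -> Circuit:
    """Copy of ``c`` with background currents calibrated to ``target_rates``."""
    return c.with_background(calibrate_background(c, target_rates, i_ext))


@dataclass(frozen=True)
class InputSchedule:
    """Piecewise-constant external currents: (t_start, t_end, pA vector)."""

    segments: tuple[tuple[float, float, np.ndarray], ...]

    def __post_init__(self):
        segs = []
        for t0, t1, vec in self.segments:
            if t0 < 0 or t1 <= t0:
                raise ValueError("segments need 0 <= t_start < t_end")
            segs.append((float(t0), float(t1), np.asarray(vec, dtype=float)))
        segs.sort(key=lambda s: s[0])
        for (_, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ValueError("segments overlap")
        object.__setattr__(self, "segments", tuple(segs))

    @classmethod
    def constant(cls, vec) -> "InputSchedule":
        return cls(((0.0, np.inf, np.asarray(vec, dtype=float)),))

    @classmethod
    def step(cls, vec, t_on: float = 0.0, t_off: float = np.inf) -> "InputSchedule":
        """Zero current before ``t_on``, ``vec`` from ``t_on`` to ``t_off``."""
        return cls(((t_on, t_off, np.asarray(vec, dtype=float)),))

    @classmethod
    def zero(cls, n: int) -> "InputSchedule":
        return cls.constant(np.zeros(n))

    def current(self, t: float, n: int) -> np.ndarray:
        for t0, t1, vec in self.segments:
            if t0 <= t < t1:
                return np.broadcast_to(vec, (n,))
        return np.zeros(n)


@dataclass(frozen=True)
class Trajectory:
    """Integrated rate traces: time grid (s), rates (Hz) and inputs V (mV)."""

    t: np.ndarray
    rates: np.ndarray  # (n_times, n_pop)
    V: np.ndarray
    populations: tuple[str, ...] = DEFAULT_POPULATIONS

    def to_frame(self):
        import pandas as pd

        cols = {"time_s": self.t}
        for k, lbl in enumerate(self.populations):
            cols[f"r_{lbl}"] = self.rates[:, k]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    c: Circuit,
    schedule: InputSchedule,
    r0: np.ndarray,
    T: float,
    dt: float = 1e-4,
    record_every: int = 1,
    method: str = "euler",
) -> Trajectory:
    """Integrate the rate dynamics from ``r0`` for ``T`` seconds.

    Explicit Euler by default (``method="rk4"`` for the classical
    Runge-Kutta scheme); ``dt`` must resolve the rate time constant
    (dt <= tau_r/4).  Raises :class:`SimulationError` with the blow-up
    time if the state becomes non-finite.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if dt > c.tau_r / 4:
        raise ValueError(f"dt={dt} too coarse for tau_r={c.tau_r} (need dt <= tau_r/4)")
    n_steps = int(round(T / dt))
    r = np.asarray(r0, dtype=float).copy()
    n = c.n_pop
    times, rates_out, V_out = [], [], []

    def record(t, r):
        times.append(t)
        rates_out.append(r.copy())
        V_out.append(net_input(c, r, schedule.current(t, n)))

    record(0.0, r)
    for k in range(n_steps):
        t = k * dt
        if method == "euler":
            r = r + dt * _rhs(c, r, schedule.current(t, n))
        elif method == "rk4":
            k1 = _rhs(c, r, schedule.current(t, n))
            k2 = _rhs(c, r + dt / 2 * k1, schedule.current(t + dt / 2, n))
            k3 = _rhs(c, r + dt / 2 * k2, schedule.current(t + dt / 2, n))
            k4 = _rhs(c, r + dt * k3, schedule.current(t + dt, n))
            r = r + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            raise ValueError(f"unknown integrator {method!r}")
        if not np.all(np.isfinite(r)):
            raise SimulationError(f"rates diverged at t={t + dt:.6f} s", t_blowup=t + dt)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            record((k + 1) * dt, r)
    return Trajectory(
        t=np.array(times), rates=np.array(rates_out), V=np.array(V_out),
        populations=c.populations,
    )


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray
    is_stable: bool


def jacobian_stability(
    c: Circuit,
    r_star: np.ndarray,
    i_ext: np.ndarray | float = 0.0,
    residual_tol: float = 1e-6,
) -> StabilityReport:
    """Linear stability of a fixed point of the rate dynamics.

    The Jacobian of the dynamics at r* is
    J_ij = (-delta_ij + f'(V_i) W_ij / g_l,i) / tau_r; the point is stable
    iff every eigenvalue has negative real part.
    """
    r_star = np.asarray(r_star, dtype=float)
    V = net_input(c, r_star, i_ext)
    res = np.linalg.norm(r_star - c.rates_of(V), np.inf)
    if res > residual_tol:
        raise ValueError(f"r_star is not a fixed point (residual {res:.3g} Hz)")
    J = (-np.eye(c.n_pop) + (c.gains_of(V) / c.g_l)[:, None] * c.W) / c.tau_r
    eig = np.linalg.eigvals(J)
    return StabilityReport(eigenvalues=eig, is_stable=bool(np.all(eig.real < 0)))
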