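"""Random unit-network expansion of the population model.

Each population is replaced by N identical rate units; a directed
connection from a unit of population j to a unit of population i exists
with probability p_ij, independently per ordered pair.  Nonzero
connections carry weight W_ij / m_ij where m_ij = p_ij N_j is the
expected in-degree, so the average total input from population j onto a
unit of population i equals the population weight W_ij.  Background and
top-down currents are broadcast identically to all units of a
population; all heterogeneity in unit responses therefore comes from the
quenched random wiring alone.

Self-connections are excluded; for diagonal blocks the expected
in-degree is p_ii (N_i - 1), which keeps the all-to-all (p = 1) network
exactly equal to the population model, unit by unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .circuit import Circuit, InputSchedule, SimulationError, Trajectory
from .fi import fi_rate

__all__ = [
    "UnitNetwork",
    "sample_unit_network",
    "simulate_units",
    "rate_modulation",
    "ModulationResult",
    "run_modulation_experiment",
]


@dataclass(frozen=True)
class UnitNetwork:
    """Unit-level expansion of a Circuit with sampled, rescaled weights."""

    circuit: Circuit
    counts: tuple[int, ...]
    membership: np.ndarray  # population index per unit
    weights: np.ndarray  # (n_units, n_units) pA·s, signed
    seed: int

    @property
    def n_units(self) -> int:
        return len(self.membership)

    def pop_slice(self, label: str) -> np.ndarray:
        """Boolean mask of the units belonging to population ``label``."""
        return self.membership == self.circuit.index(label)

    def _unit_params(self):
        c = self.circuit
        m = self.membership
        v_th = np.array([p.v_th for p in c.fi])[m]
        v_r = np.array([p.v_r for p in c.fi])[m]
        v = np.array([p.v for p in c.fi])[m]
        tau_m = c.tau_m[m]
        g_l = c.g_l[m]
        v_l = c.v_l[m]
        return v_th, v_r, v, tau_m, g_l, v_l

    def block_input_means(self) -> np.ndarray:
        """Mean over target units of the total weight received from each
        source population; equals W_ij in expectation."""
        n = self.circuit.n_pop
        out = np.zeros((n, n))
        for i in range(n):
            rows = self.membership == i
            for j in range(n):
                cols = self.membership == j
                out[i, j] = self.weights[np.ix_(rows, cols)].sum(axis=1).mean()
        return out


def sample_unit_network(
    c: Circuit,
    p: np.ndarray,
    counts=None,
    seed: int = 0,
    normalization: str = "expected",
) -> UnitNetwork:
    """Draw a Bernoulli unit network with population-block probabilities.

    ``normalization="expected"`` rescales weights by the expected
    in-degree m_ij = p_ij N_j (p_ii (N_i - 1) on diagonal blocks);
    ``"realized"`` divides each unit's incoming block weights by its
    realized in-degree instead (units with no incoming connection in a
    block receive none).
    """
    p = np.asarray(p, dtype=float)
    n = c.n_pop
    if p.shape != (n, n):
        raise ValueError(f"probability matrix must be {n}x{n}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(
            "connection probabilities must lie in [0, 1]; published tables "
            "carrying an inhibitory sign must be magnitude-normalized first"
        )
    if normalization not in ("expected", "realized"):
        raise ValueError("normalization must be 'expected' or 'realized'")
    counts = tuple(int(k) for k in (counts if counts is not None else (800, 100, 50, 50)))
    if len(counts) != n or min(counts) < 1:
        raise ValueError("need a positive unit count per population")

    rng = np.random.default_rng(seed)
    membership = np.repeat(np.arange(n), counts)
    n_units = int(np.sum(counts))
    starts = np.concatenate(([0], np.cumsum(counts)))
    weights = np.zeros((n_units, n_units))
    for i in range(n):
        ri = slice(starts[i], starts[i + 1])
        for j in range(n):
            rj = slice(starts[j], starts[j + 1])
            if p[i, j] == 0 or c.W[i, j] == 0:
                # draw anyway to keep the stream layout stable across W edits
                if p[i, j] > 0:
                    rng.random((counts[i], counts[j]))
                continue
            adj = rng.random((counts[i], counts[j])) < p[i, j]
            if i == j:
                np.fill_diagonal(adj, False)
            if normalization == "expected":
                m_ij = p[i, j] * (counts[j] - 1 if i == j else counts[j])
                weights[ri, rj] = adj * (c.W[i, j] / m_ij)
            else:
                indeg = adj.sum(axis=1, keepdims=True)
                with np.errstate(divide="ignore", invalid="ignore"):
                    w = np.where(indeg > 0, c.W[i, j] / indeg, 0.0)
                weights[ri, rj] = adj * w
    return UnitNetwork(circuit=c, counts=counts, membership=membership, weights=weights, seed=seed)


def simulate_units(
    net: UnitNetwork,
    schedule: InputSchedule,
    r0: np.ndarray | None = None,
    T: float = 0.5,
    dt: float = 1e-4,
    record_every: int = 1,
) -> Trajectory:
    """Explicit-Euler integration of the unit-level rate dynamics.

    External and background currents are population-level vectors,
    broadcast to every unit of the population.  ``r0`` is per unit
    (defaults to the population background-free rest state of zeros).
    """
    c = net.circuit
    if dt > c.tau_r / 4:
        raise ValueError(f"dt={dt} too coarse for tau_r={c.tau_r}")
    v_th, v_r, v, tau_m, g_l, v_l = net._unit_params()
    m = net.membership
    i_bkg = c.background[m]
    r = np.zeros(net.n_units) if r0 is None else np.asarray(r0, dtype=float).copy()
    n_steps = int(round(T / dt))
    times, rates_out = [0.0], [r.copy()]
    for k in range(n_steps):
        t = k * dt
        i_ext = schedule.current(t, c.n_pop)[m]
        V = v_l + (net.weights @ r + i_ext + i_bkg) / g_l
        r = r + dt / c.tau_r * (-r + fi_rate(V, v_th, v_r, v, tau_m))
        if not np.all(np.isfinite(r)):
            raise SimulationError(f"unit rates diverged at t={t + dt:.6f} s", t_blowup=t + dt)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            times.append((k + 1) * dt)
            rates_out.append(r.copy())
    rates = np.array(rates_out)
    # V traces are cheap to reconstruct but bulky; store rates only
    return Trajectory(
        t=np.array(times), rates=rates, V=np.full_like(rates, np.nan),
        populations=tuple(f"u{i}" for i in range(net.n_units)),
    )


@dataclass(frozen=True)
class ModulationResult:
    """Per-unit rate modulations (Hz) with population summaries."""

    delta: np.ndarray  # per unit: modulated - baseline
    baseline: np.ndarray  # per-unit baseline rate
    pop_delta: np.ndarray  # mean modulation per population
    pop_sem: np.ndarray
    membership: np.ndarray
    populations: tuple[str, ...]
    stationary: bool


def rate_modulation(
    net: UnitNetwork,
    traj: Trajectory,
    baseline_window: tuple[float, float],
    modulated_window: tuple[float, float],
    drift_tol: float = 1e-3,
) -> ModulationResult:
    """Rate during modulation minus baseline rate, per unit.

    Each window is averaged over time; if the mean rate drifts by more
    than ``drift_tol`` Hz between the two halves of either window a
    non-stationarity warning is emitted (result still returned).
    """
    def window_mean(t0, t1):
        sel = (traj.t >= t0) & (traj.t <= t1)
        if sel.sum() < 4:
            raise ValueError("window contains too few samples")
        block = traj.rates[sel]
        half = len(block) // 2
        drift = np.abs(block[:half].mean(axis=0) - block[half:].mean(axis=0)).max()
        return block.mean(axis=0), drift

    base, drift_b = window_mean(*baseline_window)
    mod, drift_m = window_mean(*modulated_window)
    stationary = max(drift_b, drift_m) <= drift_tol
    if not stationary:
        warnings.warn(
            f"rates drift by {max(drift_b, drift_m):.2e} Hz within an averaging window",
            stacklevel=2,
        )
    delta = mod - base
    n = net.circuit.n_pop
    pop_delta = np.array([delta[net.membership == i].mean() for i in range(n)])
    pop_sem = np.array(
        [
            delta[net.membership == i].std(ddof=1) / np.sqrt((net.membership == i).sum())
            for i in range(n)
        ]
    )
    return ModulationResult(
        delta=delta,
        baseline=base,
        pop_delta=pop_delta,
        pop_sem=pop_sem,
        membership=net.membership,
        populations=net.circuit.populations,
        stationary=stationary,
    )


def run_modulation_experiment(
    c: Circuit,
    p: np.ndarray,
    counts=None,
    seed: int = 0,
    step_pA: np.ndarray | None = None,
    t_pre: float = 0.3,
    t_mod: float = 0.3,
    dt: float = 1e-4,
) -> ModulationResult:
    """Sample a network, relax it, apply a current step, measure modulations.

    ``step_pA`` defaults to the 10 pA top-down current onto VIP.  The
    baseline and modulated windows are the last 100 ms of each epoch.
    The initial condition seeds every unit at its population's target
    rate if the circuit is calibrated (its background is nonzero), so
    the pre-epoch only needs to absorb the quenched-connectivity
    transient.
    """
    if step_pA is None:
        step_pA = np.zeros(c.n_pop)
        step_pA[c.index("V")] = 10.0
    net = sample_unit_network(c, p, counts=counts, seed=seed)
    sched = InputSchedule.step(step_pA, t_on=t_pre)
    # start units at the population-model rest to shorten the transient
    from .circuit import steady_state

    r_pop = steady_state(c, 0.0, r0=np.ones(c.n_pop))
    r0 = r_pop[net.membership]
    traj = simulate_units(net, sched, r0=r0, T=t_pre + t_mod, dt=dt, record_every=10)
    return rate_modulation(
        net, traj,
        baseline_window=(t_pre - 0.1, t_pre),
        modulated_window=(t_pre + t_mod - 0.1, t_pre + t_mod),
    )
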