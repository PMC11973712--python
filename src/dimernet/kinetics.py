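"""Deterministic association/dissociation kinetics of dimerization networks.

Kinetics follow a minimal single-transition-state model: every association
shares one rate constant ``kon`` (default 5e5 M^-1 s^-1, typical of
coiled-coil dimerization) while dissociation rates ``koff_ij`` vary per
dimer, sampled log-uniform on 1e-4..1 s^-1.  All concentrations are
molecules per cell assuming a 3 pL cell volume, so one dimensionless
concentration unit corresponds to 1000 molecules.  The implied equilibrium
constant of each edge is ``K_ij = kon / koff_ij`` in molecules-per-cell
units, which makes the ODE steady state coincide with the equilibrium
solver's solution.

The mass-action ODEs are

    dM_i/dt = 2 koff_ii D_ii + sum_{j!=i} koff_ij D_ij
              - 2 kon M_i^2 - sum_{j!=i} kon M_i M_j
    dD_ij/dt = kon M_i M_j - koff_ij D_ij     (homodimer: kon M_i^2)

with terms present only for the network's edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import SolverError, solve_equilibrium_free
from .network import DimerizationNetwork

__all__ = [
    "AVOGADRO",
    "CELL_VOLUME_L",
    "KON_MOLAR",
    "KineticParameters",
    "Trajectory",
    "convert_units",
    "sample_kinetics",
    "kinetic_network",
    "ode_rhs",
    "simulate_relaxation",
    "simulate_oscillating_input",
    "OscillationResult",
]

AVOGADRO = 6.02214076e23
CELL_VOLUME_L = 3.0e-12  # 3 pL
#: Default association rate constant, M^-1 s^-1.
KON_MOLAR = 5.0e5
#: Default log10 range of dissociation rates, s^-1.
KOFF_LOG10_RANGE = (-4.0, 0.0)
#: Default log10 range of total monomer abundances, molecules per cell.
ABUNDANCE_LOG10_RANGE = (0.0, 6.0)


def convert_units(value, direction: str, volume: float = CELL_VOLUME_L):
    """Convert between molar concentration and molecules per cell.

    ``direction``: ``"molar_to_molecules"`` or ``"molecules_to_molar"``.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("concentrations must be non-negative")
    factor = AVOGADRO * volume
    if direction == "molar_to_molecules":
        out = value * factor
    elif direction == "molecules_to_molar":
        out = value / factor
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class KineticParameters:
    """Association rate (shared) and per-edge dissociation rates.

    Rates are in molecules-per-cell units: ``kon`` per molecule per second,
    ``koff`` per second, aligned with the network's edges.
    """

    kon: float
    koff: tuple[float, ...]

    def __post_init__(self):
        if not self.kon > 0:
            raise ValueError("kon must be positive")
        if any(k <= 0 for k in self.koff):
            raise ValueError("koff rates must be positive")

    @property
    def equilibrium_constants(self) -> np.ndarray:
        """Implied per-edge K in molecules-per-cell units."""
        return self.kon / np.asarray(self.koff)

    @classmethod
    def default_kon(cls) -> float:
        return KON_MOLAR / (AVOGADRO * CELL_VOLUME_L)


def sample_kinetics(
    n_edges: int,
    seed=None,
    kon_molar: float = KON_MOLAR,
    koff_log10_range: tuple[float, float] = KOFF_LOG10_RANGE,
) -> KineticParameters:
    """Draw per-edge dissociation rates log-uniformly."""
    rng = np.random.default_rng(seed)
    lo, hi = koff_log10_range
    koff = 10.0 ** rng.uniform(lo, hi, size=n_edges)
    kon = kon_molar / (AVOGADRO * CELL_VOLUME_L)
    return KineticParameters(kon=kon, koff=tuple(koff))


def kinetic_network(
    m: int,
    seed=None,
    n_hetero: int | None = None,
    abundance_log10_range: tuple[float, float] = ABUNDANCE_LOG10_RANGE,
) -> tuple[DimerizationNetwork, KineticParameters, np.ndarray]:
    """Random network in molecules-per-cell units with sampled kinetics.

    Returns the network (affinities are the implied ``kon / koff``), its
    kinetic parameters, and total abundances drawn log-uniform on
    1..1e6 molecules per cell.
    """
    from .network import random_network

    rng = np.random.default_rng(seed)
    net, _ = random_network(m, n_hetero=n_hetero, seed=rng)
    kin = sample_kinetics(net.n_dimers, seed=rng)
    net = net.with_affinities(kin.equilibrium_constants)
    lo, hi = abundance_log10_range
    totals = 10.0 ** rng.uniform(lo, hi, size=m)
    return net, kin, totals


@dataclass
class Trajectory:
    """Sampled kinetic trajectory; species order is monomers then dimers."""

    times: np.ndarray
    concentrations: np.ndarray  # (n_times, m + n_dimers)
    network: DimerizationNetwork
    equilibration_time: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def monomer(self, i: int) -> np.ndarray:
        return self.concentrations[:, i]

    def dimer(self, edge: tuple[int, int], network=None) -> np.ndarray:
        net = network or self.network
        return self.concentrations[:, net.m + net.edge_index()[tuple(sorted(edge))]]


def _edge_arrays(network: DimerizationNetwork):
    ei = np.array([e[0] for e in network.edges])
    ej = np.array([e[1] for e in network.edges])
    return ei, ej


def ode_rhs(
    t: float,
    state: np.ndarray,
    network: DimerizationNetwork,
    kinetics: KineticParameters,
) -> np.ndarray:
    """Mass-action time derivatives for [monomers..., dimers...]."""
    m = network.m
    mono = state[:m]
    dim = state[m:]
    kon = kinetics.kon
    koff = np.asarray(kinetics.koff)
    ei, ej = _edge_arrays(network)
    assoc = kon * mono[ei] * mono[ej]
    dd = assoc - koff * dim
    dm = np.zeros(m)
    for idx in range(dd.size):
        i, j = ei[idx], ej[idx]
        if i == j:
            dm[i] -= 2.0 * dd[idx]
        else:
            dm[i] -= dd[idx]
            dm[j] -= dd[idx]
    return np.concatenate([dm, dd])


def equilibrium_state_vector(
    network: DimerizationNetwork, totals: np.ndarray
) -> np.ndarray:
    """Exact equilibrium [monomers..., dimers...] for given totals."""
    kmat = network.affinity_matrix()
    free = solve_equilibrium_free(kmat, np.asarray(totals, dtype=float))
    ei, ej = _edge_arrays(network)
    dim = np.asarray(network.K) * free[ei] * free[ej]
    return np.concatenate([free, dim])


def _totals_of_state(network: DimerizationNetwork, state: np.ndarray) -> np.ndarray:
    m = network.m
    tot = state[:m].copy()
    for idx, (i, j) in enumerate(network.edges):
        if i == j:
            tot[i] += 2.0 * state[m + idx]
        else:
            tot[i] += state[m + idx]
            tot[j] += state[m + idx]
    return tot


def _integrate_segment(network, kinetics, y0, t0, t1, rtol=1e-8, atol=1e-6):
    sol = solve_ivp(
        ode_rhs,
        (t0, t1),
        y0,
        args=(network, kinetics),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}", np.nan)
    return sol.y[:, -1]


def simulate_relaxation(
    network: DimerizationNetwork,
    kinetics: KineticParameters,
    totals: np.ndarray,
    input_index: int = 0,
    initial_input_total: float = 1.0,
    perturbed_input_total: float = 1e6,
    dt: float = 10.0,
    t_max: float = 1e7,
    equilibration_tol: float = 1.0,
) -> Trajectory:
    """Relax from a low-input equilibrium after a step change of the input.

    The system starts at the exact equilibrium with the input monomer at
    ``initial_input_total`` molecules/cell; at t=0 the input's free pool is
    adjusted so its total becomes ``perturbed_input_total``.  Sampled every
    ``dt`` seconds until every species is within ``equilibration_tol``
    molecules of the new exact equilibrium (and stays there), or ``t_max``.
    Per-species equilibration times are the first sample time after which
    the species remains within tolerance.
    """
    totals = np.asarray(totals, dtype=float).copy()
    totals[input_index] = initial_input_total
    y0 = equilibrium_state_vector(network, totals)
    y0[input_index] += perturbed_input_total - initial_input_total
    totals[input_index] = perturbed_input_total
    y_eq = equilibrium_state_vector(network, totals)

    times = [np.array([0.0])]
    states = [y0[None, :]]
    y = y0
    t = 0.0
    chunk = 500  # samples per integrator call before re-checking convergence
    while t < t_max:
        t_end = min(t + chunk * dt, t_max)
        t_eval = np.arange(t + dt, t_end + dt / 2, dt)
        sol = solve_ivp(
            ode_rhs,
            (t, t_end),
            y,
            args=(network, kinetics),
            method="LSODA",
            t_eval=t_eval,
            rtol=1e-8,
            atol=1e-6,
        )
        if not sol.success:
            raise SolverError(f"ODE integration failed at t={t}: {sol.message}", np.nan)
        times.append(sol.t)
        states.append(sol.y.T)
        y = sol.y[:, -1]
        t = t_end
        if np.all(np.abs(y - y_eq) <= equilibration_tol):
            break
    conc = np.concatenate(states, axis=0)
    tarr = np.concatenate(times)
    within = np.abs(conc - y_eq) <= equilibration_tol
    eq_time = np.full(conc.shape[1], np.nan)
    for s in range(conc.shape[1]):
        ok = within[:, s]
        # first index from which the species stays within tolerance
        idx = np.nonzero(~ok)[0]
        first = 0 if idx.size == 0 else idx[-1] + 1
        if first < len(tarr):
            eq_time[s] = tarr[first]
    return Trajectory(
        times=tarr,
        concentrations=conc,
        network=network,
        equilibration_time=eq_time,
        metadata={"y_eq": y_eq, "totals": totals},
    )


@dataclass
class OscillationResult:
    """Quasi-equilibrium bookkeeping for a sinusoidally driven input."""

    n_dimers_changing: int
    n_dimers_quasi_equilibrium: int
    n_failures: int
    max_log_deviation: np.ndarray  # per dimer, over time
    times: np.ndarray
    log_range_equilibrium: np.ndarray  # per dimer

    @property
    def fraction_quasi_equilibrium(self) -> float:
        if self.n_dimers_changing == 0:
            return np.nan
        return self.n_dimers_quasi_equilibrium / self.n_dimers_changing


def simulate_oscillating_input(
    network: DimerizationNetwork,
    kinetics: KineticParameters,
    totals: np.ndarray,
    input_index: int = 0,
    period: float = 97200.0,
    log10_lo: float = 0.0,
    log10_hi: float = 6.0,
    n_periods: float = 2.0,
    sample_dt: float | None = None,
    tolerance_log: float = 0.5,
    changing_threshold_log: float = 0.5,
) -> OscillationResult:
    """Drive one monomer's total sinusoidally (in log space) and track lag.

    The input total follows ``10**(mid + amp * sin(2 pi t / period))``
    between ``10**log10_lo`` and ``10**log10_hi`` molecules/cell, applied
    by adjusting the free pool at each sampling step (removal is limited to
    the available free monomers).  A dimer is "changing" when its
    instantaneous-equilibrium concentration spans more than
    ``changing_threshold_log`` log10 units over the run, and at
    quasi-equilibrium when its dynamic concentration stays within
    ``tolerance_log`` log10 units of the instantaneous equilibrium at every
    sample.  Concentrations are floored at 1 molecule for the comparison.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if sample_dt is None:
        sample_dt = max(period / 200.0, 10.0)
    totals = np.asarray(totals, dtype=float).copy()
    mid = 0.5 * (log10_lo + log10_hi)
    amp = 0.5 * (log10_hi - log10_lo)

    def input_total(t):
        return 10.0 ** (mid + amp * np.sin(2.0 * np.pi * t / period))

    totals[input_index] = input_total(0.0)
    y = equilibrium_state_vector(network, totals)
    n_steps = int(np.ceil(n_periods * period / sample_dt))
    n_dim = network.n_dimers
    m = network.m
    dev = np.zeros(n_dim)
    eq_log = np.empty((n_steps + 1, n_dim))
    dyn_log = np.empty((n_steps + 1, n_dim))
    times = np.empty(n_steps + 1)
    n_fail = 0
    floor = 1.0

    def record(k, t, state):
        times[k] = t
        cur_tot = _totals_of_state(network, state)
        eq = equilibrium_state_vector(network, cur_tot)
        eq_log[k] = np.log10(np.maximum(eq[m:], floor))
        dyn_log[k] = np.log10(np.maximum(state[m:], floor))

    record(0, 0.0, y)
    t = 0.0
    for k in range(1, n_steps + 1):
        # set the input's free pool so its total matches the prescribed value
        cur_tot = _totals_of_state(network, y)
        delta = input_total(t) - cur_tot[input_index]
        y[input_index] = max(y[input_index] + delta, 0.0)
        try:
            y = _integrate_segment(network, kinetics, y, t, t + sample_dt)
        except SolverError:
            n_fail += 1
            y = np.maximum(y, 0.0)
        t += sample_dt
        record(k, t, y)
    dev = np.max(np.abs(dyn_log - eq_log), axis=0)
    eq_range = np.ptp(eq_log, axis=0)
    changing = eq_range > changing_threshold_log
    quasi = changing & (dev <= tolerance_log)
    return OscillationResult(
        n_dimers_changing=int(changing.sum()),
        n_dimers_quasi_equilibrium=int(quasi.sum()),
        n_failures=n_fail,
        max_log_deviation=dev,
        times=times,
        log_range_equilibrium=eq_range,
    )
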