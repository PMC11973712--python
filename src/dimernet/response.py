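"""Input-output responses of dimerization networks and their discretization.

A network's input-output function is the equilibrium concentration of each
dimer over a titration of the input monomer(s), log-spaced over the
physiological window 1e-3..1e3 (dimensionless; 1e-3 corresponds to one
molecule per cell).  Concentrations below 1e-3 are floored to 1e-3.
Responses with dynamic range <= 10-fold are discarded as non-responsive;
the survivors are discretized into decade-bin integer codes, which define
the notion of a "unique function" used for expressivity counting and for
building target-function libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibrium import SolverError, solve_equilibrium_free
from .network import ConcentrationProfile, DimerizationNetwork

__all__ = [
    "TitrationGrid",
    "ResponseSurface",
    "DiscretizedFunction",
    "TargetLibrary",
    "FLOOR",
    "titrate",
    "response_matrix",
    "floor_response",
    "dynamic_range_filter",
    "discretize",
    "count_unique_functions",
    "count_local_extrema",
    "build_target_library",
    "two_output_census",
]

#: Concentration floor: one molecule per cell in dimensionless units.
FLOOR = 1e-3

#: Decade bin edges shared by the input and output axes (log10 scale).
BIN_EDGES_LOG10 = np.arange(-3.0, 4.0)  # -3, -2, ..., 3
N_BINS = 6


@dataclass(frozen=True)
class TitrationGrid:
    """Log-spaced input titration grid.

    One-input functions use 30 points; two-input functions 12 points per
    axis, both spanning 1e-3..1e3.
    """

    n_inputs: int = 1
    points_per_axis: int = 30
    log10_lo: float = -3.0
    log10_hi: float = 3.0

    def __post_init__(self):
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.points_per_axis < 2:
            raise ValueError("need at least 2 points per axis")
        if self.log10_lo >= self.log10_hi:
            raise ValueError("log10_lo must be < log10_hi")

    @classmethod
    def default(cls, n_inputs: int) -> "TitrationGrid":
        return cls(n_inputs=n_inputs, points_per_axis=30 if n_inputs == 1 else 12)

    @property
    def axis_values(self) -> np.ndarray:
        return np.logspace(self.log10_lo, self.log10_hi, self.points_per_axis)

    @property
    def points(self) -> np.ndarray:
        """(n_points, n_inputs) array of input totals, meshgrid flattened."""
        axes = [self.axis_values] * self.n_inputs
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in mesh], axis=-1)

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.points_per_axis,) * self.n_inputs

    def input_bin_indices(self) -> np.ndarray:
        """Decade-bin index of each titration point along one axis.

        Bins are half-open ``[10^k, 10^(k+1))`` with the top edge closed.
        On the default grids no interior point falls exactly on an edge.
        """
        exps = np.log10(self.axis_values)
        idx = np.floor(exps - self.log10_lo).astype(int)
        return np.clip(idx, 0, N_BINS - 1)


def floor_response(values: np.ndarray) -> np.ndarray:
    """Clamp concentrations below one molecule per cell to the floor."""
    return np.maximum(np.asarray(values, dtype=float), FLOOR)


@dataclass(frozen=True)
class ResponseSurface:
    """Floored concentration of one dimer over a titration grid."""

    dimer: tuple[int, int]
    values: np.ndarray  # floored, shape grid.shape
    grid: TitrationGrid

    @property
    def dynamic_range(self) -> float:
        return float(self.values.max() / self.values.min())

    @property
    def log_values(self) -> np.ndarray:
        return np.log10(self.values)


@dataclass(frozen=True)
class DiscretizedFunction:
    """Decade-binned integer code of a response; equality defines function identity."""

    code: tuple  # flat tuple of ints in {0..5}; length 6 (1-D) or 36 (2-D)
    n_inputs: int = 1

    def __post_init__(self):
        if any(not (0 <= c < N_BINS) for c in self.code):
            raise ValueError("code entries must lie in {0..5}")
        if len(self.code) != N_BINS**self.n_inputs:
            raise ValueError("code length does not match the input dimension")

    def as_array(self) -> np.ndarray:
        a = np.array(self.code, dtype=int)
        return a.reshape((N_BINS,) * self.n_inputs)


def response_matrix(
    kmat: np.ndarray,
    kvec: np.ndarray,
    edges_i: np.ndarray,
    edges_j: np.ndarray,
    totals: np.ndarray,
    input_indices,
    points: np.ndarray,
) -> np.ndarray:
    """Floored dimer concentrations, shape (n_points, n_dimers).

    Low-level titration kernel shared by :func:`titrate` and the
    optimizers; consecutive points warm-start the Newton solve.
    """
    inputs = list(input_indices)
    out = np.empty((points.shape[0], kvec.size))
    x_prev = None
    for p, point in enumerate(points):
        t = totals.copy()
        t[inputs] = point
        try:
            x0 = x_prev if x_prev is not None and np.all(t > 0) else None
            free = solve_equilibrium_free(kmat, t, x0=x0)
        except SolverError as err:
            raise SolverError(
                f"equilibrium failed at titration point {p} (inputs {point}): {err}",
                err.residual_norm,
            ) from err
        x_prev = np.log(free) if np.all(free > 0) else None
        out[p] = kvec * free[edges_i] * free[edges_j]
    return floor_response(out)


def titrate(
    network: DimerizationNetwork,
    profile: ConcentrationProfile,
    grid: TitrationGrid | None = None,
) -> list[ResponseSurface]:
    """Equilibrium response of every dimer over the input titration.

    Input totals run over the grid; accessory totals stay at the profile's
    values.  Returns one floored surface per dimer.
    """
    if not profile.input_indices:
        raise ValueError("profile designates no input monomers")
    if grid is None:
        grid = TitrationGrid.default(len(profile.input_indices))
    if grid.n_inputs != len(profile.input_indices):
        raise ValueError("grid dimension does not match the number of inputs")
    if profile.m != network.m:
        raise ValueError("profile size does not match network")
    kmat = network.affinity_matrix()
    edges_i = np.array([e[0] for e in network.edges])
    edges_j = np.array([e[1] for e in network.edges])
    out = response_matrix(
        kmat,
        np.asarray(network.K),
        edges_i,
        edges_j,
        profile.totals_array(),
        profile.input_indices,
        grid.points,
    )
    return [
        ResponseSurface(dimer=e, values=out[:, d].reshape(grid.shape), grid=grid)
        for d, e in enumerate(network.edges)
    ]


def dynamic_range_filter(responses, fold: float = 10.0) -> list[ResponseSurface]:
    """Keep responses whose floored max/min ratio strictly exceeds ``fold``."""
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    return [r for r in responses if r.dynamic_range > fold]


def discretize(response: ResponseSurface) -> DiscretizedFunction:
    """Decade-bin code of a response.

    Within each input decade bin the floored response is averaged in log
    space; the mean is assigned to an output decade bin (half-open decade
    intervals, top edge closed).  Two-input surfaces are binned per 6x6
    cell over the 2x2 grid points each cell contains.
    """
    grid = response.grid
    logv = response.log_values
    bin_idx = grid.input_bin_indices()
    if grid.n_inputs == 1:
        means = np.array([logv[bin_idx == b].mean() for b in range(N_BINS)])
    elif grid.n_inputs == 2:
        means = np.empty((N_BINS, N_BINS))
        for b1 in range(N_BINS):
            for b2 in range(N_BINS):
                means[b1, b2] = logv[np.ix_(bin_idx == b1, bin_idx == b2)].mean()
        means = means.ravel()
    else:
        raise NotImplementedError("discretization supports 1 or 2 inputs")
    code = np.clip(np.floor(means - grid.log10_lo).astype(int), 0, N_BINS - 1)
    return DiscretizedFunction(code=tuple(int(c) for c in code), n_inputs=grid.n_inputs)


def count_unique_functions(codes) -> int:
    """Number of distinct discretized functions."""
    return len(set(codes))


def count_local_extrema(response: ResponseSurface) -> int:
    """Strict local extrema of a one-input response.

    Counts sign changes of successive differences of the floored log
    response after merging equal-value plateaus.
    """
    if response.grid.n_inputs != 1:
        raise ValueError("extrema counting applies to one-input responses")
    v = response.log_values
    merged = [v[0]]
    for val in v[1:]:
        if val != merged[-1]:
            merged.append(val)
    diffs = np.sign(np.diff(merged))
    return int(np.sum(diffs[1:] != diffs[:-1])) if len(diffs) > 1 else 0


@dataclass(frozen=True)
class TargetLibrary:
    """Log-scaled target functions, one per unique discretized function.

    Each target is the pointwise log10-space mean of every screened
    response sharing that code; by construction it re-discretizes to the
    code it represents.
    """

    m: int
    grid: TitrationGrid
    codes: tuple[DiscretizedFunction, ...]
    targets: tuple = field(default_factory=tuple)  # log10 arrays aligned with codes

    @property
    def size(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(zip(self.codes, self.targets))

    def subset(self, indices) -> "TargetLibrary":
        return TargetLibrary(
            m=self.m,
            grid=self.grid,
            codes=tuple(self.codes[i] for i in indices),
            targets=tuple(self.targets[i] for i in indices),
        )


def build_target_library(responses, m: int, grid: TitrationGrid | None = None) -> TargetLibrary:
    """Group responses by code and log-average each group into a target."""
    responses = list(responses)
    if grid is None and responses:
        grid = responses[0].grid
    groups: dict[DiscretizedFunction, list[np.ndarray]] = {}
    for r in responses:
        groups.setdefault(discretize(r), []).append(r.log_values)
    codes = tuple(groups)
    targets = tuple(np.mean(groups[c], axis=0) for c in codes)
    return TargetLibrary(m=m, grid=grid, codes=codes, targets=targets)


def two_output_census(per_network_codes: dict, seed=None) -> tuple[int, int]:
    """Unique co-occurring code pairs versus a scrambled control.

    ``per_network_codes`` maps a network id to the list of surviving codes of
    its dimers.  Observed: distinct unordered code pairs taken within a
    network.  Control: the same number of pairs drawn by sampling codes with
    replacement from the pooled set and pairing them at random.
    """
    observed_pairs = set()
    n_drawn = 0
    pooled = []
    for codes in per_network_codes.values():
        codes = list(codes)
        pooled.extend(codes)
        for a in range(len(codes)):
            for b in range(a + 1, len(codes)):
                key = tuple(sorted([codes[a].code, codes[b].code]))
                observed_pairs.add(key)
                n_drawn += 1
    rng = np.random.default_rng(seed)
    control_pairs = set()
    if pooled and n_drawn:
        ia = rng.integers(0, len(pooled), size=n_drawn)
        ib = rng.integers(0, len(pooled), size=n_drawn)
        for a, b in zip(ia, ib):
            control_pairs.add(tuple(sorted([pooled[a].code, pooled[b].code])))
    return len(observed_pairs), len(control_pairs)
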