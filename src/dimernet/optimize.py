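"""Fitting dimerization networks to target functions and logic gates.

Two optimization regimes:

* **Dual annealing** over both affinities K and accessory expression levels
  a, for a fully connected candidate topology of a given size.  Used to ask
  whether *any* network of ``m`` monomers can perform a target function or
  Boolean gate, and hence the minimal size that suffices.
* **Genetic algorithm** over accessory levels a only, with K fixed.  Used to
  measure *versatility*: the fraction of a target-function library a single
  random-affinity network can perform by re-tuning expression alone.

Losses compare log10-scaled responses G to log10 targets F: the sum of
squared residuals (annealing objective), the mean squared error (GA
objective), the Chebyshev loss ``L_inf = max |F - G|`` (one-input
success: ``<= 1`` means within 10-fold everywhere), and the Pearson
correlation (two-input success: ``r >= 0.85``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import dual_annealing

from .equilibrium import SolverError
from .network import ConcentrationProfile, DimerizationNetwork
from .response import FLOOR, TargetLibrary, TitrationGrid, response_matrix

__all__ = [
    "TargetFunction",
    "TruthTable",
    "OptimizationResult",
    "VersatilityReport",
    "GAParams",
    "compute_loss",
    "gate_input_grid",
    "logic_gate_success",
    "gate_margin",
    "fit_network_dual_annealing",
    "find_minimal_network_size",
    "optimize_accessories_ga",
    "versatility_single_dimer",
    "versatility_any_dimer",
    "versatility_two_input",
    "named_gate",
    "named_two_input_targets",
]

AFFINITY_BOUNDS = (-5.0, 7.0)  # log10 box for annealed affinities
ACCESSORY_BOUNDS = (-3.0, 3.0)  # log10 box for expression levels
#: Per-input titration levels used for Boolean gates; the lower two are
#: "off", the upper two "on".
GATE_LEVELS = np.array([1e-3, 1e-1, 1e1, 1e3])
BAD_LOSS = 1e10  # assigned when an equilibrium solve fails inside an objective


# --------------------------------------------------------------------------
# targets


@dataclass(frozen=True)
class TargetFunction:
    """A log10-scaled target response over a titration grid."""

    log_values: np.ndarray
    grid: TitrationGrid

    def __post_init__(self):
        v = np.asarray(self.log_values, dtype=float)
        object.__setattr__(self, "log_values", v)
        if v.size != np.prod(self.grid.shape):
            raise ValueError("target length does not match grid")


@dataclass(frozen=True)
class TruthTable:
    """Desired Boolean output for every combination of on/off inputs."""

    n_inputs: int
    outputs: dict  # tuple[bool, ...] -> bool
    name: str = ""

    def __post_init__(self):
        patterns = set(product([False, True], repeat=self.n_inputs))
        if set(self.outputs) != patterns:
            raise ValueError(
                f"truth table must cover all {2 ** self.n_inputs} input patterns"
            )

    def __call__(self, pattern) -> bool:
        return bool(self.outputs[tuple(pattern)])


_GATES_2 = {
    "AND": lambda a, b: a and b,
    "OR": lambda a, b: a or b,
    "NAND": lambda a, b: not (a and b),
    "NOR": lambda a, b: not (a or b),
    "XOR": lambda a, b: a != b,
    "XNOR": lambda a, b: a == b,
    "NIMPLY": lambda a, b: a and not b,  # "A AND NOT B"
    "IMPLY": lambda a, b: (not a) or b,
}


def named_gate(name: str, n_inputs: int = 2) -> TruthTable:
    """Standard Boolean gates by name.

    Two-input gates: AND, OR, NAND, NOR, XOR, XNOR, NIMPLY, IMPLY.  For
    more inputs: ``AND``/``OR`` generalize; ``AT_LEAST_<k>`` is high when
    at least k inputs are on; ``ANY_2_OR_NONE`` (three inputs) is high when
    exactly two or zero inputs are on.
    """
    key = name.upper()
    patterns = list(product([False, True], repeat=n_inputs))
    if n_inputs == 2 and key in _GATES_2:
        fn = _GATES_2[key]
        return TruthTable(2, {p: fn(*p) for p in patterns}, name=key)
    if key == "AND":
        return TruthTable(n_inputs, {p: all(p) for p in patterns}, name=key)
    if key == "OR":
        return TruthTable(n_inputs, {p: any(p) for p in patterns}, name=key)
    if key.startswith("AT_LEAST_"):
        k = int(key.rsplit("_", 1)[1])
        return TruthTable(n_inputs, {p: sum(p) >= k for p in patterns}, name=key)
    if key == "ANY_2_OR_NONE":
        return TruthTable(
            n_inputs, {p: sum(p) in (0, 2) for p in patterns}, name=key
        )
    raise KeyError(f"unknown gate {name!r} for {n_inputs} inputs")


# --------------------------------------------------------------------------
# losses


def compute_loss(metric: str, F: np.ndarray, G: np.ndarray) -> float:
    """Loss between log10 target F and log10 response G.

    Metrics: ``sum_squares``, ``mse``, ``inf`` (Chebyshev), ``pearson``
    (higher is better; callers negate for minimization).
    """
    F = np.asarray(F, dtype=float).ravel()
    G = np.asarray(G, dtype=float).ravel()
    if F.shape != G.shape:
        raise ValueError("F and G must have the same length")
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(G))):
        raise ValueError("losses require finite (floored) log values")
    diff = F - G
    if metric == "sum_squares":
        return float(np.sum(diff**2))
    if metric == "mse":
        return float(np.mean(diff**2))
    if metric == "inf":
        return float(np.max(np.abs(diff)))
    if metric == "pearson":
        if np.ptp(F) == 0 or np.ptp(G) == 0:
            raise ValueError("pearson correlation undefined for constant series")
        return float(np.corrcoef(F, G)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


# --------------------------------------------------------------------------
# Boolean gates


def gate_input_grid(n_inputs: int) -> tuple[np.ndarray, np.ndarray]:
    """All gate evaluation points and their Boolean patterns.

    Four levels per input (1e-3, 1e-1 off; 1e1, 1e3 on) give ``4**n``
    points; returns (points, patterns) with patterns boolean (n, n_inputs).
    """
    pts = np.array(list(product(GATE_LEVELS, repeat=n_inputs)))
    return pts, pts >= 10.0


def logic_gate_success(responses: np.ndarray, truth_table: TruthTable) -> bool:
    """Strict separation criterion for a Boolean gate.

    ``responses`` holds the output-dimer concentration at every point of
    :func:`gate_input_grid`; success means the highest "off" response is
    strictly below the lowest "on" response.
    """
    return gate_margin(responses, truth_table) > 0.0


def gate_margin(responses: np.ndarray, truth_table: TruthTable) -> float:
    """log10(min on-response) - log10(max off-response); > 0 means success."""
    responses = np.asarray(responses, dtype=float).ravel()
    _, patterns = gate_input_grid(truth_table.n_inputs)
    if responses.size != patterns.shape[0]:
        raise ValueError(
            f"expected {patterns.shape[0]} responses for a "
            f"{truth_table.n_inputs}-input gate, got {responses.size}"
        )
    desired = np.array([truth_table(p) for p in patterns])
    if desired.all() or (~desired).all():
        raise ValueError("degenerate truth table: output constant")
    lo = np.log10(max(responses[~desired].max(), FLOOR))
    hi = np.log10(max(responses[desired].min(), FLOOR))
    return float(hi - lo)


# --------------------------------------------------------------------------
# dual annealing over K and a


@dataclass
class OptimizationResult:
    success: bool
    best_loss: float
    losses: dict = field(default_factory=dict)
    network: DimerizationNetwork | None = None
    profile: ConcentrationProfile | None = None
    output_dimer: tuple[int, int] | None = None
    seed: int | None = None
    n_evaluations: int = 0
    metadata: dict = field(default_factory=dict)


def _full_topology(m: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(m) for j in range(i, m)]


def fit_network_dual_annealing(
    target: TargetFunction | TruthTable,
    m: int,
    n_inputs: int | None = None,
    affinity_bounds: tuple[float, float] = AFFINITY_BOUNDS,
    accessory_bounds: tuple[float, float] = ACCESSORY_BOUNDS,
    budget: int = 2000,
    seed: int | None = None,
    success_tol: float = 1.0,
) -> OptimizationResult:
    """Fit a fully connected ``m``-monomer candidate to a target.

    All ``m (m + 1) / 2`` affinities and the accessory totals are optimized
    in log10 space.  Function targets minimize the sum of squared log
    residuals of the best dimer (success: Chebyshev loss ``<= success_tol``);
    Boolean targets maximize the best dimer's on/off log margin (success:
    strictly positive margin).  Equilibria that fail to converge score
    ``BAD_LOSS``.  Deterministic given ``seed``.
    """
    if isinstance(target, TruthTable):
        n_inputs = target.n_inputs
        points, _ = gate_input_grid(n_inputs)
    else:
        n_inputs = n_inputs or target.grid.n_inputs
        points = target.grid.points
        F = target.log_values.ravel()
    if m < 2 or m <= n_inputs - 1:
        raise ValueError(f"network size m={m} too small")
    edges = _full_topology(m)
    n_k = len(edges)
    n_acc = m - n_inputs
    bounds = [affinity_bounds] * n_k + [accessory_bounds] * n_acc
    inputs = tuple(range(n_inputs))
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    n_eval = 0

    def simulate(params):
        kvec = 10.0 ** params[:n_k]
        kmat = np.zeros((m, m))
        kmat[ei, ej] = kvec
        kmat[ej, ei] = kvec
        totals = np.empty(m)
        totals[n_inputs:] = 10.0 ** params[n_k:]
        return response_matrix(kmat, kvec, ei, ej, totals, inputs, points)

    def objective(params):
        nonlocal n_eval
        n_eval += 1
        try:
            resp = simulate(params)
        except SolverError:
            return BAD_LOSS
        logr = np.log10(resp)
        if isinstance(target, TruthTable):
            margins = [gate_margin(resp[:, d], target) for d in range(n_k)]
            return -max(margins)
        sq = np.sum((logr - F[:, None]) ** 2, axis=0)
        return float(sq.min())

    result = dual_annealing(
        objective,
        bounds=bounds,
        maxfun=budget,
        maxiter=1000,
        rng=seed,
    )
    best = np.asarray(result.x)
    try:
        resp = simulate(best)
    except SolverError:
        return OptimizationResult(
            success=False, best_loss=BAD_LOSS, seed=seed, n_evaluations=n_eval
        )
    kvec = 10.0 ** best[:n_k]
    network = DimerizationNetwork(m, tuple(edges), tuple(kvec))
    totals = np.concatenate([np.ones(n_inputs), 10.0 ** best[n_k:]])
    profile = ConcentrationProfile(tuple(totals), inputs)
    logr = np.log10(resp)
    losses: dict = {}
    if isinstance(target, TruthTable):
        margins = np.array([gate_margin(resp[:, d], target) for d in range(n_k)])
        j = int(np.argmax(margins))
        losses["margin"] = float(margins[j])
        success = margins[j] > 0.0
        best_loss = -float(margins[j])
    else:
        sq = np.sum((logr - F[:, None]) ** 2, axis=0)
        j = int(np.argmin(sq))
        losses["sum_squares"] = float(sq[j])
        losses["mse"] = float(sq[j] / F.size)
        losses["inf"] = compute_loss("inf", F, logr[:, j])
        success = losses["inf"] <= success_tol
        best_loss = float(sq[j])
    return OptimizationResult(
        success=success,
        best_loss=best_loss,
        losses=losses,
        network=network,
        profile=profile,
        output_dimer=edges[j],
        seed=seed,
        n_evaluations=n_eval,
        metadata={"budget": budget, "bounds": bounds, "success_tol": success_tol},
    )


def find_minimal_network_size(
    target: TargetFunction | TruthTable,
    m_start: int,
    attempts: int = 5,
    budget: int = 2000,
    seed: int | None = None,
    m_min: int = 2,
    **fit_kwargs,
) -> dict:
    """Scan network sizes downward to find the smallest that fits the target.

    At each size, up to ``attempts`` independent annealing runs are tried
    (stopping at the first success); the scan descends while sizes keep
    succeeding and stops at the first size where every attempt fails.
    Returns a report with the minimal size (or None) and per-size best
    losses.
    """
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    ss = np.random.SeedSequence(seed)
    per_size: dict[int, dict] = {}
    minimal = None
    for m in range(m_start, m_min - 1, -1):
        best: OptimizationResult | None = None
        succeeded = False
        for child in ss.spawn(attempts):
            run_seed = int(child.generate_state(1)[0] % (2**31))
            res = fit_network_dual_annealing(
                target, m, budget=budget, seed=run_seed, **fit_kwargs
            )
            if best is None or res.best_loss < best.best_loss:
                best = res
            if res.success:
                succeeded = True
                break
        per_size[m] = {"success": succeeded, "best_loss": best.best_loss, "losses": best.losses}
        if not succeeded:
            break
        minimal = m
    return {"minimal_m": minimal, "per_size": per_size}


# --------------------------------------------------------------------------
# genetic algorithm over accessory levels


@dataclass(frozen=True)
class GAParams:
    """Real-coded GA hyperparameters (tournament selection, SBX crossover,
    polynomial mutation, elitist mu+lambda survival)."""

    population: int = 100
    iterations: int = 20
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0

    @classmethod
    def default_for(cls, n_inputs: int) -> "GAParams":
        if n_inputs == 1:
            return cls(population=100, iterations=20)
        return cls(population=1000, iterations=200)


def _ga_minimize(fun, n_dim, bounds, params: GAParams, rng) -> tuple[np.ndarray, float]:
    """Minimize ``fun`` over a box with a seeded real-coded GA."""
    lo, hi = bounds
    pop = rng.uniform(lo, hi, size=(params.population, n_dim))
    fit = np.array([fun(ind) for ind in pop])
    p_mut = 1.0 / n_dim
    for _ in range(params.iterations):
        # binary tournament selection for each parent slot
        cand = rng.integers(0, params.population, size=(2, params.population))
        parents = pop[np.where(fit[cand[0]] <= fit[cand[1]], cand[0], cand[1])]
        # simulated binary crossover (SBX) on consecutive pairs
        children = parents.copy()
        for a in range(0, params.population - 1, 2):
            if rng.random() < params.crossover_prob:
                u = rng.random(n_dim)
                beta = np.where(
                    u <= 0.5,
                    (2 * u) ** (1.0 / (params.crossover_eta + 1)),
                    (1.0 / (2 * (1 - u))) ** (1.0 / (params.crossover_eta + 1)),
                )
                p1, p2 = parents[a], parents[a + 1]
                children[a] = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
                children[a + 1] = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
        # polynomial mutation
        mask = rng.random(children.shape) < p_mut
        u = rng.random(children.shape)
        delta = np.where(
            u < 0.5,
            (2 * u) ** (1.0 / (params.mutation_eta + 1)) - 1.0,
            1.0 - (2 * (1 - u)) ** (1.0 / (params.mutation_eta + 1)),
        )
        children = np.where(mask, children + delta * (hi - lo), children)
        children = np.clip(children, lo, hi)
        child_fit = np.array([fun(ind) for ind in children])
        # elitist mu+lambda truncation
        merged = np.vstack([pop, children])
        merged_fit = np.concatenate([fit, child_fit])
        order = np.argsort(merged_fit, kind="stable")[: params.population]
        pop, fit = merged[order], merged_fit[order]
    best = int(np.argmin(fit))
    return pop[best].copy(), float(fit[best])


def optimize_accessories_ga(
    network: DimerizationNetwork,
    target: TargetFunction,
    dimer: tuple[int, int] | int,
    input_indices=(0,),
    accessory_bounds: tuple[float, float] = ACCESSORY_BOUNDS,
    ga_params: GAParams | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Tune accessory totals (K fixed) to fit ``target`` with one dimer.

    Minimizes the mean squared log residual; returns the optimal accessory
    totals and a dict of losses (``mse``, ``inf``, and ``pearson`` when
    defined) evaluated at the optimum.
    """
    grid = target.grid
    inputs = tuple(input_indices)
    if ga_params is None:
        ga_params = GAParams.default_for(len(inputs))
    m = network.m
    acc = [i for i in range(m) if i not in inputs]
    d_idx = dimer if isinstance(dimer, int) else network.edge_index()[tuple(sorted(dimer))]
    kmat = network.affinity_matrix()
    kvec = np.asarray(network.K)
    ei = np.array([e[0] for e in network.edges])
    ej = np.array([e[1] for e in network.edges])
    F = target.log_values.ravel()
    pts = grid.points
    totals = np.ones(m)

    def response_for(log_a):
        t = totals.copy()
        t[acc] = 10.0**log_a
        return np.log10(
            response_matrix(kmat, kvec, ei, ej, t, inputs, pts)[:, d_idx]
        )

    def fun(log_a):
        try:
            G = response_for(log_a)
        except SolverError:
            return BAD_LOSS
        return compute_loss("mse", F, G)

    rng = np.random.default_rng(seed)
    best, best_mse = _ga_minimize(fun, len(acc), accessory_bounds, ga_params, rng)
    losses = {"mse": best_mse}
    try:
        G = response_for(best)
        losses["inf"] = compute_loss("inf", F, G)
        if np.ptp(F) > 0 and np.ptp(G) > 0:
            losses["pearson"] = compute_loss("pearson", F, G)
    except SolverError:
        losses["inf"] = np.inf
    return 10.0**best, losses


# --------------------------------------------------------------------------
# versatility


@dataclass
class VersatilityReport:
    """Per-dimer and any-dimer achievable fractions of a target library."""

    m: int
    gamma: float
    library_size: int
    per_dimer: dict  # dimer -> fraction of targets achieved with that dimer
    any_dimer: float
    detail: dict  # (dimer, target index) -> {"losses", "accessories"}

    @property
    def best_single_dimer(self) -> float:
        return max(self.per_dimer.values())


def _versatility_runs(
    network: DimerizationNetwork,
    library: TargetLibrary,
    input_indices,
    ga_params: GAParams | None,
    seed,
    dimers=None,
) -> dict:
    if library.size == 0:
        raise ValueError("target library is empty")
    dimers = list(network.edges if dimers is None else dimers)
    ss = np.random.SeedSequence(seed)
    detail = {}
    for d, d_ss in zip(dimers, ss.spawn(len(dimers))):
        for t_idx, t_ss in enumerate(d_ss.spawn(library.size)):
            target = TargetFunction(library.targets[t_idx], library.grid)
            a_star, losses = optimize_accessories_ga(
                network,
                target,
                dimer=d,
                input_indices=input_indices,
                ga_params=ga_params,
                seed=int(t_ss.generate_state(1)[0] % (2**31)),
            )
            detail[(d, t_idx)] = {"losses": losses, "accessories": a_star}
    return detail


def versatility_single_dimer(
    network: DimerizationNetwork,
    library: TargetLibrary,
    input_indices=(0,),
    gamma: float = 1.0,
    ga_params: GAParams | None = None,
    seed: int | None = None,
    dimers=None,
) -> VersatilityReport:
    """Fraction of library targets each dimer achieves by tuning accessories.

    A target is achieved when the Chebyshev loss of the GA-optimized
    response is at most ``gamma`` (1 = within 10-fold everywhere).  The
    any-dimer fraction counts targets achieved by at least one dimer.
    """
    detail = _versatility_runs(network, library, input_indices, ga_params, seed, dimers)
    dimer_list = sorted({d for d, _ in detail})
    per_dimer = {}
    for d in dimer_list:
        hits = sum(
            detail[(d, t)]["losses"].get("inf", np.inf) <= gamma
            for t in range(library.size)
        )
        per_dimer[d] = hits / library.size
    any_hits = sum(
        any(
            detail[(d, t)]["losses"].get("inf", np.inf) <= gamma
            for d in dimer_list
        )
        for t in range(library.size)
    )
    return VersatilityReport(
        m=network.m,
        gamma=gamma,
        library_size=library.size,
        per_dimer=per_dimer,
        any_dimer=any_hits / library.size,
        detail=detail,
    )


def versatility_any_dimer(
    network: DimerizationNetwork,
    library: TargetLibrary,
    input_indices=(0,),
    gamma: float = 1.0,
    ga_params: GAParams | None = None,
    seed: int | None = None,
) -> float:
    """Fraction of targets achievable with free choice of output dimer."""
    report = versatility_single_dimer(
        network, library, input_indices, gamma, ga_params, seed
    )
    return report.any_dimer


def named_two_input_targets(grid: TitrationGrid | None = None) -> dict[str, TargetFunction]:
    """Idealized two-input target surfaces for versatility analysis.

    Seven Boolean gates (AND, OR, NAND, NOR, XOR, XNOR, NIMPLY) rendered as
    log surfaces (high decade +1, low decade -2, inputs "on" above 1), a
    ratiometric target (log of the input ratio), an equality target (high
    within one decade of the diagonal), and a two-input bump (high only
    when both inputs are mid-range).  Success for these targets is judged
    by Pearson correlation, which is affine invariant, so only the shapes
    matter.
    """
    if grid is None:
        grid = TitrationGrid.default(2)
    pts = np.log10(grid.points)  # (n, 2)
    x1, x2 = pts[:, 0], pts[:, 1]
    on1, on2 = x1 > 0, x2 > 0
    hi, lo = 1.0, -2.0

    def boolify(mask):
        return np.where(mask, hi, lo)

    targets = {}
    for name in ("AND", "OR", "NAND", "NOR", "XOR", "XNOR", "NIMPLY"):
        fn = _GATES_2[name]
        mask = np.array([fn(a, b) for a, b in zip(on1, on2)])
        targets[name] = boolify(mask)
    targets["ratiometric"] = np.clip((x1 - x2) / 2.0, lo, hi)
    targets["equality"] = boolify(np.abs(x1 - x2) <= 1.0)
    targets["two_input_bump"] = boolify(
        (np.abs(x1) <= 1.5) & (np.abs(x2) <= 1.5)
    )
    return {
        name: TargetFunction(vals.reshape(grid.shape), grid)
        for name, vals in targets.items()
    }


def versatility_two_input(
    network: DimerizationNetwork,
    targets: dict[str, TargetFunction] | None = None,
    input_indices=(0, 1),
    r_threshold: float = 0.85,
    ga_params: GAParams | None = None,
    seed: int | None = None,
) -> dict:
    """Which named two-input targets a fixed-K network can perform.

    Accessories are GA-tuned (MSE objective) per dimer; a target is
    achieved when the best dimer's Pearson correlation with the target
    reaches ``r_threshold``.
    """
    if targets is None:
        targets = named_two_input_targets()
    ss = np.random.SeedSequence(seed)
    report = {}
    for (name, target), child in zip(targets.items(), ss.spawn(len(targets))):
        best_r = -np.inf
        best = None
        for d, d_ss in zip(network.edges, child.spawn(network.n_dimers)):
            a_star, losses = optimize_accessories_ga(
                network,
                target,
                dimer=d,
                input_indices=input_indices,
                ga_params=ga_params,
                seed=int(d_ss.generate_state(1)[0] % (2**31)),
            )
            r = losses.get("pearson", -np.inf)
            if r > best_r:
                best_r, best = r, {"dimer": d, "accessories": a_star, "losses": losses}
        report[name] = {
            "achieved": bool(best_r >= r_threshold),
            "pearson": best_r,
            **(best or {}),
        }
    return report
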