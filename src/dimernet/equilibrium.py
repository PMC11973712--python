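"""Equilibrium of coupled dimerization reactions under mass conservation.

For a network with affinities ``K_ij`` and conserved totals ``T_i``, the
equilibrium satisfies, for every monomer ``i``,

    T_i = M_i + 2 K_ii M_i^2 + sum_{j != i} K_ij M_i M_j,

together with the mass-action relations ``D_ij = K_ij M_i M_j``.  In log
free-monomer coordinates ``x_i = log M_i`` this system is the gradient of
the strictly convex potential

    Phi(x) = sum_i e^{x_i} + sum_i K_ii e^{2 x_i}
             + sum_{i<j} K_ij e^{x_i + x_j} - sum_i T_i x_i,

so the equilibrium is unique and a damped Newton iteration with a
backtracking line search on Phi converges globally.  Monomers with total
exactly zero are removed from the solve (their free form and every dimer
they participate in are exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ConcentrationProfile, DimerizationNetwork

__all__ = [
    "EquilibriumState",
    "SolverError",
    "solve_equilibrium",
    "solve_equilibrium_free",
    "pair_equilibrium_closed_form",
    "homodimer_equilibrium_closed_form",
]

DEFAULT_TOL = 1e-9
MAX_ITER = 200

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


class SolverError(RuntimeError):
    """Newton iteration failed to reach the requested conservation tolerance."""

    def __init__(self, msg: str, residual_norm: float):
        super().__init__(msg)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class EquilibriumState:
    """Free-monomer and dimer concentrations at equilibrium."""

    free: np.ndarray
    dimers: dict[tuple[int, int], float]
    residual_norm: float

    def dimer_array(self, network: DimerizationNetwork) -> np.ndarray:
        return np.array([self.dimers[e] for e in network.edges])

    def total_of(self, i: int, network: DimerizationNetwork) -> float:
        """Reconstructed conserved total of monomer ``i`` (homodimers count twice)."""
        tot = self.free[i]
        for (a, b), d in self.dimers.items():
            if a == b == i:
                tot += 2.0 * d
            elif i in (a, b):
                tot += d
        return tot


@njit(cache=True)
def _newton_log(kmat, totals, tol, max_iter):
    """Damped Newton on the convex potential in log free-monomer coordinates.

    Returns (x, residual_norm, converged, n_iter); residual_norm is the max
    conservation violation relative to each total.
    """
    m = totals.shape[0]
    x = np.log(totals)  # totals > 0 guaranteed by caller

    # potential at x
    def _phi(xv):
        e = np.exp(xv)
        p = 0.0
        for i in range(m):
            p += e[i] + kmat[i, i] * e[i] * e[i] - totals[i] * xv[i]
            for j in range(i + 1, m):
                p += kmat[i, j] * e[i] * e[j]
        return p

    phi = _phi(x)
    res_norm = np.inf
    for it in range(max_iter):
        e = np.exp(x)
        r = np.empty(m)
        jac = np.zeros((m, m))
        for i in range(m):
            ri = e[i] + 2.0 * kmat[i, i] * e[i] * e[i]
            jac[i, i] = e[i] + 4.0 * kmat[i, i] * e[i] * e[i]
            for j in range(m):
                if j != i and kmat[i, j] > 0.0:
                    d = kmat[i, j] * e[i] * e[j]
                    ri += d
                    jac[i, i] += d
                    jac[i, j] = d
            r[i] = ri - totals[i]
        res_norm = 0.0
        for i in range(m):
            rel = abs(r[i]) / totals[i]
            if rel > res_norm:
                res_norm = rel
        if res_norm <= tol:
            return x, res_norm, True, it
        dx = np.linalg.solve(jac, -r)
        # cap the step to keep exp() in range
        step_max = 0.0
        for i in range(m):
            if abs(dx[i]) > step_max:
                step_max = abs(dx[i])
        if step_max > 10.0:
            dx *= 10.0 / step_max
        # backtracking Armijo line search on the convex potential
        g_dot_dx = 0.0
        for i in range(m):
            g_dot_dx += r[i] * dx[i]
        t = 1.0
        if res_norm > 1e-2:  # line search only outside the quadratic region
            for _ in range(60):
                phi_new = _phi(x + t * dx)
                if phi_new <= phi + 1e-4 * t * g_dot_dx:
                    break
                t *= 0.5
        x = x + t * dx
        phi = _phi(x)
    return x, res_norm, False, max_iter


def solve_equilibrium_free(
    kmat: np.ndarray,
    totals: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Free-monomer concentrations for an affinity matrix and totals vector.

    Low-level entry point used by titrations and optimizers; ``kmat`` is the
    symmetric (m, m) affinity matrix with zeros where no dimer forms.
    ``x0`` optionally supplies log free-monomer starting values for the
    positive-total submatrix (warm start along a titration).
    """
    totals = np.asarray(totals, dtype=float)
    if np.any(totals < 0) or not np.all(np.isfinite(totals)):
        raise ValueError("totals must be non-negative and finite")
    m = totals.size
    free = np.zeros(m)
    active = totals > 0.0
    if not np.any(active):
        return free
    idx = np.nonzero(active)[0]
    sub_k = np.ascontiguousarray(kmat[np.ix_(idx, idx)])
    sub_t = np.ascontiguousarray(totals[idx])
    if x0 is not None:
        x, res, ok, _ = _newton_from(sub_k, sub_t, np.ascontiguousarray(x0), tol, max_iter)
    else:
        x, res, ok, _ = _newton_log(sub_k, sub_t, tol, max_iter)
    if not ok:
        raise SolverError(
            f"equilibrium solve did not converge (residual {res:.3e} > tol {tol:.1e})", res
        )
    free[idx] = np.exp(x)
    return free


@njit(cache=True)
def _newton_from(kmat, totals, x0, tol, max_iter):
    """Same iteration as _newton_log but from a caller-supplied start."""
    m = totals.shape[0]
    x = x0.copy()

    def _phi(xv):
        e = np.exp(xv)
        p = 0.0
        for i in range(m):
            p += e[i] + kmat[i, i] * e[i] * e[i] - totals[i] * xv[i]
            for j in range(i + 1, m):
                p += kmat[i, j] * e[i] * e[j]
        return p

    phi = _phi(x)
    res_norm = np.inf
    for it in range(max_iter):
        e = np.exp(x)
        r = np.empty(m)
        jac = np.zeros((m, m))
        for i in range(m):
            ri = e[i] + 2.0 * kmat[i, i] * e[i] * e[i]
            jac[i, i] = e[i] + 4.0 * kmat[i, i] * e[i] * e[i]
            for j in range(m):
                if j != i and kmat[i, j] > 0.0:
                    d = kmat[i, j] * e[i] * e[j]
                    ri += d
                    jac[i, i] += d
                    jac[i, j] = d
            r[i] = ri - totals[i]
        res_norm = 0.0
        for i in range(m):
            rel = abs(r[i]) / totals[i]
            if rel > res_norm:
                res_norm = rel
        if res_norm <= tol:
            return x, res_norm, True, it
        dx = np.linalg.solve(jac, -r)
        step_max = 0.0
        for i in range(m):
            if abs(dx[i]) > step_max:
                step_max = abs(dx[i])
        if step_max > 10.0:
            dx *= 10.0 / step_max
        g_dot_dx = 0.0
        for i in range(m):
            g_dot_dx += r[i] * dx[i]
        t = 1.0
        if res_norm > 1e-2:  # line search only outside the quadratic region
            for _ in range(60):
                phi_new = _phi(x + t * dx)
                if phi_new <= phi + 1e-4 * t * g_dot_dx:
                    break
                t *= 0.5
        x = x + t * dx
        phi = _phi(x)
    return x, res_norm, False, max_iter


def solve_equilibrium(
    network: DimerizationNetwork,
    profile: ConcentrationProfile,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
) -> EquilibriumState:
    """Unique equilibrium of ``network`` at the profile's total concentrations."""
    totals = profile.totals_array()
    if totals.size != network.m:
        raise ValueError("profile size does not match network")
    kmat = network.affinity_matrix()
    free = solve_equilibrium_free(kmat, totals, tol=tol, max_iter=max_iter)
    dimers = {
        (i, j): float(k * free[i] * free[j]) for (i, j), k in zip(network.edges, network.K)
    }
    # realized max relative conservation violation
    res = 0.0
    for i in range(network.m):
        if totals[i] > 0:
            tot = free[i]
            for (a, b), d in dimers.items():
                if a == b == i:
                    tot += 2 * d
                elif i in (a, b):
                    tot += d
            res = max(res, abs(tot - totals[i]) / totals[i])
    return EquilibriumState(free=free, dimers=dimers, residual_norm=res)


def pair_equilibrium_closed_form(K: float, T_A: float, T_B: float):
    """Exact single-heterodimer equilibrium via the stable quadratic root.

    The dimer concentration solves ``D^2 - D (T_A + T_B + 1/K) + T_A T_B = 0``
    with the physical root in ``[0, min(T_A, T_B)]``.  Evaluated in the
    numerically stable form ``D = 2 T_A T_B / (b + sqrt(b^2 - 4 T_A T_B))``.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if T_A < 0 or T_B < 0:
        raise ValueError("totals must be non-negative")
    if T_A == 0 or T_B == 0:
        return T_A, T_B, 0.0
    q = 1.0 / K
    b = T_A + T_B + q
    # expanded discriminant avoids the catastrophic cancellation of
    # b^2 - 4 Ta Tb when Ta ~ Tb and 1/K is tiny
    disc = (T_A - T_B) ** 2 + q * q + 2.0 * q * (T_A + T_B)
    dimer = 2.0 * T_A * T_B / (b + np.sqrt(disc))

    def _free(T_self, T_other):
        # free monomer solves K a^2 + a (K (T_other - T_self) + 1) - T_self = 0;
        # picking the branch without subtraction keeps it stable when nearly
        # all of this monomer is sequestered
        bp = K * (T_other - T_self) + 1.0
        root = np.sqrt(bp * bp + 4.0 * K * T_self)
        if bp >= 0:
            return 2.0 * T_self / (bp + root)
        return (root - bp) / (2.0 * K)

    return _free(T_A, T_B), _free(T_B, T_A), dimer


def homodimer_equilibrium_closed_form(K: float, T: float):
    """Exact single-homodimer equilibrium: solves ``M + 2 K M^2 = T``.

    Uses the stable root ``M = 2 T / (1 + sqrt(1 + 8 K T))``; ``D = K M^2``.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if T < 0:
        raise ValueError("total must be non-negative")
    if T == 0:
        return 0.0, 0.0
    free = 2.0 * T / (1.0 + np.sqrt(1.0 + 8.0 * K * T))
    return free, K * free * free
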