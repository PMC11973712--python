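"""Competitive dimerization networks and random-network generation.

A dimerization network is an undirected graph on ``m`` monomer species in
which each edge ``(i, j)`` (``i <= j``, homodimer loops allowed) carries a
dimensionless association constant ``K_ij = D_ij / (M_i * M_j)``.  Random
networks are drawn the way large parameter screens build them: a connected
Erdos-Renyi heterodimer backbone with a fixed edge count, independent
homodimer loops, and log-uniform Latin-hypercube affinities and expression
levels.

Monomers are indexed 0-based internally; serialized files use 1-based
indices (see :mod:`dimernet.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import qmc

__all__ = [
    "DimerizationNetwork",
    "ConcentrationProfile",
    "enumerate_heterodimer_edge_counts",
    "sample_connected_topology",
    "sample_affinities",
    "sample_expression_levels",
    "random_network",
    "screen_design",
]

#: Default log10 affinity range of the broad parameter screen.
SCREEN_AFFINITY_RANGE = (-5.0, 7.0)
#: Restricted affinity range used for biologically narrow screens.
RESTRICTED_AFFINITY_RANGE = (-3.0, 1.0)
#: Affinity range used when sampling random networks for versatility analysis.
VERSATILITY_AFFINITY_RANGE = (-7.0, 5.0)
#: Default log10 range of total monomer concentrations (expression levels).
EXPRESSION_RANGE = (-3.0, 3.0)
#: Fraction of monomers that receive a homodimerization loop.
HOMODIMER_PROB = 0.75

_CONNECTIVITY_RETRY_CAP = 100_000


def _canonical_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class DimerizationNetwork:
    """A set of monomers plus the dimers they can form.

    Parameters
    ----------
    m : int
        Number of monomer species (>= 2).
    edges : tuple of (int, int)
        Sorted unordered monomer pairs, 0-based, ``i <= j``; ``i == j`` is a
        homodimer.
    K : tuple of float
        Dimensionless affinity constant per edge, aligned with ``edges``.
    """

    m: int
    edges: tuple[tuple[int, int], ...]
    K: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"network needs at least 2 monomers, got m={self.m}")
        edges = tuple(_canonical_edge(*e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "K", tuple(float(k) for k in self.K))
        if len(self.K) != len(edges):
            raise ValueError("K must align with edges")
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges")
        for (i, j), k in zip(edges, self.K):
            if not (0 <= i <= j < self.m):
                raise ValueError(f"edge {(i, j)} out of range for m={self.m}")
            if not (k > 0 and math.isfinite(k)):
                raise ValueError(f"affinity for edge {(i, j)} must be positive and finite, got {k}")
        hetero = [e for e in edges if e[0] != e[1]]
        g = nx.Graph()
        g.add_nodes_from(range(self.m))
        g.add_edges_from(hetero)
        if not nx.is_connected(g):
            raise ValueError("heterodimer subgraph must be connected")

    @property
    def n_dimers(self) -> int:
        return len(self.edges)

    @property
    def heterodimer_edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(e for e in self.edges if e[0] != e[1])

    @property
    def homodimer_edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(e for e in self.edges if e[0] == e[1])

    def affinity_matrix(self) -> np.ndarray:
        """Symmetric (m, m) matrix of affinities, 0 where no edge exists."""
        kmat = np.zeros((self.m, self.m))
        for (i, j), k in zip(self.edges, self.K):
            kmat[i, j] = k
            kmat[j, i] = k
        return kmat

    def with_affinities(self, K) -> "DimerizationNetwork":
        return DimerizationNetwork(self.m, self.edges, tuple(K))

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {e: idx for idx, e in enumerate(self.edges)}


@dataclass(frozen=True)
class ConcentrationProfile:
    """Total monomer concentrations with a designated set of input monomers.

    ``totals[i]`` is the conserved total of monomer ``i`` (free plus bound,
    counting homodimers twice).  Input monomers are the ones an input-output
    simulation titrates; the remaining accessory totals stay fixed.
    """

    totals: tuple[float, ...]
    input_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        totals = tuple(float(t) for t in self.totals)
        object.__setattr__(self, "totals", totals)
        inputs = tuple(sorted(int(i) for i in self.input_indices))
        object.__setattr__(self, "input_indices", inputs)
        for t in totals:
            if not (t >= 0 and math.isfinite(t)):
                raise ValueError(f"totals must be non-negative and finite, got {t}")
        if len(set(inputs)) != len(inputs):
            raise ValueError("duplicate input indices")
        for i in inputs:
            if not 0 <= i < len(totals):
                raise ValueError(f"input index {i} out of range")

    @property
    def m(self) -> int:
        return len(self.totals)

    @property
    def accessory_indices(self) -> tuple[int, ...]:
        inputs = set(self.input_indices)
        return tuple(i for i in range(self.m) if i not in inputs)

    def totals_array(self) -> np.ndarray:
        return np.asarray(self.totals, dtype=float)

    def with_totals(self, totals) -> "ConcentrationProfile":
        return ConcentrationProfile(tuple(totals), self.input_indices)


def enumerate_heterodimer_edge_counts(m: int) -> range:
    """Inclusive range of heterodimer edge counts for a connected topology.

    A connected graph on ``m`` monomers needs at least ``m - 1`` edges and
    can hold at most ``m (m - 1) / 2``.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    return range(m - 1, m * (m - 1) // 2 + 1)


def screen_design(m: int, n_networks_total: int = 1_000_000) -> dict:
    """Per-connectivity allocation of a screen stratified over edge counts.

    Screens draw equal numbers of networks at every admissible heterodimer
    edge count; the per-count quota is ``ceil(total / n_options)``, so the
    realized total can slightly exceed the requested one (for m=8 and a
    requested 1e6: 22 options * 45455 = 1,000,010 networks).
    """
    counts = enumerate_heterodimer_edge_counts(m)
    n_options = len(counts)
    per_count = -(-n_networks_total // n_options)  # ceil division
    return {
        "edge_counts": counts,
        "n_options": n_options,
        "networks_per_edge_count": per_count,
        "total_networks": per_count * n_options,
    }


def sample_connected_topology(
    m: int,
    n_hetero: int,
    homodimer_prob: float = HOMODIMER_PROB,
    seed=None,
    retry_cap: int = _CONNECTIVITY_RETRY_CAP,
) -> tuple[tuple[int, int], ...]:
    """Draw a connected heterodimer topology plus Bernoulli homodimer loops.

    The heterodimer subgraph is a G(m, n_hetero) Erdos-Renyi draw, rejected
    and re-drawn until connected.  Each monomer independently receives a
    homodimer loop with probability ``homodimer_prob``.
    """
    if n_hetero not in enumerate_heterodimer_edge_counts(m):
        raise ValueError(
            f"n_hetero={n_hetero} outside the admissible range "
            f"[{m - 1}, {m * (m - 1) // 2}] for m={m}"
        )
    if not 0.0 <= homodimer_prob <= 1.0:
        raise ValueError("homodimer_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(retry_cap):
        g = nx.gnm_random_graph(m, n_hetero, seed=rng)
        if nx.is_connected(g):
            break
    else:
        raise RuntimeError(f"no connected topology found in {retry_cap} attempts")
    edges = sorted(_canonical_edge(i, j) for i, j in g.edges())
    homo = [(i, i) for i in range(m) if rng.random() < homodimer_prob]
    return tuple(sorted(edges + homo))


def _lhs_log_uniform(n: int, log10_lo: float, log10_hi: float, rng) -> np.ndarray:
    """n log-uniform samples on [10**lo, 10**hi], Latin-hypercube stratified
    along the exponent axis (one sample per stratum)."""
    if log10_lo > log10_hi:
        raise ValueError("log10_lo must not exceed log10_hi")
    if log10_lo == log10_hi:
        return np.full(n, 10.0 ** log10_lo)
    sampler = qmc.LatinHypercube(d=1, seed=rng)
    u = sampler.random(n)[:, 0]
    return 10.0 ** (log10_lo + u * (log10_hi - log10_lo))


def sample_affinities(
    edges,
    log10_lo: float = SCREEN_AFFINITY_RANGE[0],
    log10_hi: float = SCREEN_AFFINITY_RANGE[1],
    seed=None,
) -> dict[tuple[int, int], float]:
    """One log-uniform LHS affinity per edge."""
    edges = list(edges)
    if not edges:
        raise ValueError("edge set is empty")
    rng = np.random.default_rng(seed)
    vals = _lhs_log_uniform(len(edges), log10_lo, log10_hi, rng)
    return {(min(i, j), max(i, j)): float(v) for (i, j), v in zip(edges, vals)}


def sample_expression_levels(
    count: int,
    log10_lo: float = EXPRESSION_RANGE[0],
    log10_hi: float = EXPRESSION_RANGE[1],
    seed=None,
) -> np.ndarray:
    """LHS log-uniform total concentrations for ``count`` monomers."""
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    return _lhs_log_uniform(count, log10_lo, log10_hi, rng)


def random_network(
    m: int,
    n_hetero: int | None = None,
    n_inputs: int = 1,
    affinity_range: tuple[float, float] = SCREEN_AFFINITY_RANGE,
    expression_range: tuple[float, float] = EXPRESSION_RANGE,
    homodimer_prob: float = HOMODIMER_PROB,
    seed=None,
) -> tuple[DimerizationNetwork, ConcentrationProfile]:
    """Draw a full random network plus a concentration profile.

    Input monomers are, by convention, the lowest indices (monomer 0 for
    one-input studies, 0 and 1 for two-input); their sampled totals are
    placeholders that a titration overrides.
    """
    rng = np.random.default_rng(seed)
    if n_hetero is None:
        n_hetero = int(rng.choice(list(enumerate_heterodimer_edge_counts(m))))
    edges = sample_connected_topology(m, n_hetero, homodimer_prob, seed=rng)
    kmap = sample_affinities(edges, *affinity_range, seed=rng)
    net = DimerizationNetwork(m, edges, tuple(kmap[e] for e in edges))
    totals = sample_expression_levels(m, *expression_range, seed=rng)
    profile = ConcentrationProfile(tuple(totals), tuple(range(n_inputs)))
    return net, profile
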