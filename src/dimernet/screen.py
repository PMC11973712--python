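"""Random parameter screens over network sizes.

Drives the pipeline random network -> input titration -> dynamic-range
filter -> discretized code, collecting a tidy results table, the unique
functions found per size, and representative networks for downstream
robustness or versatility analyses.  Screens stratify evenly over the
admissible heterodimer edge counts of each size, mirroring how large
screens allocate networks per connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibrium import SolverError
from .network import (
    EXPRESSION_RANGE,
    HOMODIMER_PROB,
    SCREEN_AFFINITY_RANGE,
    ConcentrationProfile,
    DimerizationNetwork,
    enumerate_heterodimer_edge_counts,
    random_network,
)
from .response import (
    DiscretizedFunction,
    ResponseSurface,
    TargetLibrary,
    TitrationGrid,
    build_target_library,
    count_local_extrema,
    count_unique_functions,
    discretize,
    dynamic_range_filter,
    titrate,
)

__all__ = ["ScreenRecord", "ScreenResult", "run_screen", "unique_function_counts"]


@dataclass(frozen=True)
class ScreenRecord:
    """One surviving response of one screened network."""

    network_id: int
    m: int
    n_hetero: int
    network: DimerizationNetwork
    profile: ConcentrationProfile
    response: ResponseSurface
    code: DiscretizedFunction


@dataclass
class ScreenResult:
    records: list[ScreenRecord]
    grid: TitrationGrid
    n_networks: int
    n_solver_failures: int

    def table(self) -> pd.DataFrame:
        """Tidy per-response table (one row per surviving dimer response)."""
        rows = []
        for r in self.records:
            row = {
                "network_id": r.network_id,
                "m": r.m,
                "n_hetero": r.n_hetero,
                "dimer": f"D{r.response.dimer[0] + 1}{r.response.dimer[1] + 1}",
                "code": "".join(str(c) for c in r.code.code),
                "dynamic_range": r.response.dynamic_range,
            }
            if self.grid.n_inputs == 1:
                row["n_extrema"] = count_local_extrema(r.response)
            rows.append(row)
        return pd.DataFrame(rows)

    def codes(self, m: int | None = None) -> list[DiscretizedFunction]:
        return [r.code for r in self.records if m is None or r.m == m]

    def n_unique_functions(self, m: int | None = None) -> int:
        return count_unique_functions(self.codes(m))

    def per_network_codes(self) -> dict[int, list[DiscretizedFunction]]:
        out: dict[int, list[DiscretizedFunction]] = {}
        for r in self.records:
            out.setdefault(r.network_id, []).append(r.code)
        return out

    def target_library(self, m: int) -> TargetLibrary:
        responses = [r.response for r in self.records if r.m == m]
        return build_target_library(responses, m=m, grid=self.grid)

    def representatives(self, seed=None) -> list[ScreenRecord]:
        """One randomly chosen representative record per unique function."""
        rng = np.random.default_rng(seed)
        by_code: dict[tuple, list[ScreenRecord]] = {}
        for r in self.records:
            by_code.setdefault(r.code.code, []).append(r)
        reps = []
        for code in sorted(by_code):
            members = by_code[code]
            reps.append(members[rng.integers(0, len(members))])
        return reps


def run_screen(
    sizes,
    n_per_size: int,
    n_inputs: int = 1,
    affinity_range: tuple[float, float] = SCREEN_AFFINITY_RANGE,
    expression_range: tuple[float, float] = EXPRESSION_RANGE,
    homodimer_prob: float = HOMODIMER_PROB,
    grid: TitrationGrid | None = None,
    fold: float = 10.0,
    seed=None,
) -> ScreenResult:
    """Screen ``n_per_size`` random networks at each size in ``sizes``.

    Edge counts cycle through the admissible range of each size so every
    connectivity receives an equal share.  Networks whose titration fails
    to converge are counted and skipped.
    """
    sizes = list(sizes)
    if grid is None:
        grid = TitrationGrid.default(n_inputs)
    seeds = np.random.SeedSequence(seed)
    records: list[ScreenRecord] = []
    n_total = 0
    n_fail = 0
    network_id = 0
    for m, child in zip(sizes, seeds.spawn(len(sizes))):
        edge_options = list(enumerate_heterodimer_edge_counts(m))
        for k, sub in enumerate(child.spawn(n_per_size)):
            n_hetero = edge_options[k % len(edge_options)]
            net, prof = random_network(
                m,
                n_hetero=n_hetero,
                n_inputs=n_inputs,
                affinity_range=affinity_range,
                expression_range=expression_range,
                homodimer_prob=homodimer_prob,
                seed=sub,
            )
            n_total += 1
            try:
                responses = titrate(net, prof, grid)
            except SolverError:
                n_fail += 1
                network_id += 1
                continue
            for resp in dynamic_range_filter(responses, fold=fold):
                records.append(
                    ScreenRecord(
                        network_id=network_id,
                        m=m,
                        n_hetero=n_hetero,
                        network=net,
                        profile=prof,
                        response=resp,
                        code=discretize(resp),
                    )
                )
            network_id += 1
    return ScreenResult(
        records=records, grid=grid, n_networks=n_total, n_solver_failures=n_fail
    )


def unique_function_counts(result: ScreenResult) -> pd.DataFrame:
    """Unique-function count per network size (expressivity census)."""
    sizes = sorted({r.m for r in result.records})
    return pd.DataFrame(
        {
            "m": sizes,
            "n_unique_functions": [result.n_unique_functions(m) for m in sizes],
        }
    )
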