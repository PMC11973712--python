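"""Catalog of elementary dimerization networks with known behaviors.

Each fixture is a minimal network performing a canonical function:
monotone switches, biphasic bumps and their inversions for one input, and
Boolean gates / analog surfaces for two inputs.  The switch/bump/gate
mechanisms were designed from sequestration reasoning (an input monomer
titrates its partner away from downstream dimers); the XOR parameters were
refined by annealing on the fixed topology.  Expected behavior is stored
as a discretized response code or a truth table, not exact concentrations,
and every fixture is verified against its expectation by the test suite.

Monomer indices below are 0-based; names in comments use the 1-based
convention (input M1, output e.g. D22).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ConcentrationProfile, DimerizationNetwork
from .optimize import TruthTable, named_gate
from .response import DiscretizedFunction

__all__ = ["Fixture", "FIXTURE_NAMES", "make_fixture"]


@dataclass(frozen=True)
class Fixture:
    name: str
    network: DimerizationNetwork
    profile: ConcentrationProfile
    output_dimer: tuple[int, int]
    expected_code: DiscretizedFunction | None = None
    expected_gate: TruthTable | None = None
    n_extrema: int | None = None
    monotone: str | None = None  # "increasing" / "decreasing"


def _fx(name, m, edges, K, totals, inputs, out, **kw):
    return Fixture(
        name=name,
        network=DimerizationNetwork(m, edges, K),
        profile=ConcentrationProfile(totals, inputs),
        output_dimer=out,
        **kw,
    )


def _catalog() -> dict[str, Fixture]:
    c = {}
    # M1 sequesters M2 away from the D22 output homodimer.
    c["switch_off"] = _fx(
        "switch_off", 2, ((0, 1), (1, 1)), (1e6, 1e4), (1.0, 1.0), (0,), (1, 1),
        expected_code=DiscretizedFunction((2, 2, 2, 0, 0, 0)),
        n_extrema=0, monotone="decreasing",
    )
    # M1 takes M2, freeing M3 to form D33: one extra species inverts the switch.
    c["switch_on"] = _fx(
        "switch_on", 3, ((0, 1), (1, 2), (2, 2)), (1e6, 1e6, 1e4),
        (1.0, 1.0, 1.0), (0,), (2, 2),
        expected_code=DiscretizedFunction((0, 1, 2, 2, 2, 2)),
        n_extrema=0, monotone="increasing",
    )
    # Strong M1-M2 plus weak M1-M3: mid-range input frees M3, high input
    # sequesters it again -> biphasic D33.
    c["bump"] = _fx(
        "bump", 3, ((0, 1), (0, 2), (1, 2), (2, 2)), (1e6, 1e2, 1e6, 1e4),
        (1.0, 1.0, 1.0), (0,), (2, 2),
        expected_code=DiscretizedFunction((0, 1, 2, 2, 0, 0)),
        n_extrema=1,
    )
    # The bump's free-M3 phase sequesters M4, inverting the response of D44.
    c["inverted_bump"] = _fx(
        "inverted_bump", 4, ((0, 1), (0, 2), (1, 2), (2, 3), (3, 3)),
        (1e6, 1e2, 1e6, 1e6, 1e4), (1.0, 1.0, 1.0, 1.0), (0,), (3, 3),
        expected_code=DiscretizedFunction((2, 2, 2, 1, 2, 2)),
        n_extrema=1,
    )
    # D13 forms with input M1 unless input M2 outcompetes for M3.
    c["nimply"] = _fx(
        "nimply", 3, ((0, 2), (1, 2)), (1e3, 1e6), (1.0, 1.0, 1.0), (0, 1), (0, 2),
        expected_gate=named_gate("NIMPLY"),
    )
    # Strong D34 survives either single input titrating M3 or M4; both
    # inputs together dismantle it.
    c["nand"] = _fx(
        "nand", 4, ((0, 2), (1, 3), (2, 3)), (1e4, 1e4, 1e7),
        (1.0, 1.0, 10.0, 10.0), (0, 1), (2, 3),
        expected_gate=named_gate("NAND"),
    )
    # Two bump motifs share the output monomer M5: D55 needs both inputs
    # at intermediate levels.
    c["two_input_bump"] = _fx(
        "two_input_bump", 5,
        ((0, 2), (0, 4), (1, 3), (1, 4), (2, 4), (3, 4), (4, 4)),
        (1e6, 1e1, 1e6, 1e1, 1e6, 1e6, 1e6),
        (1.0, 1.0, 1.0, 1.0, 1.0), (0, 1), (4, 4),
        expected_code=DiscretizedFunction(
            (0, 0, 0, 0, 0, 0,
             0, 0, 0, 1, 0, 0,
             0, 0, 0, 2, 1, 0,
             0, 1, 2, 2, 2, 1,
             0, 0, 1, 2, 2, 1,
             0, 0, 0, 1, 1, 0),
            n_inputs=2,
        ),
    )
    # M3-M4 pairing (no inputs) or mutual sequestration (both inputs)
    # leaves M5 free to capture M6; exactly one input frees the other of
    # M3/M4 to occupy M5, releasing M6 into the D66 output.
    c["xor"] = _fx(
        "xor", 6,
        ((0, 2), (1, 3), (2, 3), (2, 4), (3, 4), (4, 5), (5, 5)),
        (1e7, 1e7, 1e7, 1e5, 1e5, 10**6.3, 1e3),
        (1.0, 1.0, 10**0.5, 10**0.5, 10**0.25, 10**0.2), (0, 1), (5, 5),
        expected_gate=named_gate("XOR"),
    )
    return c


_CATALOG = None


def _get_catalog() -> dict[str, Fixture]:
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = _catalog()
    return _CATALOG


FIXTURE_NAMES = (
    "switch_off", "switch_on", "bump", "inverted_bump",
    "nimply", "nand", "two_input_bump", "xor",
)


def make_fixture(name: str) -> Fixture:
    """Look up an elementary network by name (see FIXTURE_NAMES)."""
    try:
        return _get_catalog()[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
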