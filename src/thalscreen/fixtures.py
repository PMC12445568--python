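"""Packaged worked example: a 10-patient CBC decision table.

A small hand-checkable table of red-cell parameters, derived columns and
binary carrier labels, on which the full dominance analysis is exact:
every boundary region is empty, the quality of approximation is 1, and
the carrier class's approximations are {x5, x9}.

Column notes (verified by recomputation over all ten rows): ``mi`` is the
Mentzer index MCV/RBC; ``gk`` numerically equals (RBC/HGB) x 100 — the
BTD index — not the Green & King formula, and ``greenking`` equals
MCV^2 x gk; ``msquare`` is MCV^2.  The columns are carried exactly as
given.  All twelve condition criteria use the gain direction: that is the
convention under which the table is dominance-consistent.
"""

from __future__ import annotations

import pandas as pd

from .dominance import Criterion, DecisionTable

__all__ = [
    "WORKED_EXAMPLE_CRITERIA",
    "worked_example_frame",
    "fixture_worked_example",
]

_ROWS = [
    # id,   rbc,  hgb, hct, mcv, msquare, mch, mchc, rdwcv, mi,       gk,       greenking, rdwi,     decision
    ("x1", 3.87, 10.4, 32, 83, 6889, 27, 32, 14, 21.44703, 37.21154, 256350.3, 300.2584, 0),
    ("x2", 4.53, 6.3, 23, 51, 2601, 14, 27, 23, 11.25828, 71.90476, 187024.3, 258.9404, 0),
    ("x3", 4.14, 9.1, 29, 71, 5041, 22, 31, 19, 17.14976, 45.49451, 229337.8, 325.8454, 0),
    ("x4", 4.01, 11.0, 34, 84, 7056, 28, 33, 17, 20.94763, 36.45455, 257223.3, 356.1097, 0),
    ("x5", 3.42, 7.4, 24, 69, 4761, 22, 31, 17, 20.17544, 46.21622, 220035.4, 342.9825, 1),
    ("x6", 4.06, 10.5, 32, 78, 6084, 26, 33, 17, 19.21182, 38.66667, 235248.0, 326.6010, 0),
    ("x7", 4.75, 10.9, 34, 71, 5041, 23, 33, 16, 14.94737, 43.57798, 219676.6, 239.1579, 0),
    ("x8", 4.19, 5.4, 23, 55, 3025, 13, 24, 24, 13.12649, 77.59259, 234717.6, 315.0358, 0),
    ("x9", 5.46, 10.9, 34, 62, 3844, 20, 32, 16, 11.35531, 50.09174, 192552.7, 181.6850, 1),
    ("x10", 3.80, 10.2, 32, 83, 6889, 27, 33, 20, 21.84211, 37.25490, 256649.0, 436.8421, 0),
]

_COLUMNS = [
    "rbc", "hgb", "hct", "mcv", "msquare", "mch", "mchc", "rdwcv",
    "mi", "gk", "greenking", "rdwi",
]

WORKED_EXAMPLE_CRITERIA = [Criterion(name, "gain") for name in _COLUMNS]


def worked_example_frame() -> pd.DataFrame:
    """The ten patients as a DataFrame indexed by patient id."""
    frame = pd.DataFrame(
        [row[1:] for row in _ROWS],
        columns=_COLUMNS + ["decision"],
        index=pd.Index([row[0] for row in _ROWS], name="patient_id"),
    )
    return frame


def fixture_worked_example() -> DecisionTable:
    """The worked example as a ready-to-analyze DecisionTable."""
    return DecisionTable(
        worked_example_frame(),
        WORKED_EXAMPLE_CRITERIA,
        decision_col="decision",
        class_order=(0, 1),
    )
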