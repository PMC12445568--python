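"""Hematological discrimination indices for thalassemia-trait screening.

A complete blood count (CBC) alone cannot confirm beta-thalassemia trait,
but several ratio indices computed from red-cell parameters separate the
microcytic-erythrocytotic carrier profile from iron-deficiency anemia well
enough for first-line screening.  This module implements the classical
indices (Mentzer, Green & King, MCHD, RDWI, Ricerca) together with the
red-cell/hemoglobin ratio index BTD = (RBC / HGB) x 100, and the published
carrier-suggestive ranges for each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import pandas as pd

__all__ = [
    "CBCRecord",
    "IndexPanel",
    "CARRIER_RANGES",
    "compute_mentzer",
    "compute_gki",
    "compute_mchd",
    "compute_rdwi",
    "compute_ricerca",
    "compute_btd",
    "compute_panel",
    "index_flags",
    "add_index_columns",
]

#: Carrier-suggestive ranges, one (comparison, threshold) pair per index.
#: The carrier interval is closed at the printed bound; its complement is
#: the non-carrier range, so the two partition the line.
CARRIER_RANGES: dict[str, tuple[str, float]] = {
    "mi": ("<=", 13.0),
    "gki": ("<=", 65.0),
    "mchd": (">", 0.35),
    "rdwi": ("<=", 220.0),
    "ri": (">", 4.4),
}

_PERCENT_FIELDS = ("lymp", "midp", "neutp", "hct", "rdwcv", "pct")


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class CBCRecord:
    """One patient's CBC panel, optionally labeled with a carrier class.

    Units follow standard hematology-analyzer output: counts in 10^3/uL
    (WBC, PLT) or 10^6/uL (RBC), hemoglobin-family measures in g/dL or pg,
    volumes in fL, and percentage fields in percent.  ``decision`` is 0
    (non-carrier) or 1 (carrier) when known.
    """

    patient_id: str
    wbc: float
    lymp: float
    lymn: float
    midp: float
    midn: float
    neutp: float
    neutn: float
    rbc: float
    hgb: float
    hct: float
    mch: float
    mcv: float
    mchc: float
    rdwsd: float
    rdwcv: float
    plt: float
    pct: float
    plcr: float
    decision: Optional[int] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("patient_id", "decision"):
                continue
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(
                    f"CBC field {f.name!r} must be strictly positive, got {value!r}"
                )
        for name in _PERCENT_FIELDS:
            value = getattr(self, name)
            if not 0 < value <= 100:
                raise ValueError(
                    f"CBC percentage field {name!r} must lie in (0, 100], got {value!r}"
                )
        if self.decision is not None and self.decision not in (0, 1):
            raise ValueError(f"decision must be 0 or 1, got {self.decision!r}")


@dataclass
class IndexPanel:
    """The six discrimination indices for one record, with carrier flags."""

    mi: float
    gki: float
    mchd: float
    rdwi: float
    ri: float
    btd: float
    flags: dict[str, bool] = field(default_factory=dict)


def compute_mentzer(mcv: float, rbc: float) -> float:
    """Mentzer index MCV / RBC; <= 13 suggests thalassemia trait."""
    _require_positive(mcv=mcv, rbc=rbc)
    return mcv / rbc


def compute_gki(mcv: float, rdw: float, hgb: float) -> float:
    """Green & King index MCV^2 x RDW / (Hb x 100); <= 65 suggests carrier.

    ``rdw`` is the coefficient-of-variation RDW in percent.
    """
    _require_positive(mcv=mcv, rdw=rdw, hgb=hgb)
    return mcv * mcv * rdw / (hgb * 100.0)


def compute_mchd(mch: float, mcv: float) -> float:
    """MCH / MCV ratio; > 0.35 suggests carrier."""
    _require_positive(mch=mch, mcv=mcv)
    return mch / mcv


def compute_rdwi(mcv: float, rdwcv: float, rbc: float) -> float:
    """Red cell distribution width index MCV x RDW / RBC; <= 220 suggests carrier."""
    _require_positive(mcv=mcv, rdwcv=rdwcv, rbc=rbc)
    return mcv * rdwcv / rbc


def compute_ricerca(rdwcv: float, rbc: float) -> float:
    """Ricerca index RDW / RBC; > 4.4 suggests carrier."""
    _require_positive(rdwcv=rdwcv, rbc=rbc)
    return rdwcv / rbc


def compute_btd(rbc: float, hgb: float) -> float:
    """Beta-thalassemia detector index (RBC / HGB) x 100.

    Carriers keep a near-normal red-cell count while hemoglobin falls, so
    the ratio rises relative to both normals and iron deficiency.
    """
    _require_positive(rbc=rbc, hgb=hgb)
    return rbc / hgb * 100.0


def index_flags(panel: IndexPanel) -> dict[str, bool]:
    """Per-index carrier flags from the published screening ranges.

    Each flag is True iff the index value falls in the carrier-suggestive
    interval (MI <= 13, GKI <= 65, MCHD > 0.35, RDWI <= 220, RI > 4.4);
    bounds are inclusive exactly as printed.  BTD has no published cut-off
    and carries no flag.
    """
    flags = {}
    for name, (op, threshold) in CARRIER_RANGES.items():
        value = getattr(panel, name)
        flags[name] = value <= threshold if op == "<=" else value > threshold
    return flags


def compute_panel(record: CBCRecord) -> IndexPanel:
    """All six indices plus carrier flags for one CBC record."""
    panel = IndexPanel(
        mi=compute_mentzer(record.mcv, record.rbc),
        gki=compute_gki(record.mcv, record.rdwcv, record.hgb),
        mchd=compute_mchd(record.mch, record.mcv),
        rdwi=compute_rdwi(record.mcv, record.rdwcv, record.rbc),
        ri=compute_ricerca(record.rdwcv, record.rbc),
        btd=compute_btd(record.rbc, record.hgb),
    )
    panel.flags = index_flags(panel)
    return panel


def add_index_columns(frame: pd.DataFrame, flags: bool = False) -> pd.DataFrame:
    """Append index columns (MI, GKI, MCHD, RDWI, RI, BTD) to a CBC table.

    Expects lower-case column names ``rbc, hgb, mch, mcv, rdwcv``; values are
    kept at full floating precision (printed-precision rounding belongs in
    reports, not in data that feeds dominance comparisons).  With
    ``flags=True`` boolean ``<index>_carrier`` columns are appended too.
    """
    required = {"rbc", "hgb", "mch", "mcv", "rdwcv"}
    missing = required - set(frame.columns)
    if missing:
        raise KeyError(f"CBC table missing columns: {sorted(missing)}")
    bad = frame[list(required)].le(0).any()
    if bad.any():
        raise ValueError(
            f"non-positive values in columns: {list(bad[bad].index)}"
        )
    out = frame.copy()
    out["mi"] = out["mcv"] / out["rbc"]
    out["gki"] = out["mcv"] ** 2 * out["rdwcv"] / (out["hgb"] * 100.0)
    out["mchd"] = out["mch"] / out["mcv"]
    out["rdwi"] = out["mcv"] * out["rdwcv"] / out["rbc"]
    out["ri"] = out["rdwcv"] / out["rbc"]
    out["btd"] = out["rbc"] / out["hgb"] * 100.0
    if flags:
        for name, (op, threshold) in CARRIER_RANGES.items():
            col = out[name] <= threshold if op == "<=" else out[name] > threshold
            out[f"{name}_carrier"] = col
    return out
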