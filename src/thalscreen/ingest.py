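"""Reading raw CBC exports, cleaning, and decision-table construction.

Laboratory CBC exports arrive with free-text hematologist remarks and a
patient-demographics block.  Cleaning turns such an export into a labeled
analysis table by a fixed, auditable sequence of rules (first matching
rule wins):

1. drop records missing a critical parameter (RBC or HGB);
2. drop records with no remark at all;
3. drop records the lab marked inconclusive;
4. drop records whose remark matches the ambiguity lexicon (or is not in
   the lexicon at all — unknown wording is treated as ambiguous);
5. map the remaining remarks to classes (e.g. "NOT DETECTED" -> 0,
   "...CARRIER..." -> 1), then drop exact duplicates and the age/gender
   columns.

Every drop is attributed to exactly one rule and counted, so the
resulting :class:`CleaningReport` reconciles with row arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .dominance import Criterion, DecisionTable
from .indices import add_index_columns

__all__ = [
    "RemarkLexicon",
    "CleaningReport",
    "normalize_columns",
    "read_cbc_csv",
    "clean",
    "build_decision_table",
    "load_decision_table",
]

_SYNONYMS = {
    "patientid": "patient_id",
    "patient": "patient_id",
    "hb": "hgb",
    "hemoglobin": "hgb",
    "hemoglobinlevel": "hgb",
    "hemoglobinlevelgdl": "hgb",
    "rdwcv": "rdwcv",
    "rdwsd": "rdwsd",
    "rbccount": "rbc",
    "plateletcount": "plt",
}

_CRITICAL = ("rbc", "hgb")
_DEMOGRAPHICS = ("age", "gender", "sex")


@dataclass(frozen=True)
class RemarkLexicon:
    """Configurable phrase lists for remark standardization.

    Matching is case-insensitive substring matching; common lab-report
    phrasing is the default, and anything outside the lexicon counts as
    ambiguous.
    """

    normal: tuple[str, ...] = ("NOT DETECTED", "NO ABNORMALITY")
    carrier: tuple[str, ...] = ("CARRIER", "THALASSEMIA TRAIT", "DETECTED")
    inconclusive: tuple[str, ...] = ("INCONCLUSIVE",)
    ambiguous: tuple[str, ...] = ("BORDERLINE", "UNCERTAIN")


@dataclass
class CleaningReport:
    """Per-rule drop counts plus retained counts per class."""

    input_rows: int = 0
    dropped: dict = field(
        default_factory=lambda: {
            "missing_critical": 0,
            "missing_remarks": 0,
            "inconclusive": 0,
            "ambiguous_remarks": 0,
            "duplicates": 0,
        }
    )
    retained: dict = field(default_factory=lambda: {0: 0, 1: 0})

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())

    @property
    def total_retained(self) -> int:
        return sum(self.retained.values())

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "dropped": dict(self.dropped),
            "retained": {str(k): v for k, v in self.retained.items()},
        }


def normalize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Lower-case, squeeze out spaces/punctuation, and map known synonyms."""
    def norm(name: str) -> str:
        key = re.sub(r"[^a-z0-9]", "", str(name).lower())
        return _SYNONYMS.get(key, key)

    out = frame.copy()
    out.columns = [norm(c) for c in frame.columns]
    return out


def read_cbc_csv(path, index_col: Optional[str] = "patient_id") -> pd.DataFrame:
    """Read a CBC CSV with normalized column names."""
    frame = normalize_columns(pd.read_csv(path))
    if index_col and index_col in frame.columns:
        frame = frame.set_index(index_col)
    return frame


def _classify_remark(remark: str, lexicon: RemarkLexicon) -> Optional[int]:
    upper = remark.upper()
    # normal phrases first: "NOT DETECTED" must not match carrier "DETECTED"
    if any(p in upper for p in lexicon.normal):
        return 0
    if any(p in upper for p in lexicon.carrier):
        return 1
    return None


def clean(
    raw: pd.DataFrame, lexicon: RemarkLexicon = RemarkLexicon()
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the cleaning rules; returns (clean table, report).

    Accepts either a raw export (with a ``remarks`` column) or an
    already-clean table (with a ``decision`` column), so cleaning is
    idempotent.
    """
    frame = normalize_columns(raw)
    report = CleaningReport(input_rows=len(frame))
    has_remarks = "remarks" in frame.columns
    if not has_remarks and "decision" not in frame.columns:
        raise KeyError("expected a 'remarks' (raw) or 'decision' (clean) column")
    missing_cols = [c for c in _CRITICAL if c not in frame.columns]
    if missing_cols:
        raise KeyError(f"required CBC columns missing: {missing_cols}")

    keep_rows = []
    decisions = []
    for _, row in frame.iterrows():
        if any(pd.isna(row[c]) for c in _CRITICAL):
            report.dropped["missing_critical"] += 1
            continue
        if has_remarks:
            remark = row["remarks"]
            if pd.isna(remark) or not str(remark).strip():
                report.dropped["missing_remarks"] += 1
                continue
            remark = str(remark)
            upper = remark.upper()
            if any(p in upper for p in lexicon.inconclusive):
                report.dropped["inconclusive"] += 1
                continue
            if any(p in upper for p in lexicon.ambiguous):
                report.dropped["ambiguous_remarks"] += 1
                continue
            decision = _classify_remark(remark, lexicon)
            if decision is None:  # unknown wording: conservatively ambiguous
                report.dropped["ambiguous_remarks"] += 1
                continue
        else:
            decision = int(row["decision"])
        keep_rows.append(row.name)
        decisions.append(decision)

    out = frame.loc[keep_rows].copy()
    out["decision"] = decisions
    drop_cols = [c for c in out.columns if c in _DEMOGRAPHICS or c == "remarks"]
    out = out.drop(columns=drop_cols)

    duplicated = out.duplicated(keep="first")
    report.dropped["duplicates"] = int(duplicated.sum())
    out = out[~duplicated]

    counts = out["decision"].value_counts()
    report.retained = {0: int(counts.get(0, 0)), 1: int(counts.get(1, 0))}
    assert report.total_dropped + report.total_retained == report.input_rows
    return out, report


def build_decision_table(
    table: pd.DataFrame,
    directions: Mapping[str, str],
    criteria: Optional[Sequence[str]] = None,
    with_indices: bool = False,
    class_order: Sequence = (0, 1),
) -> DecisionTable:
    """Build a DecisionTable from a clean CBC table.

    ``directions`` must declare gain/cost for every selected criterion.
    With ``with_indices=True`` the discrimination-index columns (MI, GKI,
    MCHD, RDWI, RI, BTD) are appended before selection.
    """
    frame = table.copy()
    if with_indices:
        decision = frame["decision"]
        frame = add_index_columns(frame.drop(columns=["decision"]))
        frame["decision"] = decision
    names = list(criteria) if criteria is not None else [
        c for c in frame.columns if c != "decision"
    ]
    undeclared = [n for n in names if n not in directions]
    if undeclared:
        raise KeyError(
            f"preference direction not declared for criteria: {undeclared}"
        )
    crits = [Criterion(n, directions[n]) for n in names]
    return DecisionTable(frame, crits, decision_col="decision", class_order=class_order)


def load_decision_table(csv_path, yaml_path) -> DecisionTable:
    """Decision-table CSV plus sidecar YAML with directions and class order.

    The YAML document carries ``directions: {name: gain|cost}`` and an
    optional ``class_order`` (default ``[0, 1]``).
    """
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    frame = read_cbc_csv(csv_path)
    return build_decision_table(
        frame,
        directions=meta["directions"],
        criteria=list(meta["directions"]),
        class_order=meta.get("class_order", (0, 1)),
    )
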