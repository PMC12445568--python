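"""Synthetic labeled CBC datasets with the statistical structure the
screening analysis assumes.

The generator emulates a screening-lab population with roughly 17%
beta-thalassemia-carrier prevalence.  Carriers follow the classical trait
profile — microcytosis (low MCV), relatively elevated red-cell count, and
mildly reduced hemoglobin — so that the published index ranges (e.g.
Mentzer <= 13) mostly but not perfectly separate the classes.  Red-cell
aggregates (HCT, MCH, MCHC) are derived from the simulated RBC/HGB/MCV so
records stay internally coherent; white-cell and platelet parameters are
class-independent reference-range draws.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the config (PCG64, pinned), so a fixed seed reproduces the
dataset bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .rules import RuleSet
from .classifier import classify

__all__ = [
    "SimulationConfig",
    "CLASS_CONDITIONAL_DEFAULTS",
    "SHARED_DEFAULTS",
    "generate_dataset",
    "inject_inconsistency",
    "planted_rule_labels",
]

#: (mean, sd, lower, upper) truncated-normal parameters per class for the
#: red-cell attributes that carry the carrier signal.  MCV in fL, RBC in
#: 10^6/uL, HGB in g/dL.
CLASS_CONDITIONAL_DEFAULTS: dict[str, dict[int, tuple[float, float, float, float]]] = {
    "mcv": {1: (63.0, 5.0, 50.0, 78.0), 0: (88.0, 6.0, 76.0, 102.0)},
    "rbc": {1: (5.5, 0.6, 4.2, 7.2), 0: (4.7, 0.5, 3.6, 6.0)},
    "hgb": {1: (10.5, 1.2, 7.5, 13.5), 0: (13.5, 1.3, 10.5, 17.0)},
}

#: Class-independent reference-range draws for the remaining parameters.
SHARED_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "wbc": (7.5, 2.0, 3.0, 13.5),
    "rdwcv": (14.2, 1.6, 10.8, 19.5),
    "rdwsd": (42.0, 4.0, 33.0, 58.0),
    "lymp": (32.0, 7.0, 12.0, 55.0),
    "midp": (7.0, 2.5, 2.0, 14.0),
    "plt": (280.0, 70.0, 140.0, 480.0),
    "pct": (0.25, 0.05, 0.10, 0.45),
    "plcr": (26.0, 6.0, 11.0, 45.0),
}

_COLUMNS = [
    "wbc", "lymp", "lymn", "midp", "midn", "neutp", "neutn",
    "rbc", "hgb", "hct", "mch", "mcv", "mchc",
    "rdwsd", "rdwcv", "plt", "pct", "plcr",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic CBC generator.

    ``overlap_noise`` is the fraction of records whose attribute values are
    drawn from the *other* class's distributions while keeping their own
    label — the simple mechanism that produces dominance inconsistencies.
    ``planted_rules`` optionally relabels every record by a known rule set
    so rule-recovery is testable against ground truth.
    """

    n: int = 1000
    carrier_prob: float = 0.17
    overlap_noise: float = 0.0
    seed: int = 0
    class_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in CLASS_CONDITIONAL_DEFAULTS.items()}
    )
    shared_params: dict = field(default_factory=lambda: dict(SHARED_DEFAULTS))
    planted_rules: Optional[RuleSet] = None

    def validate(self) -> None:
        problems = []
        if self.n < 0:
            problems.append("n must be >= 0")
        if not 0 < self.carrier_prob < 1:
            problems.append("carrier_prob must lie in (0, 1)")
        if not 0 <= self.overlap_noise < 0.5:
            problems.append("overlap_noise must lie in [0, 0.5)")
        for name, per_class in self.class_params.items():
            for cls, (mean, sd, lo, hi) in per_class.items():
                if not (lo < hi and lo < mean < hi and sd > 0):
                    problems.append(f"class_params[{name!r}][{cls}] invalid: {(mean, sd, lo, hi)}")
        for name, (mean, sd, lo, hi) in self.shared_params.items():
            if not (lo < hi and lo < mean < hi and sd > 0):
                problems.append(f"shared_params[{name!r}] invalid: {(mean, sd, lo, hi)}")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a labeled CBC table.

    Returns a DataFrame indexed by patient id with the 18 CBC columns plus
    a binary ``decision`` column (1 = carrier).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    ids = [f"p{i + 1:05d}" for i in range(n)]
    if n == 0:
        return pd.DataFrame(columns=_COLUMNS + ["decision"], index=pd.Index(ids, name="patient_id"))

    labels = (rng.random(n) < config.carrier_prob).astype(int)
    # overlap: a fraction of records borrow the other class's red-cell profile
    flip = rng.random(n) < config.overlap_noise
    profile = np.where(flip, 1 - labels, labels)

    data = {}
    for name, per_class in config.class_params.items():
        out = np.empty(n)
        for cls in (0, 1):
            idx = np.flatnonzero(profile == cls)
            mean, sd, lo, hi = per_class[cls]
            out[idx] = _truncnorm(rng, mean, sd, lo, hi, idx.size)
        data[name] = out
    for name, (mean, sd, lo, hi) in config.shared_params.items():
        data[name] = _truncnorm(rng, mean, sd, lo, hi, n)

    rbc, hgb, mcv = data["rbc"], data["hgb"], data["mcv"]
    data["hct"] = mcv * rbc / 10.0               # %
    data["mch"] = hgb / rbc * 10.0               # pg
    data["mchc"] = hgb / data["hct"] * 100.0     # g/dL
    # white-cell differential: neutrophils absorb the remainder
    data["neutp"] = 100.0 - data["lymp"] - data["midp"]
    for frac, absolute in (("lymp", "lymn"), ("midp", "midn"), ("neutp", "neutn")):
        data[absolute] = data["wbc"] * data[frac] / 100.0

    frame = pd.DataFrame({c: data[c] for c in _COLUMNS}, index=pd.Index(ids, name="patient_id"))
    frame["decision"] = labels
    if config.planted_rules is not None:
        frame = planted_rule_labels(frame, config.planted_rules)
    return frame


def inject_inconsistency(table: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Clone attribute values across class lines to force gamma < 1.

    ``ceil(fraction * n)`` randomly chosen records get their attribute
    values replaced by those of a random record of the opposite class,
    keeping their own label.  Each clone/source pair then mutually
    dominates with opposite classes, so both fall in every relevant
    boundary region.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    if fraction == 0 or len(table) == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    k = math.ceil(fraction * len(table))
    attr_cols = [c for c in table.columns if c != "decision"]
    targets = rng.choice(len(table), size=k, replace=False)
    labels = table["decision"].to_numpy()
    for pos in targets:
        donors = np.flatnonzero(labels != labels[pos])
        if donors.size == 0:
            raise ValueError("cannot inject inconsistency: only one class present")
        donor = int(rng.choice(donors))
        out.iloc[pos, [out.columns.get_loc(c) for c in attr_cols]] = table.iloc[donor][attr_cols].to_numpy()
    return out


def planted_rule_labels(table: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Relabel a table from a known rule set (ground truth for recovery tests).

    The new label is 1 iff any ``Class >= 1`` rule fires on the row, which
    makes the table perfectly dominance-consistent on the rule's criteria.
    """
    out = table.copy()
    out["decision"] = [
        classify(ruleset, row).predicted_class for _, row in out.iterrows()
    ]
    return out
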