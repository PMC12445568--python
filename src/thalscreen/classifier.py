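"""Rule-based classification of CBC records, sklearn-style.

``DominanceRuleClassifier`` wraps the whole train path (decision table ->
variable-consistency positive regions -> DOMLEM rule induction) behind the
scikit-learn estimator protocol, so it drops into pipelines and model
selection.  The module-level ``classify`` / ``classify_batch`` functions
apply an existing :class:`~thalscreen.rules.RuleSet` directly.

Two-class decision policy: only ``Class >= 1`` rules are consulted; a
record is predicted a carrier iff at least one of them fires, and class 0
is the default conclusion otherwise.  The continuous score used for
ROC/PR evaluation is the maximum training confidence among fired
``Class >= 1`` rules (0 when none fires), which is monotone in the set of
firing rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dominance import DecisionTable, quality_of_approximation
from .rules import AT_LEAST, RuleSet, induce_rules

__all__ = [
    "Prediction",
    "MissingAttributeError",
    "classify",
    "score",
    "classify_batch",
    "DominanceRuleClassifier",
]


class MissingAttributeError(KeyError):
    """A record lacks an attribute required by the rule set."""


@dataclass
class Prediction:
    """One record's predicted class with its explanation."""

    object_id: object
    predicted_class: int
    fired_rules: list[int] = field(default_factory=list)
    score: float = 0.0


def _fired_at_least(ruleset: RuleSet, record: Mapping) -> list[int]:
    fired = []
    for i, rule in enumerate(ruleset.rules):
        if rule.kind != AT_LEAST or rule.t < 1:
            continue
        try:
            ok = rule.fires(record)
        except KeyError as exc:
            raise MissingAttributeError(
                f"record is missing attribute {exc.args[0]!r} required by rule {i}"
            ) from None
        if ok:
            fired.append(i)
    return fired


def classify(ruleset: RuleSet, record: Mapping, object_id=None) -> Prediction:
    """Apply the rule set to one record.

    A rule fires iff all its conditions hold; the record is a carrier
    (class 1) iff some ``Class >= 1`` rule fires.  ``fired_rules`` lists
    every firing rule index, so each prediction is fully auditable.
    """
    fired = _fired_at_least(ruleset, record)
    s = max((ruleset.rules[i].consistency for i in fired), default=0.0)
    return Prediction(
        object_id=object_id,
        predicted_class=1 if fired else 0,
        fired_rules=fired,
        score=float(s),
    )


def score(ruleset: RuleSet, record: Mapping) -> float:
    """Maximum confidence among fired ``Class >= 1`` rules; 0 if none fires."""
    return classify(ruleset, record).score


def classify_batch(
    ruleset: RuleSet, table: pd.DataFrame
) -> tuple[list[Prediction], dict]:
    """One prediction per row plus a summary.

    Rows that cannot be classified (missing attributes) are collected as
    refusals in the summary instead of aborting the batch.
    """
    predictions: list[Prediction] = []
    refusals: list[tuple[object, str]] = []
    for oid, row in table.iterrows():
        try:
            predictions.append(classify(ruleset, row, object_id=oid))
        except MissingAttributeError as exc:
            refusals.append((oid, str(exc)))
    counts = {0: 0, 1: 0}
    for p in predictions:
        counts[p.predicted_class] += 1
    summary = {
        "n": len(table),
        "classified": len(predictions),
        "refused": refusals,
        "counts": counts,
    }
    return predictions, summary


class DominanceRuleClassifier(ClassifierMixin, BaseEstimator):
    """Interpretable carrier screening via dominance rough sets + DOMLEM.

    Parameters
    ----------
    directions : mapping name -> {"gain", "cost"}, or "gain"/"cost"
        Preference direction per criterion.  A single string applies the
        same direction to every feature (the all-gain convention matches
        ordinal CBC decision tables whose columns all point toward the
        carrier class the same way).
    consistency : float in (0, 1], default 1.0
        Variable-consistency threshold l for the positive regions rules
        are induced from; 1.0 is plain DOMLEM on the lower approximations.
    criteria : optional sequence of column names
        Subset of features to induce rules over (e.g. a reduct); default
        all columns.

    Attributes
    ----------
    ruleset_ : RuleSet               induced decision rules
    gamma_ : float                   quality of approximation of the training table
    classes_ : ndarray of [0, 1]
    feature_names_in_ : ndarray      column names seen at fit
    """

    def __init__(
        self,
        directions: Mapping[str, str] | str = "gain",
        consistency: float = 1.0,
        criteria: Optional[Sequence[str]] = None,
    ):
        self.directions = directions
        self.consistency = consistency
        self.criteria = criteria

    def _as_frame(self, X, fitted: bool) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            if fitted:
                frame = pd.DataFrame(arr, columns=list(self.feature_names_in_))
            else:
                frame = pd.DataFrame(
                    arr, columns=[f"f{j}" for j in range(arr.shape[1])]
                )
        if fitted:
            missing = set(self.feature_names_in_) - set(frame.columns)
            if missing:
                raise ValueError(f"X is missing fitted feature columns: {sorted(missing)}")
        return frame

    def fit(self, X, y) -> "DominanceRuleClassifier":
        frame = self._as_frame(X, fitted=False).copy()
        y = np.asarray(y)
        if len(y) != len(frame):
            raise ValueError("X and y lengths differ")
        labels = set(np.unique(y).tolist())
        if not labels <= {0, 1}:
            raise ValueError(f"y must be binary in {{0, 1}}, got classes {sorted(labels)}")
        if not 0 < self.consistency <= 1:
            raise ValueError("consistency must lie in (0, 1]")

        names = list(self.criteria) if self.criteria is not None else list(frame.columns)
        if isinstance(self.directions, str):
            directions = {n: self.directions for n in names}
        else:
            directions = {n: self.directions[n] for n in names}

        data = frame[names].copy()
        data["decision"] = y.astype(int)
        data.index = range(len(data))
        table = DecisionTable(data, directions, decision_col="decision")
        self.table_ = table
        self.gamma_ = quality_of_approximation(table)
        self.ruleset_ = induce_rules(table, names, l=self.consistency)
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-record carrier score in [0, 1] (max fired-rule confidence)."""
        check_is_fitted(self, "ruleset_")
        frame = self._as_frame(X, fitted=True)
        return np.array(
            [classify(self.ruleset_, row).score for _, row in frame.iterrows()]
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "ruleset_")
        frame = self._as_frame(X, fitted=True)
        return np.array(
            [classify(self.ruleset_, row).predicted_class for _, row in frame.iterrows()],
            dtype=int,
        )

    def predict_proba(self, X) -> np.ndarray:
        """Scores folded into two pseudo-probability columns (1 - s, s)."""
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])

    def explain(self, X) -> list[Prediction]:
        """Full predictions with fired-rule lists for each row of X."""
        check_is_fitted(self, "ruleset_")
        frame = self._as_frame(X, fitted=True)
        return classify_batch(self.ruleset_, frame)[0]
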