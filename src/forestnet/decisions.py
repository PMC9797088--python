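"""Decisions and decision ensembles.

A *rule* is a conjunction of at most one condition per feature; a *decision*
pairs a rule with a constant prediction on the rule's sample support.  A tree
ensemble is flattened into a *decision ensemble* with one decision per
root-to-leaf path: the split conditions along each path are intersected
per feature, the support is computed on the training data, and the prediction
and error are recomputed from the support (leaf values are not reused, so
every later rule modification stays under one estimator).

Error functions follow the task: mean residual sum of squares for regression,
and ``mean(1 - ŷ^y (1-ŷ)^(1-y))`` for binary classification, which reduces to
the misclassification fraction when ``ŷ ∈ {0, 1}``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .model_io import REGRESSION, Dataset, TreeEnsembleSpec

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")
POS_INF = float("inf")


# ---------------------------------------------------------------------------
# Conditions and rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """A single-feature condition.

    Numeric: membership in the half-open interval ``[lo, hi)`` (strict-less
    splits generate exactly these).  Categorical / discretized: membership in
    the admitted ``levels`` set (stored sorted for canonical hashing).  A
    ``negated`` condition admits the complement; it is produced only by
    complement decisions.
    """

    feature: str
    lo: float = NEG_INF
    hi: float = POS_INF
    levels: Optional[tuple] = None
    negated: bool = False

    def __post_init__(self):
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(sorted(self.levels)))
            if len(self.levels) == 0:
                raise DataError(f"empty admitted set on {self.feature!r}")
        elif not self.lo < self.hi:
            raise DataError(
                f"empty interval [{self.lo}, {self.hi}) on {self.feature!r}"
            )

    @property
    def is_numeric(self) -> bool:
        return self.levels is None

    def mask(self, data: Dataset) -> np.ndarray:
        if self.is_numeric:
            x = data.numeric(self.feature)
            m = np.ones(data.n, dtype=bool)
            if self.lo > NEG_INF:
                m &= x >= self.lo
            if self.hi < POS_INF:
                m &= x < self.hi
        else:
            order = data.levels(self.feature)
            codes = data.codes(self.feature)
            admitted = np.array(
                [i for i, lab in enumerate(order) if lab in set(self.levels)],
                dtype=np.int32,
            )
            m = np.isin(codes, admitted)
        return ~m if self.negated else m

    def complement(self, data: Dataset) -> "Condition":
        """Complement within the observed domain."""
        if not self.is_numeric:
            rest = tuple(
                lab for lab in data.levels(self.feature)
                if lab not in set(self.levels)
            )
            if not rest:
                raise DataError(
                    f"condition on {self.feature!r} admits the full domain"
                )
            return Condition(self.feature, levels=rest, negated=self.negated)
        if self.lo == NEG_INF:
            return Condition(self.feature, lo=self.hi, negated=self.negated)
        if self.hi == POS_INF:
            return Condition(self.feature, hi=self.lo, negated=self.negated)
        # two-sided interval: complement is a union, represented via negation
        return replace(self, negated=not self.negated)

    def describe(self) -> str:
        if self.is_numeric:
            if self.lo == NEG_INF:
                body = f"{self.feature}<{_fmt(self.hi)}"
            elif self.hi == POS_INF:
                body = f"{self.feature}>={_fmt(self.lo)}"
            else:
                body = f"{self.feature} in [{_fmt(self.lo)},{_fmt(self.hi)})"
        else:
            body = f"{self.feature} in {{{','.join(map(str, self.levels))}}}"
        return f"not({body})" if self.negated else body


def _fmt(x: float) -> str:
    return f"{x:.6g}"


Rule = tuple  # tuple[Condition, ...] sorted by feature name


def make_rule(conditions: Sequence[Condition]) -> Rule:
    """Canonicalize a conjunction: sorted by feature, one condition each."""
    feats = [c.feature for c in conditions]
    if len(feats) != len(set(feats)):
        raise DataError("a rule may hold at most one condition per feature")
    return tuple(sorted(conditions, key=lambda c: c.feature))


def rule_mask(rule: Rule, data: Dataset) -> np.ndarray:
    m = np.ones(data.n, dtype=bool)
    for cond in rule:
        m &= cond.mask(data)
    return m


def rule_to_string(rule: Rule) -> str:
    return " & ".join(c.describe() for c in rule) if rule else "<empty rule>"


# ---------------------------------------------------------------------------
# Error functions and decision evaluation
# ---------------------------------------------------------------------------

def prediction_on(y: np.ndarray, task: str) -> float:
    """The constant prediction for a support: mean response (for
    classification this is the class-1 proportion)."""
    return float(np.mean(y))

def error_on(y: np.ndarray, yhat: float, task: str) -> float:
    """α(S, ŷ) evaluated on the response values of a support S."""
    if len(y) == 0:
        return math.nan
    if task == REGRESSION:
        return float(np.mean((y - yhat) ** 2))
    # 1 - ŷ^y (1-ŷ)^(1-y)  ==  (1-ŷ) where y=1, ŷ where y=0
    return float(np.mean(np.where(y == 1.0, 1.0 - yhat, yhat)))


def evaluate_rule(rule: Rule, data: Dataset):
    """Support mask, data-recomputed prediction, and error of a rule."""
    mask = rule_mask(rule, data)
    if not mask.any():
        return mask, math.nan, math.nan
    ys = data.y[mask]
    pred = prediction_on(ys, data.task)
    return mask, pred, error_on(ys, pred, data.task)


# ---------------------------------------------------------------------------
# Decisions and ensembles
# ---------------------------------------------------------------------------

@dataclass
class Decision:
    """A rule, its data-recomputed prediction, support, and error."""

    rule: Rule
    prediction: float
    error: float
    support: np.ndarray = field(repr=False)  # boolean mask over samples
    n_support: int = 0
    multiplicity: int = 1
    importance: Optional[float] = None
    selection_probability: Optional[float] = None

    def features(self) -> tuple:
        return tuple(c.feature for c in self.rule)

    def condition(self, feature: str) -> Condition:
        for c in self.rule:
            if c.feature == feature:
                return c
        raise DataError(f"feature {feature!r} is not active in this rule")


@dataclass
class DecisionEnsemble:
    """A collection of decisions bound to one dataset and task."""

    decisions: list
    data: Dataset

    @property
    def task(self) -> str:
        return self.data.task

    @property
    def global_mean(self) -> float:
        return self.data.ybar

    def __len__(self) -> int:
        return len(self.decisions)

    def total_multiplicity(self) -> int:
        return sum(d.multiplicity for d in self.decisions)

    def support_matrix(self) -> np.ndarray:
        if not self.decisions:
            return np.zeros((0, self.data.n), dtype=bool)
        return np.stack([d.support for d in self.decisions])

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "rule": rule_to_string(d.rule),
                "prediction": d.prediction,
                "support": d.n_support,
                "error": d.error,
                "multiplicity": d.multiplicity,
                "importance": d.importance,
                "selection_probability": d.selection_probability,
            }
            for d in self.decisions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "rule", "prediction", "support", "error",
                "multiplicity", "importance", "selection_probability",
            ],
        )

    def export_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _intersect_numeric(a: Condition, b: Condition) -> Optional[Condition]:
    lo, hi = max(a.lo, b.lo), min(a.hi, b.hi)
    if not lo < hi:
        return None
    return Condition(a.feature, lo=lo, hi=hi)


def _intersect_categorical(a: Condition, b: Condition) -> Optional[Condition]:
    inter = set(a.levels) & set(b.levels)
    if not inter:
        return None
    return Condition(a.feature, levels=tuple(inter))


def extract_decisions(model: TreeEnsembleSpec, data: Dataset) -> DecisionEnsemble:
    """One decision per root-to-leaf path.

    Conditions along a path are intersected per feature; full-domain
    conditions are dropped; paths whose conditions are contradictory or whose
    support is empty are discarded (count logged).  Predictions and errors are
    recomputed from the data.
    """
    decisions: list = []
    n_dropped = 0
    y = data.y
    task = data.task
    for t, nodes in enumerate(model.trees):
        root = model.root_id(t)
        full = np.ones(data.n, dtype=bool)
        # stack holds (node_id, {feature: Condition}, mask)
        stack = [(root, {}, full)]
        while stack:
            nid, conds, mask = stack.pop()
            node = nodes[nid]
            if node.is_leaf:
                if not mask.any():
                    n_dropped += 1
                    continue
                rule = make_rule(
                    [c for c in conds.values() if not _is_full_domain(c, data)]
                )
                ys = y[mask]
                pred = prediction_on(ys, task)
                decisions.append(
                    Decision(
                        rule=rule,
                        prediction=pred,
                        error=error_on(ys, pred, task),
                        support=mask,
                        n_support=int(mask.sum()),
                    )
                )
                continue
            if node.category_set is not None:
                observed = set(data.levels(node.feature))
                left_levels = set(node.category_set) & observed
                left_cond = (
                    Condition(node.feature, levels=tuple(left_levels))
                    if left_levels
                    else None
                )
                right_levels = observed - set(node.category_set)
                right_cond = (
                    Condition(node.feature, levels=tuple(right_levels))
                    if right_levels
                    else None
                )
            else:
                left_cond = Condition(node.feature, hi=node.threshold)
                right_cond = Condition(node.feature, lo=node.threshold)
            for child, cond in (
                (node.left_child, left_cond),
                (node.right_child, right_cond),
            ):
                if cond is None:
                    n_dropped += 1
                    continue
                prev = conds.get(node.feature)
                if prev is None:
                    merged = cond
                else:
                    merged = (
                        _intersect_numeric(prev, cond)
                        if cond.is_numeric
                        else _intersect_categorical(prev, cond)
                    )
                if merged is None:  # contradictory path
                    n_dropped += 1
                    continue
                new_conds = dict(conds)
                new_conds[node.feature] = merged
                stack.append((child, new_conds, mask & cond.mask(data)))
    if n_dropped:
        logger.info("dropped %d empty/contradictory paths", n_dropped)
    return DecisionEnsemble(decisions=decisions, data=data)


def _is_full_domain(cond: Condition, data: Dataset) -> bool:
    if cond.is_numeric:
        return cond.lo == NEG_INF and cond.hi == POS_INF
    return set(cond.levels) >= set(data.levels(cond.feature))


def decision_from_rule(rule: Rule, data: Dataset,
                       multiplicity: int = 1) -> Optional[Decision]:
    """Build and evaluate a decision; None if its support is empty."""
    mask, pred, err = evaluate_rule(rule, data)
    if not mask.any():
        return None
    return Decision(
        rule=rule,
        prediction=pred,
        error=err,
        support=mask,
        n_support=int(mask.sum()),
        multiplicity=multiplicity,
    )


def group_duplicate_rules(ensemble: DecisionEnsemble) -> DecisionEnsemble:
    """Collapse decisions with identical (canonical) rules.

    Multiplicity adds up; prediction/support/error are those of the shared
    rule (identical rules have identical supports), so Σ multiplicity is
    conserved.
    """
    by_rule: dict = {}
    for d in ensemble.decisions:
        if d.rule in by_rule:
            by_rule[d.rule].multiplicity += d.multiplicity
        else:
            by_rule[d.rule] = replace(d)
    grouped = list(by_rule.values())
    return DecisionEnsemble(decisions=grouped, data=ensemble.data)
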