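"""Fully simulated benchmark data, ground-truth networks, and evaluation.

The generator draws 12 independent N(0.5, 1) predictors ``V1..V12`` and a
group factor uniform over {a, b, c, d}; the binary response follows a fixed
rule table (``FSD_RULES``): e.g. in group b the response is 1 iff ``V3 > 0``,
in group a it is 1 iff V1 and V2 share their sign, in group c only the
same-sign V4/V5 cells are covered and in group d only the opposite-sign
V6/V7 cells.  Cells not covered by any rule receive a uniform ±1 label
(pure noise), every label's sign is then flipped independently with
probability ``r``, and ±1 is re-encoded as {0, 1} with 1 the positive class.

From the rule table a ground-truth association network is derived
(11 nodes, 10 edges for the default table), against which predicted decision
networks are scored by TP/FP/FN counts, precision, recall, and
importance-weighted precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .decisions import (
    Condition,
    DecisionEnsemble,
    decision_from_rule,
    make_rule,
)
from .errors import ConfigError, DataError
from .model_io import (
    CLASSIFICATION,
    Dataset,
    TreeEnsembleSpec,
    fold_one_hot,
    from_sklearn_forest,
    make_dataset,
)
from .network import DecisionNetwork, build_network
from .regularize import StableEnsemble

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, DEPENDS = 1, -1, 0


@dataclass(frozen=True)
class GeneratingRule:
    group: str
    conditions: tuple  # ((var, op, threshold), ...) with op in {">", "<="}
    response: int      # -1 or 1

    def matches(self, groups: np.ndarray, V: Mapping[str, np.ndarray]) -> np.ndarray:
        m = groups == self.group
        for var, op, thr in self.conditions:
            m = m & (V[var] > thr if op == ">" else V[var] <= thr)
        return m


@dataclass
class GeneratingRuleTable:
    rows: list

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def variables(self) -> list:
        seen = []
        for rule in self.rows:
            for var, _, _ in rule.conditions:
                if var not in seen:
                    seen.append(var)
        return seen


#: the default generating rules: response 1/-1 per group-specific conditions
FSD_RULES = GeneratingRuleTable(
    rows=[
        GeneratingRule("a", (("V1", ">", 0.0), ("V2", ">", 0.0)), 1),
        GeneratingRule("a", (("V1", "<=", 0.0), ("V2", "<=", 0.0)), 1),
        GeneratingRule("a", (("V1", ">", 0.0), ("V2", "<=", 0.0)), -1),
        GeneratingRule("a", (("V1", "<=", 0.0), ("V2", ">", 0.0)), -1),
        GeneratingRule("b", (("V3", ">", 0.0),), 1),
        GeneratingRule("b", (("V3", "<=", 0.0),), -1),
        GeneratingRule("c", (("V4", ">", 0.0), ("V5", ">", 0.0)), 1),
        GeneratingRule("c", (("V4", "<=", 0.0), ("V5", "<=", 0.0)), -1),
        GeneratingRule("d", (("V6", "<=", 0.0), ("V7", ">", 0.0)), -1),
        GeneratingRule("d", (("V6", ">", 0.0), ("V7", "<=", 0.0)), 1),
    ]
)

GROUP_FEATURE = "group"
GROUP_LEVELS = ("a", "b", "c", "d")
N_NUMERIC = 12


@dataclass
class GroundTruthNetwork:
    """True nodes/edges with expected association signs.

    Node labels are variable names (``V3``) or group levels (``group=a``);
    signs are +1 (high values / membership predict the positive class),
    −1, or 0 ("depends").
    """

    nodes: dict  # label -> sign
    edges: dict  # frozenset({label, label}) -> sign

    def node_labels(self) -> set:
        return set(self.nodes)

    def edge_pairs(self) -> set:
        return set(self.edges)

    def to_frames(self):
        nodes = pd.DataFrame(
            [{"node": k, "sign": v} for k, v in sorted(self.nodes.items())]
        )
        edges = pd.DataFrame(
            [
                {"node_a": min(e), "node_b": max(e), "sign": s}
                for e, s in sorted(self.edges.items(), key=lambda kv: sorted(kv[0]))
            ]
        )
        return nodes, edges


def simulate_fsd(n: int, r: float, seed: int = 0):
    """Draw one fully simulated dataset; returns ``(Dataset, truth network)``.

    Reproducible: the random stream (predictors → groups → noise labels →
    sign flips) is fixed, so identical seeds give identical datasets and the
    covered-cell labels of an ``r=1`` run are exactly the flips of ``r=0``.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if not 0.0 <= r <= 1.0:
        raise ConfigError("r must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    V = {
        f"V{i + 1}": rng.normal(0.5, 1.0, size=n) for i in range(N_NUMERIC)
    }
    groups = rng.choice(np.array(GROUP_LEVELS, dtype=object), size=n)
    noise_labels = rng.choice(np.array([-1, 1]), size=n)
    flips = rng.random(n) < r

    y = np.zeros(n, dtype=np.int64)
    covered = np.zeros(n, dtype=bool)
    for rule in FSD_RULES:
        m = rule.matches(groups, V)
        y[m] = rule.response
        covered |= m
    y[~covered] = noise_labels[~covered]
    y = np.where(flips, -y, y)
    y01 = (y + 1) // 2

    X = pd.DataFrame({k: V[k] for k in sorted(V, key=lambda s: int(s[1:]))})
    X[GROUP_FEATURE] = pd.Categorical(groups, categories=list(GROUP_LEVELS))
    data = make_dataset(X, y01.astype(np.float64), CLASSIFICATION)
    return data, ground_truth_network(FSD_RULES)


def ground_truth_network(rules: GeneratingRuleTable) -> GroundTruthNetwork:
    """Derive the true association network from a generating rule table.

    One node per variable and per group level used by the rules; one edge
    per pair co-occurring in a rule.  A variable's sign is positive if its
    high side predicts the positive class in every rule it enters, negative
    if it always predicts the negative class, "depends" otherwise; group
    levels and edges follow the responses of their rules the same way.
    """
    node_votes: dict = {}
    edge_votes: dict = {}

    def vote(store, key, sign):
        store.setdefault(key, set()).add(sign)

    for rule in rules:
        glabel = f"{GROUP_FEATURE}={rule.group}"
        vote(node_votes, glabel, rule.response)
        members = [glabel]
        for var, op, _ in rule.conditions:
            # orientation of the variable's high side within this rule
            vote(node_votes, var, rule.response if op == ">" else -rule.response)
            members.append(var)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                vote(edge_votes, frozenset((members[i], members[j])), rule.response)

    def resolve(signs: set) -> int:
        if signs == {1}:
            return POSITIVE
        if signs == {-1}:
            return NEGATIVE
        return DEPENDS

    return GroundTruthNetwork(
        nodes={k: resolve(v) for k, v in node_votes.items()},
        edges={k: resolve(v) for k, v in edge_votes.items()},
    )


def perfect_ensemble(rules: GeneratingRuleTable, data: Dataset) -> DecisionEnsemble:
    """One decision per generating rule, evaluated on the data.

    This bypasses any fitted learner: the metric/network pipeline applied to
    these decisions should reproduce the ground-truth network exactly (up to
    the label noise).  Rules with empty support are dropped with a log line.
    """
    decisions = []
    n_dropped = 0
    for rule in rules:
        conds = [Condition(GROUP_FEATURE, levels=(rule.group,))]
        for var, op, thr in rule.conditions:
            if op == ">":
                conds.append(Condition(var, lo=thr))
            else:
                conds.append(Condition(var, hi=thr))
        d = decision_from_rule(make_rule(conds), data)
        if d is None:
            n_dropped += 1
            continue
        decisions.append(d)
    if n_dropped:
        logger.info("perfect ensemble: %d rules with empty support", n_dropped)
    return DecisionEnsemble(decisions=decisions, data=data)


def permute_response(
    data: Dataset, within: Optional[str] = None, seed: int = 0
) -> Dataset:
    """Permute the response (optionally within strata of a categorical
    feature); the feature table is untouched."""
    rng = np.random.default_rng(seed)
    y = data.y.copy()
    if within is None:
        y = y[rng.permutation(data.n)]
    else:
        if data.is_numeric(within):
            raise DataError(f"stratum feature {within!r} must be categorical")
        codes = data.codes(within)
        for c in np.unique(codes):
            idx = np.flatnonzero(codes == c)
            y[idx] = y[idx[rng.permutation(len(idx))]]
    return data.replace_y(y)


# ---------------------------------------------------------------------------
# Forest-fitting harness (used by the evaluation workflow and the CLI)
# ---------------------------------------------------------------------------

def fit_forest(
    data: Dataset,
    n_trees: int = 500,
    max_depth: int = 4,
    min_samples_leaf: int = 5,
    max_features: object = 0.5,
    seed: int = 0,
) -> TreeEnsembleSpec:
    """Fit a random forest on a Dataset and return its node-table spec.

    Categorical features are one-hot encoded for scikit-learn and the dummy
    splits folded back into category-set conditions on the parent factor.
    The default ``max_features=0.5`` widens the per-split candidate set to
    compensate for the dilution of a factor across its one-hot dummies
    (factor-aware learners treat the factor as a single candidate with a
    subset split).
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    cols = []
    names = []
    encoding = {}
    domains = {}
    for feat in data.feature_names:
        if data.is_numeric(feat):
            cols.append(data.numeric(feat))
            names.append(feat)
        else:
            levels = data.levels(feat)
            domains[feat] = levels
            codes = data.codes(feat)
            for i, lvl in enumerate(levels):
                dummy = f"{feat}={lvl}"
                cols.append((codes == i).astype(np.float64))
                names.append(dummy)
                encoding[dummy] = (feat, lvl)
    Xmat = np.column_stack(cols)
    cls = (
        RandomForestClassifier
        if data.task == CLASSIFICATION
        else RandomForestRegressor
    )
    forest = cls(
        n_estimators=n_trees,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(Xmat, data.y)
    spec = from_sklearn_forest(forest, names, task=data.task)
    if encoding:
        spec = fold_one_hot(spec, encoding, domains)
    return spec


# ---------------------------------------------------------------------------
# Scoring against the ground truth
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """TP/FP/FN counts and (weighted) precision/recall, nodes and edges."""

    node_tp: int
    node_fp: int
    node_fn: int
    node_precision: Optional[float]
    node_recall: float
    node_weighted_precision: Optional[float]
    edge_tp: int
    edge_fp: int
    edge_fn: int
    edge_precision: Optional[float]
    edge_recall: float
    edge_weighted_precision: Optional[float]
    matched_nodes: set = field(default_factory=set)
    matched_edges: set = field(default_factory=set)
    sign_matches: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind in ("node", "edge"):
            rows.append(
                {
                    "kind": kind,
                    "tp": getattr(self, f"{kind}_tp"),
                    "fp": getattr(self, f"{kind}_fp"),
                    "fn": getattr(self, f"{kind}_fn"),
                    "precision": getattr(self, f"{kind}_precision"),
                    "recall": getattr(self, f"{kind}_recall"),
                    "weighted_precision": getattr(
                        self, f"{kind}_weighted_precision"
                    ),
                }
            )
        return pd.DataFrame(rows)


def _node_entities(net: DecisionNetwork, alias_map) -> dict:
    """Collapse level-set nodes to distinct variable-level entities.

    Numeric/discretized nodes collapse to their feature; categorical nodes
    expand to one label per admitted level (a node "corresponds to each
    possible value" of the factor).  Labels produced by several network
    nodes merge: importance adds up, influence is importance-weighted.
    Returns ``{label: (importance, influence)}``.
    """
    acc: dict = {}
    for node, attrs in net.graph.nodes(data=True):
        labels = str(attrs.get("entities", node)).split("|")
        imp = float(attrs.get("importance", 0.0))
        infl = float(attrs.get("influence", 0.0))
        for lab in labels:
            lab = alias_map.get(lab, lab)
            i0, w0 = acc.get(lab, (0.0, 0.0))
            acc[lab] = (i0 + imp, w0 + infl * imp)
    return {
        lab: (imp, (wi / imp if imp != 0 else 0.0))
        for lab, (imp, wi) in acc.items()
    }


def _edge_entities(net: DecisionNetwork, alias_map) -> dict:
    """Collapse edges to distinct variable-level pairs (importance summed)."""
    acc: dict = {}
    for a, b, attrs in net.graph.edges(data=True):
        la = str(net.graph.nodes[a].get("entities", a)).split("|")
        lb = str(net.graph.nodes[b].get("entities", b)).split("|")
        imp = float(attrs.get("importance", 0.0))
        for x in la:
            x = alias_map.get(x, x)
            for y in lb:
                y = alias_map.get(y, y)
                if x == y:
                    continue
                key = frozenset((x, y))
                acc[key] = acc.get(key, 0.0) + imp
    return acc


def evaluate_network(
    predicted: DecisionNetwork,
    truth: GroundTruthNetwork,
    alias_map: Optional[Mapping[str, str]] = None,
    feature_influence: Optional[Mapping[str, float]] = None,
) -> EvalResult:
    """Score a predicted network against the ground truth.

    Predicted level-set nodes are collapsed to variables (group levels keep
    their level identity) before matching; ``alias_map`` optionally renames
    predicted labels onto truth labels, with each truth entity creditable
    once.  TPs and FPs are additionally weighted by importance to give the
    weighted precision.  If ``feature_influence`` (variable-level Γ) is
    given, signs of matched non-"depends" truth nodes are checked against it.
    """
    alias_map = dict(alias_map or {})

    # ---- nodes
    node_units = _node_entities(predicted, alias_map)
    credited = {l for l in node_units if l in truth.nodes}
    node_tp = len(credited)
    node_fp = len(node_units) - node_tp
    node_fn = len(truth.nodes) - node_tp
    tot_imp = sum(imp for imp, _ in node_units.values())
    node_precision = (
        node_tp / (node_tp + node_fp) if node_units else None
    )
    node_recall = node_tp / len(truth.nodes) if truth.nodes else 0.0
    node_wprec = (
        sum(node_units[l][0] for l in credited) / tot_imp
        if tot_imp > 0
        else None
    )

    # ---- edges
    edge_units = _edge_entities(predicted, alias_map)
    credited_e = {p for p in edge_units if p in truth.edges}
    edge_tp = len(credited_e)
    edge_fp = len(edge_units) - edge_tp
    edge_fn = len(truth.edges) - edge_tp
    tot_eimp = sum(edge_units.values())
    edge_precision = (
        edge_tp / (edge_tp + edge_fp) if edge_units else None
    )
    edge_recall = edge_tp / len(truth.edges) if truth.edges else 0.0
    edge_wprec = (
        sum(edge_units[p] for p in credited_e) / tot_eimp
        if tot_eimp > 0
        else None
    )

    # ---- signs of matched, non-"depends" truth nodes
    sign_matches: dict = {}
    for label in credited:
        want = truth.nodes[label]
        if want == DEPENDS:
            continue
        got = _predicted_node_sign(label, node_units, feature_influence)
        if got is not None:
            sign_matches[label] = int(np.sign(got)) == want

    return EvalResult(
        node_tp=node_tp,
        node_fp=node_fp,
        node_fn=node_fn,
        node_precision=node_precision,
        node_recall=node_recall,
        node_weighted_precision=node_wprec,
        edge_tp=edge_tp,
        edge_fp=edge_fp,
        edge_fn=edge_fn,
        edge_precision=edge_precision,
        edge_recall=edge_recall,
        edge_weighted_precision=edge_wprec,
        matched_nodes=credited,
        matched_edges=credited_e,
        sign_matches=sign_matches,
    )


def _predicted_node_sign(label, node_units, feature_influence):
    if feature_influence is not None and label in feature_influence:
        return float(feature_influence[label])
    # fall back to the collapsed entity's importance-weighted influence
    if label in node_units:
        return node_units[label][1]
    return None


# ---------------------------------------------------------------------------
# TP/FP curves over selection probabilities
# ---------------------------------------------------------------------------

@dataclass
class TPFPCurve:
    """TP/FP counts per selection-probability threshold + random baseline."""

    points: pd.DataFrame    # threshold, node_tp, node_fp, edge_tp, edge_fp
    baseline: pd.DataFrame  # n_drawn, expected_tp, expected_fp  (edges)

    def to_frames(self):
        return self.points, self.baseline


def tpfp_curve(
    stable: StableEnsemble,
    truth: GroundTruthNetwork,
    disc_features: Optional[set] = None,
    alias_map: Optional[Mapping[str, str]] = None,
    n_random: int = 1000,
    seed: int = 0,
) -> TPFPCurve:
    """Networks at every distinct selection probability, scored vs truth.

    Both TP and FP counts are nondecreasing as the threshold is lowered.
    The random baseline draws the loosest network's edge units in random
    order (``n_random`` times, averaged), i.e. the hypergeometric
    expectation of TPs among the first k drawn.
    """
    probs = sorted(
        {p for p in stable.selection_probability if p > 0}, reverse=True
    )
    rows = []
    loosest = None
    for thr in probs:
        net = build_network(stable, disc_features, min_prob=thr)
        res = evaluate_network(net, truth, alias_map)
        rows.append(
            {
                "threshold": thr,
                "node_tp": res.node_tp,
                "node_fp": res.node_fp,
                "edge_tp": res.edge_tp,
                "edge_fp": res.edge_fp,
            }
        )
        loosest = net
    points = pd.DataFrame(
        rows, columns=["threshold", "node_tp", "node_fp", "edge_tp", "edge_fp"]
    )

    if loosest is None:
        baseline = pd.DataFrame(
            columns=["n_drawn", "expected_tp", "expected_fp"]
        )
        return TPFPCurve(points=points, baseline=baseline)

    alias = dict(alias_map or {})
    units = _edge_entities(loosest, alias)
    ordered = sorted(units.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    flags = np.asarray(
        [pair in truth.edges for pair, _ in ordered], dtype=np.float64
    )
    N = len(flags)
    rng = np.random.default_rng(seed)
    acc = np.zeros(N)
    for _ in range(n_random):
        acc += np.cumsum(flags[rng.permutation(N)])
    exp_tp = acc / n_random
    ks = np.arange(1, N + 1)
    baseline = pd.DataFrame(
        {
            "n_drawn": ks,
            "expected_tp": exp_tp,
            "expected_fp": ks - exp_tp,
        }
    )
    return TPFPCurve(points=points, baseline=baseline)
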