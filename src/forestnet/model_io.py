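"""Readers and writers for tree-ensemble models and feature tables.

A fitted tree ensemble is held as a :class:`TreeEnsembleSpec`: a list of
per-tree node tables.  Two on-disk dialects are supported — the JSON dump
produced by XGBoost (``Booster.dump_model(..., dump_format="json")``) and a
canonical per-node CSV defined by this package (columns
``tree,node,kind,feature,threshold,category_set,left,right,value``;
``category_set`` is a ``|``-joined label list).  Numeric splits follow the
strict-less convention: the *left* child holds samples with
``value < threshold``.

The training data side is a :class:`Dataset`: a validated feature table
(numeric and categorical columns) plus a response vector.  Classification
responses are mapped to ``{0, 1}`` internally; multi-class responses are
reduced one-versus-all via ``positive_class``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError

logger = logging.getLogger(__name__)

NUMERIC = "numeric"
CATEGORICAL = "categorical"

REGRESSION = "regression"
CLASSIFICATION = "classification"

#: fixed float formatting for the node-csv writer (round-trips float64 exactly)
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Tree model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    """One node of a decision tree.

    Split nodes carry either a numeric ``threshold`` (left child ⇔
    ``value < threshold``) or a ``category_set`` (left child ⇔ value in the
    set).  Leaves carry only ``leaf_value``.
    """

    tree_id: int
    node_id: int
    kind: str  # "split" | "leaf"
    feature: Optional[str] = None
    threshold: Optional[float] = None
    category_set: Optional[frozenset] = None
    left_child: Optional[int] = None
    right_child: Optional[int] = None
    leaf_value: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"


@dataclass
class TreeEnsembleSpec:
    """A tree ensemble as a list of node tables (one dict per tree)."""

    trees: list[dict]  # list of {node_id: TreeNode}
    task: str = CLASSIFICATION
    class_labels: Optional[list] = None

    def __post_init__(self):
        if not self.trees:
            raise DataError("a tree ensemble must contain at least one tree")
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ConfigError(f"unknown task {self.task!r}")
        for t, nodes in enumerate(self.trees):
            _check_tree(t, nodes)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_nodes(self) -> int:
        return sum(len(t) for t in self.trees)

    def root_id(self, tree_index: int) -> int:
        nodes = self.trees[tree_index]
        children = set()
        for node in nodes.values():
            if not node.is_leaf:
                children.add(node.left_child)
                children.add(node.right_child)
        roots = [i for i in nodes if i not in children]
        return roots[0]

    def n_leaves(self, tree_index: int) -> int:
        return sum(1 for n in self.trees[tree_index].values() if n.is_leaf)

    def split_features(self) -> set:
        out = set()
        for nodes in self.trees:
            for node in nodes.values():
                if not node.is_leaf:
                    out.add(node.feature)
        return out

    def fingerprint(self) -> str:
        """Stable hash of the node tables (used in run manifests)."""
        import hashlib

        h = hashlib.sha256()
        for nodes in self.trees:
            for nid in sorted(nodes):
                n = nodes[nid]
                cats = "|".join(sorted(map(str, n.category_set))) if n.category_set else ""
                h.update(
                    f"{n.tree_id},{nid},{n.kind},{n.feature},{n.threshold},"
                    f"{cats},{n.left_child},{n.right_child},{n.leaf_value};".encode()
                )
        return h.hexdigest()[:16]


def _check_tree(tree_index: int, nodes: dict) -> None:
    if not nodes:
        raise ParseError(f"tree {tree_index} has no nodes")
    children = []
    for nid, node in nodes.items():
        if node.is_leaf:
            continue
        for child in (node.left_child, node.right_child):
            if child not in nodes:
                raise ParseError(
                    f"tree {tree_index}, node {nid}: child {child} does not exist"
                )
            children.append(child)
    if len(children) != len(set(children)):
        raise ParseError(f"tree {tree_index}: a node has more than one parent")
    roots = set(nodes) - set(children)
    if len(roots) != 1:
        raise ParseError(
            f"tree {tree_index}: expected exactly one root, found {len(roots)}"
        )
    # acyclicity follows from single-parent + single root + children existing,
    # but guard against a root unreachable from itself via a quick walk
    seen = set()
    stack = [next(iter(roots))]
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise ParseError(f"tree {tree_index}: cycle detected at node {nid}")
        seen.add(nid)
        node = nodes[nid]
        if not node.is_leaf:
            stack.extend((node.left_child, node.right_child))
    if seen != set(nodes):
        raise ParseError(f"tree {tree_index}: unreachable nodes {set(nodes) - seen}")


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A validated feature table plus response.

    ``X`` keeps original columns; numeric columns are cached as float64
    arrays and categorical columns as integer codes against an explicit,
    ordered level tuple (``level_orders``).  For discretized features the
    level order is the Low→High bin order; for plain factors it is the
    sorted observed labels.
    """

    X: pd.DataFrame
    y: np.ndarray
    task: str
    feature_kinds: dict = field(default_factory=dict)
    level_orders: dict = field(default_factory=dict)
    _numeric_cache: dict = field(default_factory=dict, repr=False)
    _codes_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)

    @property
    def ybar(self) -> float:
        return float(np.mean(self.y))

    def is_numeric(self, name: str) -> bool:
        return self.feature_kinds[name] == NUMERIC

    def numeric(self, name: str) -> np.ndarray:
        if name not in self._numeric_cache:
            if not self.is_numeric(name):
                raise DataError(f"feature {name!r} is not numeric")
            self._numeric_cache[name] = np.asarray(self.X[name], dtype=np.float64)
        return self._numeric_cache[name]

    def levels(self, name: str):
        return self.level_orders[name]

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes_cache:
            if self.is_numeric(name):
                raise DataError(f"feature {name!r} is not categorical")
            order = self.level_orders[name]
            lookup = {lab: i for i, lab in enumerate(order)}
            self._codes_cache[name] = np.asarray(
                [lookup[v] for v in self.X[name]], dtype=np.int32
            )
        return self._codes_cache[name]

    def replace_y(self, y: np.ndarray) -> "Dataset":
        """Same features, new response (used by response permutation)."""
        return Dataset(
            X=self.X,
            y=np.asarray(y, dtype=np.float64),
            task=self.task,
            feature_kinds=dict(self.feature_kinds),
            level_orders=dict(self.level_orders),
            _numeric_cache=self._numeric_cache,
            _codes_cache=self._codes_cache,
        )


def make_dataset(
    X: pd.DataFrame,
    y,
    task: str,
    level_orders: Optional[Mapping[str, Sequence]] = None,
) -> Dataset:
    """Validate a feature frame + response into a :class:`Dataset`."""
    if task not in (REGRESSION, CLASSIFICATION):
        raise ConfigError(f"unknown task {task!r}")
    if X.shape[1] < 1:
        raise DataError("need at least one feature")
    if len(X) < 2:
        raise DataError("need at least two observations")
    y = np.asarray(y, dtype=np.float64)
    if len(y) != len(X):
        raise DataError("response length does not match feature table")
    if np.isnan(y).any():
        rows = np.flatnonzero(np.isnan(y)).tolist()
        raise DataError(f"missing response values in rows {rows}")
    if task == CLASSIFICATION and not np.isin(y, (0.0, 1.0)).all():
        raise DataError("classification response must be coded {0,1}")

    kinds = {}
    orders = {}
    for col in X.columns:
        s = X[col]
        if s.isna().any():
            rows = np.flatnonzero(s.isna().to_numpy()).tolist()
            raise DataError(f"missing values in feature {col!r}, rows {rows}")
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            kinds[col] = NUMERIC
            if s.nunique() == 1:
                logger.warning("feature %r is constant", col)
        else:
            kinds[col] = CATEGORICAL
            if isinstance(s.dtype, pd.CategoricalDtype) and s.dtype.ordered:
                observed = [l for l in s.dtype.categories if (s == l).any()]
            else:
                observed = sorted(map(str, pd.unique(s.astype(str))))
                X = X.copy() if X is s else X
            if level_orders and col in level_orders:
                observed = [l for l in level_orders[col] if l in set(observed)]
            if len(observed) < 2:
                raise DataError(
                    f"categorical feature {col!r} has fewer than 2 observed levels"
                )
            orders[col] = tuple(observed)
    ds = Dataset(X=X, y=y, task=task, feature_kinds=kinds, level_orders=orders)
    return ds


def read_feature_table(
    path,
    response_column: str,
    task: str,
    positive_class: Optional[str] = None,
    sep: Optional[str] = None,
) -> Dataset:
    """Read a delimited feature table with a header row into a Dataset.

    For classification the response is mapped to ``{0, 1}`` with
    ``positive_class`` → 1; any other label (including every label of a
    multi-class response) maps to 0, i.e. a one-versus-all reduction.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    if response_column not in frame.columns:
        raise DataError(f"response column {response_column!r} not in table")
    raw = frame[response_column]
    X = frame.drop(columns=[response_column])
    if task == REGRESSION:
        y = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=np.float64)
    else:
        labels = raw.astype(str)
        classes = sorted(labels.unique())
        if positive_class is None:
            if len(classes) != 2:
                raise ConfigError(
                    f"{len(classes)} response classes: positive_class is required"
                )
            positive_class = classes[-1]
            logger.info("positive class defaulted to %r", positive_class)
        else:
            positive_class = str(positive_class)
            if positive_class not in set(classes):
                raise DataError(
                    f"positive class {positive_class!r} absent from response"
                )
        y = (labels == positive_class).to_numpy(dtype=np.float64)
    return make_dataset(X, y, task)


def validate_model_against_data(model: TreeEnsembleSpec, data: Dataset):
    """Check that every split is compatible with the feature table."""
    for nodes in model.trees:
        for node in nodes.values():
            if node.is_leaf:
                continue
            if node.feature not in data.feature_kinds:
                raise DataError(f"model splits on unknown feature {node.feature!r}")
            if node.category_set is not None:
                if data.is_numeric(node.feature):
                    raise DataError(
                        f"categorical split on numeric column {node.feature!r}"
                    )
                unseen = set(node.category_set) - set(data.levels(node.feature))
                if unseen:
                    logger.warning(
                        "split on %r uses unobserved levels %s", node.feature, unseen
                    )
            else:
                if not data.is_numeric(node.feature):
                    raise DataError(
                        f"numeric split on categorical column {node.feature!r}"
                    )
                if node.threshold is None or not math.isfinite(node.threshold):
                    raise DataError(
                        f"non-finite threshold on feature {node.feature!r}"
                    )
    return model, data


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_tree_dump(path, dialect: str, task: str = CLASSIFICATION) -> TreeEnsembleSpec:
    """Read a serialized tree ensemble.

    ``dialect`` is ``"xgboost-json"`` (a JSON list of tree objects as written
    by ``Booster.dump_model``) or ``"node-csv"`` (this package's canonical
    per-node table).
    """
    if dialect == "xgboost-json":
        return _read_xgboost_json(path, task)
    if dialect == "node-csv":
        return _read_node_csv(path, task)
    raise ConfigError(f"unknown tree dump dialect {dialect!r}")


def _read_xgboost_json(path, task: str) -> TreeEnsembleSpec:
    with open(path) as fh:
        try:
            dump = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(dump, list):
        raise ParseError("expected a JSON list of trees")
    trees = []
    for t, tree in enumerate(dump):
        nodes: dict = {}
        _walk_xgb(tree, t, nodes)
        trees.append(nodes)
    return TreeEnsembleSpec(trees=trees, task=task)


def _walk_xgb(obj: dict, tree_id: int, nodes: dict) -> None:
    nid = obj.get("nodeid")
    if nid is None:
        raise ParseError(f"tree {tree_id}: node without 'nodeid'")
    if "leaf" in obj:
        nodes[nid] = TreeNode(
            tree_id=tree_id, node_id=nid, kind="leaf", leaf_value=float(obj["leaf"])
        )
        return
    try:
        feature = str(obj["split"])
        threshold = float(obj["split_condition"])
        yes, no = int(obj["yes"]), int(obj["no"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"tree {tree_id}, node {nid}: malformed split: {exc}") from exc
    # xgboost: 'yes' branch holds value < split_condition, matching our left
    nodes[nid] = TreeNode(
        tree_id=tree_id,
        node_id=nid,
        kind="split",
        feature=feature,
        threshold=threshold,
        left_child=yes,
        right_child=no,
    )
    for child in obj.get("children", []):
        _walk_xgb(child, tree_id, nodes)


_CSV_COLUMNS = [
    "tree", "node", "kind", "feature", "threshold",
    "category_set", "left", "right", "value",
]


def _read_node_csv(path, task: str) -> TreeEnsembleSpec:
    trees: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_COLUMNS:
            raise ParseError(
                f"node-csv header must be {','.join(_CSV_COLUMNS)}"
            )
        for i, row in enumerate(reader):
            try:
                t = int(row["tree"])
                nid = int(row["node"])
                kind = row["kind"]
                if kind == "leaf":
                    node = TreeNode(
                        tree_id=t, node_id=nid, kind="leaf",
                        leaf_value=float(row["value"]),
                    )
                elif kind == "split":
                    cats = row["category_set"]
                    node = TreeNode(
                        tree_id=t,
                        node_id=nid,
                        kind="split",
                        feature=row["feature"],
                        threshold=float(row["threshold"]) if row["threshold"] else None,
                        category_set=(
                            frozenset(cats.split("|")) if cats else None
                        ),
                        left_child=int(row["left"]),
                        right_child=int(row["right"]),
                    )
                else:
                    raise ValueError(f"unknown kind {kind!r}")
            except (ValueError, KeyError) as exc:
                raise ParseError(f"node-csv row {i + 2}: {exc}") from exc
            trees.setdefault(t, {})[nid] = node
    ordered = [trees[t] for t in sorted(trees)]
    return TreeEnsembleSpec(trees=ordered, task=task)


def write_node_csv(model: TreeEnsembleSpec, path) -> None:
    """Write the canonical node-csv (bit-exact floats via %.17g)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for t, nodes in enumerate(model.trees):
            for nid in sorted(nodes):
                n = nodes[nid]
                if n.is_leaf:
                    writer.writerow(
                        [t, nid, "leaf", "", "", "", "", "", _FLOAT_FMT % n.leaf_value]
                    )
                else:
                    writer.writerow([
                        t, nid, "split", n.feature,
                        "" if n.threshold is None else _FLOAT_FMT % n.threshold,
                        "|".join(sorted(n.category_set)) if n.category_set else "",
                        n.left_child, n.right_child, "",
                    ])


# ---------------------------------------------------------------------------
# Converters for off-the-shelf learners (test-harness plumbing)
# ---------------------------------------------------------------------------

def from_sklearn_forest(estimator, feature_names: Sequence[str],
                        task: Optional[str] = None) -> TreeEnsembleSpec:
    """Convert a fitted scikit-learn forest/tree ensemble.

    sklearn splits send ``value <= threshold`` left; thresholds are midpoints
    of observed values, so re-reading them under this package's strict-less
    convention reproduces the training-data partition (up to exact-midpoint
    ties, which have measure zero for continuous features).
    """
    if task is None:
        task = CLASSIFICATION if hasattr(estimator, "classes_") else REGRESSION
    trees = []
    members = getattr(estimator, "estimators_", [estimator])
    for t, member in enumerate(members):
        tr = member.tree_
        nodes: dict = {}
        for nid in range(tr.node_count):
            left, right = tr.children_left[nid], tr.children_right[nid]
            if left == -1:
                value = tr.value[nid]
                if task == CLASSIFICATION:
                    counts = value[0]
                    leaf = float(counts[-1] / counts.sum()) if counts.sum() else 0.0
                else:
                    leaf = float(value[0][0])
                nodes[nid] = TreeNode(
                    tree_id=t, node_id=nid, kind="leaf", leaf_value=leaf
                )
            else:
                nodes[nid] = TreeNode(
                    tree_id=t,
                    node_id=nid,
                    kind="split",
                    feature=str(feature_names[tr.feature[nid]]),
                    threshold=float(tr.threshold[nid]),
                    left_child=int(left),
                    right_child=int(right),
                )
        trees.append(nodes)
    return TreeEnsembleSpec(trees=trees, task=task)


def fold_one_hot(
    model: TreeEnsembleSpec,
    encoding: Mapping[str, tuple],
    domains: Mapping[str, Iterable],
) -> TreeEnsembleSpec:
    """Rewrite splits on one-hot dummy columns as category-set splits.

    ``encoding`` maps a dummy column name to ``(parent_feature, level)``;
    ``domains`` maps each parent feature to its full level set.  A split
    ``dummy < t`` with ``0 < t <= 1`` sends the complement of ``level`` left.
    """
    trees = []
    for t, nodes in enumerate(model.trees):
        new: dict = {}
        for nid, node in nodes.items():
            if node.is_leaf or node.feature not in encoding:
                new[nid] = node
                continue
            parent, level = encoding[node.feature]
            thr = node.threshold
            if thr is None or not (0.0 < thr <= 1.0):
                raise DataError(
                    f"cannot fold split on dummy {node.feature!r} with "
                    f"threshold {thr!r}"
                )
            left_set = frozenset(domains[parent]) - {level}
            new[nid] = TreeNode(
                tree_id=t,
                node_id=nid,
                kind="split",
                feature=parent,
                category_set=left_set,
                left_child=node.left_child,
                right_child=node.right_child,
            )
        trees.append(new)
    return TreeEnsembleSpec(trees=trees, task=model.task,
                            class_labels=model.class_labels)
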