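"""Decision, feature and interaction importance and influence.

For a decision ``D`` with support ``S_D``, prediction ``ŷ_D`` and the error
function ``α``:

* decision importance ``I_D = (1 − α(S_D, ŷ_D)/α(S_D, ȳ)) · |S_D|`` — the
  bracket is R² (regression) or Cohen's κ (classification) on the support;
  ``I_D`` is multiplied by the decision multiplicity.
* decision-wise feature importance ``δ_D^j = α(S_D, ŷ_{D_j^rm}) − α(S_D, ŷ_D)``
  where ``D_j^rm`` removes feature ``j`` from the rule.  Both errors are
  evaluated on the *original* support ``S_D``; only the prediction comes from
  the enlarged support.
* decision-wise interaction importance ``δ_D^{j,k} = sqrt(δ_D^j · δ_D^k)``;
  a negative product yields 0 (a feature with negative δ harms the decision,
  so no positive interaction credit).
* direction indicator ``d_D^j ∈ {−1, +1}``: whether the rule admits
  predominantly large (+1) or small (−1) values of the feature.
* influences ``γ_D^j = d_D^j (ŷ_D − ŷ_{D_j^rm})`` and
  ``γ_D^{j,k} = ((d_D^j + d_D^k)/2)(ŷ_D − ŷ_{D_{j,k}^rm})`` — zero whenever
  the two directions are opposite.

Aggregates over the ensemble: ``F_j = Σ_D δ_D^j I_D`` (and the analogue for
pairs), ``Γ_j = Σ_{D∈D_j} γ_D^j I_D / Σ_{D∈D_j} I_D`` averaged over active
decisions, and the pair-direction sign
``η_{j,k} = sign(Σ_{D∈D_{j,k}} d_D^j d_D^k I_D)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .decisions import (
    Condition,
    Decision,
    DecisionEnsemble,
    Rule,
    error_on,
    make_rule,
    prediction_on,
    rule_mask,
)
from .errors import DataError
from .model_io import REGRESSION, Dataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Modified decisions
# ---------------------------------------------------------------------------

@dataclass
class ModifiedDecision:
    """A decision with one or two features removed or complemented."""

    mode: str            # removed | complement
    features: tuple
    rule: Optional[Rule]  # None only for non-representable complements
    support: np.ndarray
    prediction: float
    error: float
    ok: bool = True       # False when the new support is empty

    @property
    def n_support(self) -> int:
        return int(self.support.sum())


def _as_features(features: Union[str, Iterable[str]]) -> tuple:
    if isinstance(features, str):
        return (features,)
    return tuple(features)


def removed_decision(
    D: Decision, features: Union[str, Iterable[str]], data: Dataset
) -> ModifiedDecision:
    """``D_j^rm`` / ``D_{j,k}^rm``: drop the condition(s) on ``features``.

    An emptied rule admits every sample, so the prediction falls back to the
    full-sample mean ``ȳ``.
    """
    feats = _as_features(features)
    active = set(D.features())
    for f in feats:
        if f not in active:
            raise DataError(f"feature {f!r} is not active in the rule")
    rule = make_rule([c for c in D.rule if c.feature not in feats])
    mask = rule_mask(rule, data)
    ys = data.y[mask]
    pred = prediction_on(ys, data.task)
    return ModifiedDecision(
        mode="removed",
        features=feats,
        rule=rule,
        support=mask,
        prediction=pred,
        error=error_on(ys, pred, data.task),
    )


def complement_decision(
    D: Decision, features: Union[str, Iterable[str]], data: Dataset
) -> ModifiedDecision:
    """``D_j^c`` / ``D_{j,k}^c``: complement the condition(s) on ``features``.

    The supports of ``D`` and ``D_j^c`` partition the support of ``D_j^rm``.
    An empty complement support is flagged (``ok=False``) rather than raised.
    """
    feats = _as_features(features)
    conds = []
    for c in D.rule:
        conds.append(c.complement(data) if c.feature in feats else c)
    for f in feats:
        if f not in set(D.features()):
            raise DataError(f"feature {f!r} is not active in the rule")
    rule = make_rule(conds)
    mask = rule_mask(rule, data)
    if not mask.any():
        return ModifiedDecision(
            mode="complement", features=feats, rule=rule, support=mask,
            prediction=math.nan, error=math.nan, ok=False,
        )
    ys = data.y[mask]
    pred = prediction_on(ys, data.task)
    return ModifiedDecision(
        mode="complement",
        features=feats,
        rule=rule,
        support=mask,
        prediction=pred,
        error=error_on(ys, pred, data.task),
    )


# ---------------------------------------------------------------------------
# Single-decision metrics (reference path; the vectorized engine below is
# pinned against these in the oracle tests)
# ---------------------------------------------------------------------------

def decision_importance(D: Decision, data: Dataset) -> float:
    ys = data.y[D.support]
    alpha_bar = error_on(ys, data.ybar, data.task)
    if alpha_bar == 0.0:
        logger.info("response constant on support; importance set to 0")
        return 0.0
    kappa = 1.0 - error_on(ys, D.prediction, data.task) / alpha_bar
    return kappa * D.n_support * D.multiplicity


def feature_delta(D: Decision, j: str, data: Dataset) -> float:
    rm = removed_decision(D, j, data)
    ys = data.y[D.support]
    return error_on(ys, rm.prediction, data.task) - error_on(
        ys, D.prediction, data.task
    )


#: feature deltas below this magnitude are treated as exact zeros before
#: interaction products are formed (sqrt would amplify representation noise)
DELTA_EPS = 1e-12


def _snap(x):
    return 0.0 if abs(x) < DELTA_EPS else x


def interaction_delta(D: Decision, j: str, k: str, data: Dataset) -> float:
    prod = _snap(feature_delta(D, j, data)) * _snap(feature_delta(D, k, data))
    return math.sqrt(prod) if prod >= 0.0 else 0.0


def direction_indicator(D: Decision, j: str, data: Dataset) -> int:
    """±1: does the rule admit predominantly large (+1) or small (−1) values?

    Discrete features compare the mean rank of admitted levels against the
    mean rank of all observed levels (ties → +1).  Raw numeric intervals
    compare the mean feature value over the admitted region with the overall
    mean (ties → +1).
    """
    cond = D.condition(j)
    return _condition_direction(cond, data)


def _condition_direction(cond: Condition, data: Dataset) -> int:
    if cond.levels is not None:
        order = data.levels(cond.feature)
        ranks = {lab: i + 1 for i, lab in enumerate(order)}
        admitted = set(cond.levels)
        if cond.negated:
            admitted = set(order) - admitted
        mean_adm = float(np.mean([ranks[l] for l in admitted if l in ranks]))
        mean_all = float(np.mean(list(ranks.values())))
        return 1 if mean_adm >= mean_all else -1
    x = data.numeric(cond.feature)
    m = cond.mask(data)
    if not m.any():
        return 1
    return 1 if float(x[m].mean()) >= float(x.mean()) else -1


def influence_delta(
    D: Decision, features: Union[str, Iterable[str]], data: Dataset
) -> float:
    feats = _as_features(features)
    rm = removed_decision(D, feats, data)
    ydiff = D.prediction - rm.prediction
    if len(feats) == 1:
        return direction_indicator(D, feats[0], data) * ydiff
    dj, dk = (direction_indicator(D, f, data) for f in feats)
    return ((dj + dk) / 2.0) * ydiff


# ---------------------------------------------------------------------------
# Vectorized ensemble engine
# ---------------------------------------------------------------------------

@dataclass
class MaskPack:
    """Precomputed full-data supports for an ensemble.

    Rows of ``removed_feat``/``removed_pair`` are the supports of the
    removed decisions; slicing all matrices by a resample index vector
    reproduces every quantity on that resample.
    """

    supports: np.ndarray          # (D, n) bool
    multiplicity: np.ndarray      # (D,)
    feat_dec: np.ndarray          # (Fr,) decision index per feature-row
    feat_name: np.ndarray         # (Fr,) feature name per feature-row
    feat_dir: np.ndarray          # (Fr,) direction indicator per feature-row
    removed_feat: np.ndarray      # (Fr, n) bool
    pair_dec: np.ndarray          # (Pr,)
    pair_a: np.ndarray            # (Pr,) first feature name
    pair_b: np.ndarray            # (Pr,)
    pair_ai: np.ndarray           # (Pr,) index into feature rows
    pair_bi: np.ndarray           # (Pr,)
    removed_pair: np.ndarray      # (Pr, n) bool


def build_mask_pack(ensemble: DecisionEnsemble) -> MaskPack:
    data = ensemble.data
    n = data.n
    decs = ensemble.decisions
    supports = (
        np.stack([d.support for d in decs])
        if decs
        else np.zeros((0, n), dtype=bool)
    )
    feat_dec, feat_name, feat_dir, removed_feat = [], [], [], []
    pair_dec, pair_a, pair_b, pair_ai, pair_bi, removed_pair = [], [], [], [], [], []
    row_index: dict = {}
    for di, d in enumerate(decs):
        conds = list(d.rule)
        masks = [c.mask(data) for c in conds]
        L = len(conds)
        for i, c in enumerate(conds):
            others = np.ones(n, dtype=bool)
            for j2, m in enumerate(masks):
                if j2 != i:
                    others &= m
            row_index[(di, c.feature)] = len(feat_dec)
            feat_dec.append(di)
            feat_name.append(c.feature)
            feat_dir.append(_condition_direction(c, data))
            removed_feat.append(others)
        for i in range(L):
            for j2 in range(i + 1, L):
                others = np.ones(n, dtype=bool)
                for k2, m in enumerate(masks):
                    if k2 != i and k2 != j2:
                        others &= m
                pair_dec.append(di)
                pair_a.append(conds[i].feature)
                pair_b.append(conds[j2].feature)
                pair_ai.append(row_index[(di, conds[i].feature)])
                pair_bi.append(row_index[(di, conds[j2].feature)])
                removed_pair.append(others)
    return MaskPack(
        supports=supports,
        multiplicity=np.array([d.multiplicity for d in decs], dtype=np.float64),
        feat_dec=np.asarray(feat_dec, dtype=np.int64),
        feat_name=np.asarray(feat_name, dtype=object),
        feat_dir=np.asarray(feat_dir, dtype=np.float64),
        removed_feat=(
            np.stack(removed_feat) if removed_feat else np.zeros((0, n), dtype=bool)
        ),
        pair_dec=np.asarray(pair_dec, dtype=np.int64),
        pair_a=np.asarray(pair_a, dtype=object),
        pair_b=np.asarray(pair_b, dtype=object),
        pair_ai=np.asarray(pair_ai, dtype=np.int64),
        pair_bi=np.asarray(pair_bi, dtype=np.int64),
        removed_pair=(
            np.stack(removed_pair) if removed_pair else np.zeros((0, n), dtype=bool)
        ),
    )


@dataclass
class DecisionMetrics:
    """All decision-wise metrics of an ensemble (optionally on a resample)."""

    importance: np.ndarray     # (D,) multiplicity-weighted I_D; NaN if absent
    kappa: np.ndarray          # (D,) the R²/κ bracket
    prediction: np.ndarray     # (D,)
    error: np.ndarray          # (D,)
    n_support: np.ndarray      # (D,)
    present: np.ndarray        # (D,) bool: nonempty support on the sample
    feat: pd.DataFrame         # decision, feature, delta, direction, ydiff, gamma
    pairs: pd.DataFrame        # decision, feature_a, feature_b, delta, ydiff,
                               # gamma, dir_a, dir_b


def _moments(mask_matrix: np.ndarray, idx: Optional[np.ndarray],
             y: np.ndarray, need_sq: bool):
    """Counts and response sums per mask row, restricted to sample ``idx``."""
    M = mask_matrix if idx is None else mask_matrix[:, idx]
    Mf = M.astype(np.float64)
    yb = y if idx is None else y[idx]
    cnt = Mf.sum(axis=1)
    s1 = Mf @ yb
    s2 = Mf @ (yb * yb) if need_sq else None
    return cnt, s1, s2, yb


def _alpha_scalar_pred(cnt, s1, s2, yhat, task):
    """α(S, ŷ) from support moments, vectorized over rows; ŷ broadcastable."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if task == REGRESSION:
            return (s2 - 2.0 * yhat * s1 + cnt * yhat * yhat) / cnt
        # classification: s1 = #positives on S
        return (s1 * (1.0 - yhat) + (cnt - s1) * yhat) / cnt


def compute_decision_metrics(
    ensemble: DecisionEnsemble,
    pack: Optional[MaskPack] = None,
    idx: Optional[np.ndarray] = None,
) -> DecisionMetrics:
    """Every decision-wise metric, in closed form from support moments.

    ``idx`` restricts all supports, predictions, errors and the sample mean
    ``ȳ`` to a (bootstrap) index vector; ``None`` means the full sample.
    """
    if pack is None:
        pack = build_mask_pack(ensemble)
    data = ensemble.data
    task = data.task
    need_sq = task == REGRESSION
    y = data.y

    cnt, s1, s2, yb = _moments(pack.supports, idx, y, need_sq)
    present = cnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = s1 / cnt
    ybar = float(yb.mean()) if len(yb) else math.nan
    alpha_self = _alpha_scalar_pred(cnt, s1, s2, pred, task)
    alpha_bar = _alpha_scalar_pred(cnt, s1, s2, ybar, task)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = 1.0 - alpha_self / alpha_bar
    kappa = np.where(alpha_bar == 0.0, 0.0, kappa)
    importance = kappa * cnt * pack.multiplicity
    importance = np.where(present, importance, np.nan)

    # feature rows
    rcnt, rs1, rs2, _ = _moments(pack.removed_feat, idx, y, need_sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        pred_rm = rs1 / rcnt
    dcnt = cnt[pack.feat_dec]
    ds1 = s1[pack.feat_dec]
    ds2 = s2[pack.feat_dec] if need_sq else None
    alpha_rm_on_S = _alpha_scalar_pred(dcnt, ds1, ds2, pred_rm, task)
    delta = alpha_rm_on_S - alpha_self[pack.feat_dec]
    ydiff = pred[pack.feat_dec] - pred_rm
    gamma = pack.feat_dir * ydiff
    feat = pd.DataFrame(
        {
            "decision": pack.feat_dec,
            "feature": pack.feat_name,
            "delta": delta,
            "direction": pack.feat_dir,
            "ydiff": ydiff,
            "gamma": gamma,
        }
    )

    # pair rows
    pcnt, ps1, ps2, _ = _moments(pack.removed_pair, idx, y, need_sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        pred_rm2 = ps1 / pcnt
    ydiff2 = pred[pack.pair_dec] - pred_rm2
    da = pack.feat_dir[pack.pair_ai]
    db = pack.feat_dir[pack.pair_bi]
    snapped = np.where(np.abs(delta) < DELTA_EPS, 0.0, delta)
    prod = snapped[pack.pair_ai] * snapped[pack.pair_bi]
    delta2 = np.where(prod < 0.0, 0.0, np.sqrt(np.maximum(prod, 0.0)))
    gamma2 = ((da + db) / 2.0) * ydiff2
    pairs = pd.DataFrame(
        {
            "decision": pack.pair_dec,
            "feature_a": pack.pair_a,
            "feature_b": pack.pair_b,
            "delta": delta2,
            "ydiff": ydiff2,
            "gamma": gamma2,
            "dir_a": da,
            "dir_b": db,
        }
    )

    return DecisionMetrics(
        importance=importance,
        kappa=kappa,
        prediction=pred,
        error=alpha_self,
        n_support=cnt,
        present=present,
        feat=feat,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class FeatureMetrics:
    """Per-feature importance F and influence Γ."""

    table: pd.DataFrame  # feature, importance, influence, n_active


@dataclass
class InteractionMetrics:
    """Per-pair importance F, influence Γ and direction sign η."""

    table: pd.DataFrame  # feature_a, feature_b, importance, influence, eta, n_active


def aggregate_metrics(
    ensemble: DecisionEnsemble, dm: DecisionMetrics
) -> tuple:
    """Variable-level aggregates ``(FeatureMetrics, InteractionMetrics)``.

    Decisions absent from the working sample contribute nothing; features
    never active receive no entry.
    """
    I = dm.importance
    feat = dm.feat[dm.present[dm.feat["decision"].to_numpy()]]
    pairs = dm.pairs[dm.present[dm.pairs["decision"].to_numpy()]]

    frows = feat.assign(I=I[feat["decision"].to_numpy()])
    out_f = []
    for name, g in frows.groupby("feature", sort=True):
        denom = g["I"].sum()
        if denom == 0.0:
            logger.info("zero total importance over active set of %r", name)
            influence = 0.0
        else:
            influence = float((g["gamma"] * g["I"]).sum() / denom)
        out_f.append(
            {
                "feature": name,
                "importance": float((g["delta"] * g["I"]).sum()),
                "influence": influence,
                "n_active": int(len(g)),
            }
        )
    ftab = pd.DataFrame(out_f, columns=["feature", "importance", "influence", "n_active"])

    prows = pairs.assign(I=I[pairs["decision"].to_numpy()])
    # canonical unordered pair
    a = prows[["feature_a", "feature_b"]].min(axis=1)
    b = prows[["feature_a", "feature_b"]].max(axis=1)
    prows = prows.assign(pa=a, pb=b)
    out_p = []
    for (na, nb), g in prows.groupby(["pa", "pb"], sort=True):
        denom = g["I"].sum()
        influence = (
            float((g["gamma"] * g["I"]).sum() / denom) if denom != 0.0 else 0.0
        )
        eta = float(np.sign((g["dir_a"] * g["dir_b"] * g["I"]).sum()))
        out_p.append(
            {
                "feature_a": na,
                "feature_b": nb,
                "importance": float((g["delta"] * g["I"]).sum()),
                "influence": influence,
                "eta": eta,
                "n_active": int(len(g)),
            }
        )
    ptab = pd.DataFrame(
        out_p,
        columns=["feature_a", "feature_b", "importance", "influence", "eta", "n_active"],
    )
    return FeatureMetrics(table=ftab), InteractionMetrics(table=ptab)


def condition_node_label(cond: Condition, data: Dataset,
                         disc_features: Optional[set] = None) -> str:
    """Display label of the (feature, admitted-set) pseudo-feature."""
    disc_features = disc_features or set()
    if cond.levels is None:
        lo = "" if cond.lo == -math.inf else f"{cond.lo:.6g}"
        hi = "" if cond.hi == math.inf else f"{cond.hi:.6g}"
        return f"{cond.feature}__[{lo},{hi})"
    if cond.feature in disc_features:
        order = {lab: i for i, lab in enumerate(data.levels(cond.feature))}
        labs = sorted(cond.levels, key=order.get)
        return f"{cond.feature}__" + "_".join(labs)
    return f"{cond.feature}=" + "|".join(sorted(map(str, cond.levels)))


def aggregate_node_metrics(
    ensemble: DecisionEnsemble,
    dm: DecisionMetrics,
    disc_features: Optional[set] = None,
) -> tuple:
    """Aggregates at (feature, level-set) pseudo-feature granularity.

    Node influence is the importance-weighted mean *raw* prediction shift
    ``ŷ_D − ŷ_rm`` (membership in the admitted set plays the role of the
    "high" side), so a Low-level node of a positively associated feature
    comes out negative.  Edge influence and η keep the direction indicators.
    """
    data = ensemble.data
    disc = disc_features or set()
    I = dm.importance
    labels = {}
    features = {}
    levelsets = {}
    entities = {}
    for di, d in enumerate(ensemble.decisions):
        for c in d.rule:
            lab = condition_node_label(c, data, disc_features)
            labels[(di, c.feature)] = lab
            features[lab] = c.feature
            levelsets[lab] = c.levels
            if c.levels is None or c.feature in disc:
                entities[lab] = c.feature
            else:
                entities[lab] = "|".join(
                    f"{c.feature}={l}" for l in sorted(map(str, c.levels))
                )

    feat = dm.feat[dm.present[dm.feat["decision"].to_numpy()]]
    frows = feat.assign(
        I=I[feat["decision"].to_numpy()],
        node=[
            labels[(d, f)]
            for d, f in zip(feat["decision"].to_numpy(), feat["feature"].to_numpy())
        ],
    )
    out_n = []
    for lab, g in frows.groupby("node", sort=True):
        denom = g["I"].sum()
        influence = (
            float((g["ydiff"] * g["I"]).sum() / denom) if denom != 0.0 else 0.0
        )
        out_n.append(
            {
                "node": lab,
                "feature": features[lab],
                "levels": (
                    "|".join(map(str, levelsets[lab]))
                    if levelsets[lab] is not None
                    else ""
                ),
                "entities": entities[lab],
                "importance": float((g["delta"] * g["I"]).sum()),
                "influence": influence,
                "n_active": int(len(g)),
            }
        )
    nodes = pd.DataFrame(
        out_n,
        columns=["node", "feature", "levels", "entities", "importance",
                 "influence", "n_active"],
    )

    pairs = dm.pairs[dm.present[dm.pairs["decision"].to_numpy()]]
    prows = pairs.assign(
        I=I[pairs["decision"].to_numpy()],
        node_a=[
            labels[(d, f)]
            for d, f in zip(pairs["decision"].to_numpy(), pairs["feature_a"].to_numpy())
        ],
        node_b=[
            labels[(d, f)]
            for d, f in zip(pairs["decision"].to_numpy(), pairs["feature_b"].to_numpy())
        ],
    )
    na = prows[["node_a", "node_b"]].min(axis=1)
    nb = prows[["node_a", "node_b"]].max(axis=1)
    prows = prows.assign(pa=na, pb=nb)
    out_e = []
    for (a, b), g in prows.groupby(["pa", "pb"], sort=True):
        denom = g["I"].sum()
        influence = (
            float((g["gamma"] * g["I"]).sum() / denom) if denom != 0.0 else 0.0
        )
        out_e.append(
            {
                "node_a": a,
                "node_b": b,
                "importance": float((g["delta"] * g["I"]).sum()),
                "influence": influence,
                "eta": float(np.sign((g["dir_a"] * g["dir_b"] * g["I"]).sum())),
                "any_positive_delta": bool((g["delta"] > 0).any()),
                "n_active": int(len(g)),
            }
        )
    edges = pd.DataFrame(
        out_e,
        columns=[
            "node_a", "node_b", "importance", "influence", "eta",
            "any_positive_delta", "n_active",
        ],
    )
    return nodes, edges
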