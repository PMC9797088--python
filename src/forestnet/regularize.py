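"""Decision-wise regularization and ensemble-level stability selection.

Three steps reduce a raw decision ensemble to a stable one:

1. **Discretization** — numeric features are binned into ``K`` ordered levels
   (``K = 2`` by default) and every numeric condition is rewritten to the set
   of levels whose observations *majority-satisfy* it; conditions that admit
   every level are dropped from the rule.
2. **Pruning** — variables whose removal raises the decision error by at most
   ``tolerance`` (relative to the decision's own error) are removed
   iteratively, smallest increase first.
3. **Stability selection** — all decision-wise metrics are recomputed on
   ``B`` bootstrap resamples (sub-sampling with replacement, size
   ``fraction·n``); the ``q`` most important decisions of each resample are
   recorded, with ``q = ⌊max{1, (2π_thr − 1)·α·d}⌋`` and ``d`` the average
   decision count across resamples; decisions appearing in at least
   ``π_thr·B`` of the top-``q`` sets are retained, their metrics averaged
   over the resamples where they were present.  ``α`` plays the role of the
   expected number of false discoveries.

After each decision-wise step, identical rules are regrouped and the
multiplicity accumulated, so Σ multiplicity is conserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .decisions import (
    Condition,
    Decision,
    DecisionEnsemble,
    error_on,
    group_duplicate_rules,
    make_rule,
    prediction_on,
    rule_to_string,
)
from .errors import ConfigError
from .metrics import (
    DecisionMetrics,
    build_mask_pack,
    compute_decision_metrics,
)
from .model_io import Dataset

logger = logging.getLogger(__name__)

_EPS = 1e-6  # floor for the relative error increase used by pruning


def level_labels(K: int) -> tuple:
    if K == 2:
        return ("Low", "High")
    if K == 3:
        return ("Low", "Medium", "High")
    return tuple(f"Level{i + 1}" for i in range(K))


@dataclass
class DiscretizationMap:
    """Per-feature breakpoints and ordered level labels."""

    K: int
    method: str  # "data" | "rf-thresholds"
    breakpoints: dict = field(default_factory=dict)  # feature -> ndarray (K-1,)
    labels: dict = field(default_factory=dict)       # feature -> tuple of labels

    @property
    def features(self) -> set:
        return set(self.breakpoints)

    def level_of(self, feature: str, x: np.ndarray) -> np.ndarray:
        """Bin index per sample; level i spans [bp[i-1], bp[i])."""
        return np.searchsorted(self.breakpoints[feature], x, side="right")


def _data_breakpoints(x: np.ndarray, K: int) -> Optional[np.ndarray]:
    if len(np.unique(x)) < K:
        return None
    bps = np.quantile(x, [i / K for i in range(1, K)])
    if not np.all(np.diff(bps) > 0):
        return None
    return bps


def _threshold_breakpoints(
    thresholds: np.ndarray, weights: np.ndarray, K: int
) -> Optional[np.ndarray]:
    """1-d k-means (K−1 centers) over split thresholds, frequency-weighted."""
    uniq = np.unique(thresholds)
    if len(uniq) < K - 1:
        return None
    if len(uniq) == K - 1:
        return uniq
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K - 1, n_init=5, random_state=0)
    km.fit(thresholds.reshape(-1, 1), sample_weight=weights)
    bps = np.sort(km.cluster_centers_.ravel())
    if not np.all(np.diff(bps) > 0):
        return None
    return bps


def discretize(
    data: Dataset,
    ensemble: DecisionEnsemble,
    K: int = 2,
    method: str = "data",
):
    """Bin numeric features into levels and rewrite the ensemble's rules.

    Returns ``(leveled dataset, DiscretizationMap, rewritten ensemble)``.
    A numeric condition is rewritten to the set of levels whose members
    majority-satisfy it (strict majority); an all-level condition drops the
    feature; an empty admitted set drops the decision.  Features with fewer
    distinct values than ``K`` (or without usable breakpoints) are kept
    unsplit with a warning.
    """
    if K < 2:
        raise ConfigError("discretization needs K >= 2")
    if method not in ("data", "rf-thresholds"):
        raise ConfigError(f"unknown discretization method {method!r}")

    dmap = DiscretizationMap(K=K, method=method)
    labels = level_labels(K)
    if method == "rf-thresholds":
        thr: dict = {}
        for d in ensemble.decisions:
            for c in d.rule:
                if c.levels is None:
                    for bound in (c.lo, c.hi):
                        if math.isfinite(bound):
                            thr.setdefault(c.feature, []).append(
                                (bound, d.multiplicity)
                            )
    for feat in data.feature_names:
        if not data.is_numeric(feat):
            continue
        x = data.numeric(feat)
        if method == "data":
            bps = _data_breakpoints(x, K)
        else:
            entries = thr.get(feat)
            if entries:
                ts = np.array([t for t, _ in entries], dtype=np.float64)
                ws = np.array([w for _, w in entries], dtype=np.float64)
                bps = _threshold_breakpoints(ts, ws, K)
            else:
                bps = None
        if bps is None:
            logger.warning("feature %r kept unsplit (no usable %d-level "
                           "breakpoints)", feat, K)
            continue
        dmap.breakpoints[feat] = np.asarray(bps, dtype=np.float64)
        dmap.labels[feat] = labels

    new_data = _apply_map(data, dmap)
    new_ensemble = _rewrite_rules(ensemble, data, new_data, dmap)
    return new_data, dmap, new_ensemble


def _apply_map(data: Dataset, dmap: DiscretizationMap) -> Dataset:
    from .model_io import make_dataset

    X = data.X.copy()
    orders = {}
    for feat in dmap.features:
        labs = dmap.labels[feat]
        lvl = dmap.level_of(feat, data.numeric(feat))
        observed = [labs[i] for i in sorted(set(lvl.tolist()))]
        X[feat] = pd.Categorical(
            [labs[i] for i in lvl], categories=observed, ordered=True
        )
        orders[feat] = observed
    for feat in data.feature_names:
        if feat not in dmap.features and not data.is_numeric(feat):
            orders[feat] = data.levels(feat)
    return make_dataset(X, data.y, data.task, level_orders=orders)


def _rewrite_rules(
    ensemble: DecisionEnsemble,
    old_data: Dataset,
    new_data: Dataset,
    dmap: DiscretizationMap,
) -> DecisionEnsemble:
    # sorted feature values for majority counting
    sorted_x = {f: np.sort(old_data.numeric(f)) for f in dmap.features}
    n_dropped = 0
    decisions = []
    for d in ensemble.decisions:
        conds = []
        dead = False
        for c in d.rule:
            if c.levels is not None or c.feature not in dmap.features:
                conds.append(c)
                continue
            admitted = _majority_levels(
                c, sorted_x[c.feature], dmap.breakpoints[c.feature],
                dmap.labels[c.feature],
            )
            observed = set(new_data.levels(c.feature))
            admitted = [a for a in admitted if a in observed]
            if not admitted:
                dead = True
                break
            if set(admitted) >= observed:
                continue  # full-domain after rewriting: feature dropped
            conds.append(Condition(c.feature, levels=tuple(admitted)))
        if dead:
            n_dropped += 1
            continue
        rule = make_rule(conds)
        from .decisions import rule_mask

        mask = rule_mask(rule, new_data)
        if not mask.any():
            n_dropped += 1
            continue
        ys = new_data.y[mask]
        pred = prediction_on(ys, new_data.task)
        decisions.append(
            Decision(
                rule=rule,
                prediction=pred,
                error=error_on(ys, pred, new_data.task),
                support=mask,
                n_support=int(mask.sum()),
                multiplicity=d.multiplicity,
            )
        )
    if n_dropped:
        logger.info("discretization dropped %d decisions", n_dropped)
    return group_duplicate_rules(
        DecisionEnsemble(decisions=decisions, data=new_data)
    )


def _majority_levels(cond, xs: np.ndarray, bps: np.ndarray, labs) -> list:
    """Levels whose members majority-satisfy the interval [lo, hi)."""
    edges = np.concatenate(([-np.inf], bps, [np.inf]))
    admitted = []
    for i, lab in enumerate(labs):
        lo_l, hi_l = edges[i], edges[i + 1]
        total = np.searchsorted(xs, hi_l, side="left") - np.searchsorted(
            xs, lo_l, side="left"
        )
        if total == 0:
            continue
        a, b = max(cond.lo, lo_l), min(cond.hi, hi_l)
        inside = 0
        if a < b:
            inside = np.searchsorted(xs, b, side="left") - np.searchsorted(
                xs, a, side="left"
            )
        if inside / total > 0.5:
            admitted.append(lab)
    return admitted


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_decisions(
    ensemble: DecisionEnsemble,
    data: Optional[Dataset] = None,
    tolerance: float = 0.05,
) -> DecisionEnsemble:
    """Iteratively remove variables that barely participate in a decision.

    At each step, the variable with the smallest error increase is removed
    while ``(α(S_D, ŷ_rm) − α(S_D, ŷ_D)) / max(α(S_D, ŷ_D), 1e−6)`` stays at
    or below ``tolerance``; support, prediction and error are then
    recomputed on the widened rule.  A decision whose rule empties entirely
    becomes the trivial (empty-rule) decision — kept so multiplicity is
    conserved, ignored by metrics and stability.  Duplicates are regrouped.
    """
    if tolerance < 0:
        raise ConfigError("pruning tolerance must be >= 0")
    data = data or ensemble.data
    y = data.y
    task = data.task
    out = []
    for d in ensemble.decisions:
        conds, support = _prune_conditions(
            list(d.rule), [c.mask(data) for c in conds_of(d)], y, task, tolerance
        )
        rule = make_rule(conds)
        ys = y[support]
        pred = prediction_on(ys, task)
        out.append(
            Decision(
                rule=rule,
                prediction=pred,
                error=error_on(ys, pred, task),
                support=support,
                n_support=int(support.sum()),
                multiplicity=d.multiplicity,
            )
        )
    return group_duplicate_rules(DecisionEnsemble(decisions=out, data=data))


def conds_of(d: Decision) -> list:
    return list(d.rule)


def _prune_conditions(conds, masks, y, task, tolerance):
    """Shared pruning loop on (already sliced) condition masks.

    Returns the surviving conditions and the final support mask over the
    samples the masks describe.
    """
    n = len(y)
    support = np.ones(n, dtype=bool)
    for m in masks:
        support &= m
    while conds:
        ys = y[support]
        pred = prediction_on(ys, task)
        alpha_self = error_on(ys, pred, task)
        best_i, best_rel, best_mask = None, None, None
        for i in range(len(conds)):
            rm = np.ones(n, dtype=bool)
            for j, m in enumerate(masks):
                if j != i:
                    rm &= m
            pred_rm = float(np.mean(y[rm]))
            rel = (error_on(ys, pred_rm, task) - alpha_self) / max(
                alpha_self, _EPS
            )
            if best_rel is None or rel < best_rel or (
                rel == best_rel and conds[i].feature < conds[best_i].feature
            ):
                best_i, best_rel, best_mask = i, rel, rm
        if best_rel is not None and best_rel <= tolerance:
            del conds[best_i]
            del masks[best_i]
            support = best_mask
        else:
            break
    return conds, support


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityParams:
    """Bootstrap stability-selection settings (paper defaults)."""

    B: int = 10
    pi_thr: float = 0.7
    alpha_reg: float = 1.0
    resample_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> "StabilityParams":
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if not 0.5 < self.pi_thr <= 1.0:
            raise ConfigError("pi_thr must lie in (0.5, 1]")
        if self.alpha_reg <= 0:
            raise ConfigError("alpha (regularization) must be > 0")
        if not 0.0 < self.resample_fraction <= 1.0:
            raise ConfigError("resample_fraction must lie in (0, 1]")
        return self


def stability_q(pi_thr: float, alpha_reg: float, d: float) -> int:
    """q = ⌊max{1, (2π_thr − 1)·α·d}⌋.

    The product is rounded at the 9th decimal before flooring so that
    binary-representation noise (e.g. 0.4·100 → 39.999…) cannot shift the
    floor."""
    v = max(1.0, (2.0 * pi_thr - 1.0) * alpha_reg * d)
    return int(math.floor(round(v, 9)))


@dataclass
class StableEnsemble:
    """Decisions surviving stability selection plus bootstrap records.

    ``pool`` holds every (non-trivial) regularized decision with its
    selection probability; ``pool_metrics`` holds decision-wise metrics
    averaged over the resamples where each decision was present.  The stable
    subset is ``pool`` filtered at ``π_thr``.
    """

    pool: DecisionEnsemble
    pool_metrics: DecisionMetrics
    selection_probability: np.ndarray
    q: int
    d_mean: float
    params: StabilityParams

    @property
    def data(self) -> Dataset:
        return self.pool.data

    def stable_mask(self, min_prob: Optional[float] = None) -> np.ndarray:
        thr = self.params.pi_thr if min_prob is None else min_prob
        return self.selection_probability >= thr - 1e-12

    @property
    def decisions(self) -> list:
        m = self.stable_mask()
        return [d for d, keep in zip(self.pool.decisions, m) if keep]

    def __len__(self) -> int:
        return int(self.stable_mask().sum())

    def ensemble(self) -> DecisionEnsemble:
        return DecisionEnsemble(decisions=self.decisions, data=self.pool.data)

    def to_frame(self) -> pd.DataFrame:
        frame = self.pool.to_frame()
        frame["selection_probability"] = self.selection_probability
        frame["importance"] = self.pool_metrics.importance
        frame["stable"] = self.stable_mask()
        return frame.sort_values(
            ["stable", "selection_probability", "importance"],
            ascending=[False, False, False],
            kind="mergesort",
        ).reset_index(drop=True)


def stability_select(
    data: Dataset,
    ensemble: DecisionEnsemble,
    params: StabilityParams = None,
    prune_tolerance: Optional[float] = None,
) -> StableEnsemble:
    """Bootstrap stability selection.

    The prediction model is *not* refitted; supports, predictions, errors
    and importances are recomputed on every resample.  With
    ``prune_tolerance`` set, decision-wise regularization (pruning +
    duplicate grouping) is additionally re-run *inside* each bootstrap, so
    that conditions whose survival is a resample-level fluctuation appear
    inconsistently across resamples and drop out of the stable ensemble.
    Ties at the ``q`` boundary break deterministically by (importance,
    support size, rule string).  Per-bootstrap seeds derive from
    ``params.seed`` and the bootstrap index, so results do not depend on
    execution order.
    """
    params = (params or StabilityParams()).validate()
    working = [d for d in ensemble.decisions if len(d.rule) > 0]
    n_trivial = len(ensemble.decisions) - len(working)
    if n_trivial:
        logger.info("ignoring %d trivial (empty-rule) decisions", n_trivial)
    if prune_tolerance is not None:
        return _stability_with_pruning(data, working, params, prune_tolerance)
    pool = DecisionEnsemble(decisions=working, data=data)
    D = len(working)
    if D == 0:
        empty = compute_decision_metrics(pool)
        return StableEnsemble(
            pool=pool,
            pool_metrics=empty,
            selection_probability=np.zeros(0),
            q=1,
            d_mean=0.0,
            params=params,
        )

    pack = build_mask_pack(pool)
    n = data.n
    nb = int(math.ceil(params.resample_fraction * n))
    rule_keys = np.array([rule_to_string(d.rule) for d in working], dtype=object)

    per_boot = []
    counts = []
    for b in range(params.B):
        rng = np.random.default_rng([params.seed, b])
        idx = rng.integers(0, n, size=nb)
        dm = compute_decision_metrics(pool, pack, idx)
        per_boot.append(dm)
        counts.append(int(dm.present.sum()))
    d_mean = float(np.mean(counts))
    q = stability_q(params.pi_thr, params.alpha_reg, d_mean)

    sel_count = np.zeros(D, dtype=np.int64)
    for dm in per_boot:
        present_idx = np.flatnonzero(dm.present)
        order = sorted(
            present_idx,
            key=lambda i: (-dm.importance[i], -dm.n_support[i], rule_keys[i]),
        )
        sel_count[order[:q]] += 1
    sel_prob = sel_count / params.B

    pool_metrics = _average_metrics(per_boot)
    stable = StableEnsemble(
        pool=pool,
        pool_metrics=pool_metrics,
        selection_probability=sel_prob,
        q=q,
        d_mean=d_mean,
        params=params,
    )
    for i, d in enumerate(working):
        d.selection_probability = float(sel_prob[i])
        d.importance = (
            float(pool_metrics.importance[i])
            if np.isfinite(pool_metrics.importance[i])
            else None
        )
    return stable


def _average_metrics(per_boot) -> DecisionMetrics:
    """Average decision-wise metrics over resamples where each decision was
    present."""
    D = len(per_boot[0].importance)
    stacked_I = np.stack([dm.importance for dm in per_boot])
    stacked_pred = np.stack([dm.prediction for dm in per_boot])
    stacked_err = np.stack([dm.error for dm in per_boot])
    stacked_cnt = np.stack(
        [np.where(dm.present, dm.n_support, np.nan) for dm in per_boot]
    )
    present_any = np.stack([dm.present for dm in per_boot]).any(axis=0)

    def _nanmean(a):  # nanmean without empty-slice warnings
        k = np.sum(~np.isnan(a), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nansum(a, axis=0) / k

    mean_I = _nanmean(stacked_I)
    mean_pred = _nanmean(stacked_pred)
    mean_err = _nanmean(stacked_err)
    mean_cnt = _nanmean(stacked_cnt)
    kappa = np.full(D, np.nan)

    feat_frames = []
    pair_frames = []
    for dm in per_boot:
        pres = dm.present
        feat_frames.append(dm.feat[pres[dm.feat["decision"].to_numpy()]])
        pair_frames.append(dm.pairs[pres[dm.pairs["decision"].to_numpy()]])
    feat = (
        pd.concat(feat_frames)
        .groupby(["decision", "feature"], sort=True, as_index=False)
        .agg(
            delta=("delta", "mean"),
            direction=("direction", "first"),
            ydiff=("ydiff", "mean"),
            gamma=("gamma", "mean"),
        )
    )
    pairs = (
        pd.concat(pair_frames)
        .groupby(["decision", "feature_a", "feature_b"], sort=True, as_index=False)
        .agg(
            delta=("delta", "mean"),
            ydiff=("ydiff", "mean"),
            gamma=("gamma", "mean"),
            dir_a=("dir_a", "first"),
            dir_b=("dir_b", "first"),
        )
    )
    return DecisionMetrics(
        importance=mean_I,
        kappa=kappa,
        prediction=mean_pred,
        error=mean_err,
        n_support=mean_cnt,
        present=present_any,
        feat=feat,
        pairs=pairs,
    )


def _stability_with_pruning(
    data: Dataset, working: list, params: StabilityParams, tolerance: float
) -> StableEnsemble:
    """Stability selection with decision-wise regularization per resample."""
    from .decisions import decision_from_rule
    from .metrics import _condition_direction

    y = data.y
    task = data.task
    n = data.n
    nb = int(math.ceil(params.resample_fraction * n))

    cond_cache: dict = {}

    def cmask(c):
        m = cond_cache.get(c)
        if m is None:
            m = c.mask(data)
            cond_cache[c] = m
        return m

    support_cache: dict = {}
    removed_cache: dict = {}
    pair_cache: dict = {}
    dir_cache: dict = {}

    def full_support(rule):
        m = support_cache.get(rule)
        if m is None:
            m = np.ones(n, dtype=bool)
            for c in rule:
                m &= cmask(c)
            support_cache[rule] = m
        return m

    def removed_masks(rule):
        out = removed_cache.get(rule)
        if out is None:
            masks = [cmask(c) for c in rule]
            out = []
            for i in range(len(masks)):
                m = np.ones(n, dtype=bool)
                for j, mj in enumerate(masks):
                    if j != i:
                        m &= mj
                out.append(m)
            removed_cache[rule] = out
        return out

    def pair_masks(rule):
        out = pair_cache.get(rule)
        if out is None:
            masks = [cmask(c) for c in rule]
            out = {}
            for i in range(len(masks)):
                for j in range(i + 1, len(masks)):
                    m = np.ones(n, dtype=bool)
                    for k, mk in enumerate(masks):
                        if k != i and k != j:
                            m &= mk
                    out[(i, j)] = m
            pair_cache[rule] = out
        return out

    def directions(rule):
        d = dir_cache.get(rule)
        if d is None:
            d = [float(_condition_direction(c, data)) for c in rule]
            dir_cache[rule] = d
        return d

    rule_mults = [(d.rule, d.multiplicity) for d in working]
    boot_stats = []  # per bootstrap: {rule: (mult, I, count, pred, err,
    #                                  feat rows, pair rows)}
    for b in range(params.B):
        rng = np.random.default_rng([params.seed, b])
        idx = rng.integers(0, n, size=nb)
        y_b = y[idx]
        ybar_b = float(y_b.mean())
        rules_b: dict = {}
        for rule, mult in rule_mults:
            sliced = [cmask(c)[idx] for c in rule]
            sup = np.logical_and.reduce(sliced)
            if not sup.any():
                continue
            conds2, _ = _prune_conditions(
                list(rule), sliced, y_b, task, tolerance
            )
            if not conds2:
                continue  # pruned to the trivial decision
            rule2 = make_rule(conds2)
            rules_b[rule2] = rules_b.get(rule2, 0) + mult
        stats_b: dict = {}
        for rule2, mult in rules_b.items():
            sup = full_support(rule2)[idx]
            c = int(sup.sum())
            ys = y_b[sup]
            pred = float(ys.mean())
            err = error_on(ys, pred, task)
            abar = error_on(ys, ybar_b, task)
            kappa = 0.0 if abar == 0.0 else 1.0 - err / abar
            I = kappa * c * mult
            dirs = directions(rule2)
            rms = removed_masks(rule2)
            feats = []
            for i, cond in enumerate(rule2):
                m = rms[i][idx]
                pred_rm = float(y_b[m].mean())
                delta = error_on(ys, pred_rm, task) - err
                ydiff = pred - pred_rm
                feats.append(
                    (cond.feature, delta, dirs[i], ydiff, dirs[i] * ydiff)
                )
            pairs = []
            for (i, j), pm in pair_masks(rule2).items():
                m = pm[idx]
                pred_rm = float(y_b[m].mean())
                ydiff2 = pred - pred_rm
                from .metrics import _snap

                prod = _snap(feats[i][1]) * _snap(feats[j][1])
                d2 = math.sqrt(prod) if prod >= 0.0 else 0.0
                g2 = ((dirs[i] + dirs[j]) / 2.0) * ydiff2
                pairs.append(
                    (rule2[i].feature, rule2[j].feature, d2, ydiff2, g2,
                     dirs[i], dirs[j])
                )
            stats_b[rule2] = (mult, I, c, pred, err, feats, pairs)
        boot_stats.append(stats_b)

    d_mean = float(np.mean([len(s) for s in boot_stats]))
    q = stability_q(params.pi_thr, params.alpha_reg, d_mean)

    sel_count: dict = {}
    for stats_b in boot_stats:
        order = sorted(
            stats_b.items(),
            key=lambda kv: (-kv[1][1], -kv[1][2], rule_to_string(kv[0])),
        )
        for rule2, _ in order[:q]:
            sel_count[rule2] = sel_count.get(rule2, 0) + 1

    pool_rules = sorted(
        {r for s in boot_stats for r in s}, key=rule_to_string
    )
    index = {r: i for i, r in enumerate(pool_rules)}
    D = len(pool_rules)
    n_present = np.zeros(D)
    sums = {k: np.zeros(D) for k in ("I", "pred", "err", "cnt", "mult")}
    feat_acc: dict = {}
    pair_acc: dict = {}
    for stats_b in boot_stats:
        for rule2, (mult, I, c, pred, err, feats, pairs) in stats_b.items():
            i = index[rule2]
            n_present[i] += 1
            sums["I"][i] += I
            sums["pred"][i] += pred
            sums["err"][i] += err
            sums["cnt"][i] += c
            sums["mult"][i] += mult
            for feature, delta, direction, ydiff, gamma in feats:
                key = (i, feature)
                acc = feat_acc.setdefault(key, [0.0, 0.0, 0.0, direction, 0])
                acc[0] += delta
                acc[1] += ydiff
                acc[2] += gamma
                acc[4] += 1
            for fa, fb, d2, ydiff2, g2, da, db in pairs:
                key = (i, fa, fb)
                acc = pair_acc.setdefault(key, [0.0, 0.0, 0.0, da, db, 0])
                acc[0] += d2
                acc[1] += ydiff2
                acc[2] += g2
                acc[5] += 1

    mean = {k: sums[k] / n_present for k in sums}
    feat = pd.DataFrame(
        [
            {
                "decision": i,
                "feature": f,
                "delta": acc[0] / acc[4],
                "direction": acc[3],
                "ydiff": acc[1] / acc[4],
                "gamma": acc[2] / acc[4],
            }
            for (i, f), acc in sorted(feat_acc.items())
        ],
        columns=["decision", "feature", "delta", "direction", "ydiff", "gamma"],
    )
    pairs_frame = pd.DataFrame(
        [
            {
                "decision": i,
                "feature_a": fa,
                "feature_b": fb,
                "delta": acc[0] / acc[5],
                "ydiff": acc[1] / acc[5],
                "gamma": acc[2] / acc[5],
                "dir_a": acc[3],
                "dir_b": acc[4],
            }
            for (i, fa, fb), acc in sorted(pair_acc.items())
        ],
        columns=["decision", "feature_a", "feature_b", "delta", "ydiff",
                 "gamma", "dir_a", "dir_b"],
    )

    decisions = []
    for i, rule in enumerate(pool_rules):
        d = decision_from_rule(
            rule, data, multiplicity=max(1, int(round(mean["mult"][i])))
        )
        d.importance = float(mean["I"][i])
        d.selection_probability = sel_count.get(rule, 0) / params.B
        decisions.append(d)
    pool = DecisionEnsemble(decisions=decisions, data=data)
    sel_prob = np.array(
        [sel_count.get(r, 0) / params.B for r in pool_rules]
    )
    pool_metrics = DecisionMetrics(
        importance=mean["I"],
        kappa=np.full(D, np.nan),
        prediction=mean["pred"],
        error=mean["err"],
        n_support=mean["cnt"],
        present=np.ones(D, dtype=bool),
        feat=feat,
        pairs=pairs_frame,
    )
    return StableEnsemble(
        pool=pool,
        pool_metrics=pool_metrics,
        selection_probability=sel_prob,
        q=q,
        d_mean=d_mean,
        params=params,
    )


def trivial_stable(ensemble: DecisionEnsemble,
                   params: Optional[StabilityParams] = None) -> StableEnsemble:
    """Wrap an ensemble as if every (non-trivial) decision were stable.

    Used when stability selection is switched off: full-data metrics,
    selection probability 1 everywhere.
    """
    working = [d for d in ensemble.decisions if len(d.rule) > 0]
    pool = DecisionEnsemble(decisions=working, data=ensemble.data)
    dm = compute_decision_metrics(pool)
    for i, d in enumerate(working):
        d.importance = float(dm.importance[i])
        d.selection_probability = 1.0
    params = params or StabilityParams()
    return StableEnsemble(
        pool=pool,
        pool_metrics=dm,
        selection_probability=np.ones(len(working)),
        q=max(1, len(working)),
        d_mean=float(len(working)),
        params=params,
    )
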