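"""Straight-line brute-force re-implementation of every ensemble metric.

Deliberately written as naive loops over samples and decisions, sharing no
code with the package: it serves as the independent oracle the vectorized
implementation is pinned against.  Only rule *evaluation* (membership of a
sample in a rule's support) reuses the package's condition masks, since the
quantities under test are the metrics, not the masks.
"""

import math

import numpy as np


def alpha(y_vals, yhat, task):
    if len(y_vals) == 0:
        return math.nan
    if task == "regression":
        return sum((v - yhat) ** 2 for v in y_vals) / len(y_vals)
    total = 0.0
    for v in y_vals:
        total += 1.0 - (yhat ** v) * ((1.0 - yhat) ** (1.0 - v))
    return total / len(y_vals)


def brute_force_metrics(ensemble):
    """Recompute I, delta, direction, gamma per decision and F, Gamma, eta
    aggregates with plain loops.  Returns nested dicts keyed by decision
    index / feature name / unordered feature pair."""
    data = ensemble.data
    y = list(data.y)
    task = data.task
    n = len(y)
    ybar = sum(y) / n

    per_decision = {}
    for di, d in enumerate(ensemble.decisions):
        sup = [i for i in range(n) if d.support[i]]
        ys = [y[i] for i in sup]
        yhat = sum(ys) / len(ys)
        a_self = alpha(ys, yhat, task)
        a_bar = alpha(ys, ybar, task)
        kappa = 0.0 if a_bar == 0 else 1.0 - a_self / a_bar
        importance = kappa * len(sup) * d.multiplicity

        feats = {}
        for cond in d.rule:
            # removed decision: support of the rule minus this condition
            keep = [c for c in d.rule if c.feature != cond.feature]
            rm_mask = np.ones(n, dtype=bool)
            for c in keep:
                rm_mask &= c.mask(data)
            rm_sup = [i for i in range(n) if rm_mask[i]]
            yhat_rm = sum(y[i] for i in rm_sup) / len(rm_sup)
            delta = alpha(ys, yhat_rm, task) - a_self
            # direction: mean rank of admitted levels vs all levels,
            # or condition mean vs overall mean for numeric intervals
            if cond.levels is not None:
                order = list(data.levels(cond.feature))
                ranks = {lab: i + 1 for i, lab in enumerate(order)}
                mean_adm = sum(ranks[l] for l in cond.levels) / len(cond.levels)
                mean_all = sum(ranks.values()) / len(ranks)
                direction = 1.0 if mean_adm >= mean_all else -1.0
            else:
                x = data.numeric(cond.feature)
                cm = cond.mask(data)
                direction = (
                    1.0 if x[cm].mean() >= x.mean() else -1.0
                ) if cm.any() else 1.0
            ydiff = yhat - yhat_rm
            feats[cond.feature] = {
                "delta": delta,
                "direction": direction,
                "gamma": direction * ydiff,
                "ydiff": ydiff,
            }

        pairs = {}
        names = sorted(feats)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                fa, fb = names[i], names[j]
                keep = [c for c in d.rule if c.feature not in (fa, fb)]
                rm_mask = np.ones(n, dtype=bool)
                for c in keep:
                    rm_mask &= c.mask(data)
                rm_sup = [i2 for i2 in range(n) if rm_mask[i2]]
                yhat_rm = sum(y[i2] for i2 in rm_sup) / len(rm_sup)
                def snap(v):
                    return 0.0 if abs(v) < 1e-12 else v

                prod = snap(feats[fa]["delta"]) * snap(feats[fb]["delta"])
                delta2 = math.sqrt(prod) if prod >= 0 else 0.0
                da, db = feats[fa]["direction"], feats[fb]["direction"]
                gamma2 = ((da + db) / 2.0) * (yhat - yhat_rm)
                pairs[(fa, fb)] = {
                    "delta": delta2,
                    "gamma": gamma2,
                    "da": da,
                    "db": db,
                }
        per_decision[di] = {
            "importance": importance,
            "features": feats,
            "pairs": pairs,
        }

    # aggregates
    F = {}
    Gamma_num = {}
    Gamma_den = {}
    Fp = {}
    Gp_num = {}
    Gp_den = {}
    eta_sum = {}
    for di, rec in per_decision.items():
        I = rec["importance"]
        for f, st in rec["features"].items():
            F[f] = F.get(f, 0.0) + st["delta"] * I
            Gamma_num[f] = Gamma_num.get(f, 0.0) + st["gamma"] * I
            Gamma_den[f] = Gamma_den.get(f, 0.0) + I
        for pair, st in rec["pairs"].items():
            Fp[pair] = Fp.get(pair, 0.0) + st["delta"] * I
            Gp_num[pair] = Gp_num.get(pair, 0.0) + st["gamma"] * I
            Gp_den[pair] = Gp_den.get(pair, 0.0) + I
            eta_sum[pair] = eta_sum.get(pair, 0.0) + st["da"] * st["db"] * I
    Gamma = {
        f: (Gamma_num[f] / Gamma_den[f] if Gamma_den[f] != 0 else 0.0)
        for f in F
    }
    Gp = {
        p: (Gp_num[p] / Gp_den[p] if Gp_den[p] != 0 else 0.0) for p in Fp
    }
    eta = {p: float(np.sign(v)) for p, v in eta_sum.items()}
    return {
        "per_decision": per_decision,
        "F": F,
        "Gamma": Gamma,
        "F_pairs": Fp,
        "Gamma_pairs": Gp,
        "eta": eta,
    }


def random_mini_ensemble(rng, n_max=50, p_max=4, d_max=5, task="classification"):
    """A random small dataset + decision ensemble for oracle comparisons."""
    import pandas as pd

    from forestnet.decisions import (
        Condition,
        DecisionEnsemble,
        decision_from_rule,
        make_rule,
    )
    from forestnet.model_io import make_dataset

    n = int(rng.integers(10, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    cols = {}
    kinds = []
    for j in range(p):
        if rng.random() < 0.3:
            cols[f"C{j}"] = pd.Categorical(
                rng.choice(["u", "v", "w"], size=n)
            )
            kinds.append(("cat", f"C{j}"))
        else:
            cols[f"X{j}"] = rng.normal(0, 1, size=n)
            kinds.append(("num", f"X{j}"))
    X = pd.DataFrame(cols)
    if task == "classification":
        y = rng.integers(0, 2, size=n).astype(float)
    else:
        y = rng.normal(0, 1, size=n)
    try:
        data = make_dataset(X, y, task)
    except Exception:
        return None  # e.g. a single observed level: draw again

    decisions = []
    n_dec = int(rng.integers(1, d_max + 1))
    for _ in range(n_dec):
        chosen = rng.permutation(len(kinds))[: int(rng.integers(1, min(3, p) + 1))]
        conds = []
        for ci in chosen:
            kind, name = kinds[ci]
            if kind == "num":
                lo = float(rng.normal(0, 1))
                if rng.random() < 0.5:
                    conds.append(Condition(name, lo=lo))
                else:
                    conds.append(Condition(name, hi=lo))
            else:
                levels = [l for l in ("u", "v", "w") if rng.random() < 0.5]
                observed = set(data.levels(name))
                levels = [l for l in levels if l in observed]
                if not levels or set(levels) >= observed:
                    continue
                conds.append(Condition(name, levels=tuple(levels)))
        if not conds:
            continue
        d = decision_from_rule(
            make_rule(conds), data, multiplicity=int(rng.integers(1, 4))
        )
        if d is not None:
            decisions.append(d)
    if not decisions:
        return None
    return DecisionEnsemble(decisions=decisions, data=data)
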