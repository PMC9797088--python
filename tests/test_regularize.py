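import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestnet.decisions import (
    Condition,
    DecisionEnsemble,
    decision_from_rule,
    make_rule,
    rule_to_string,
)
from forestnet.errors import ConfigError
from forestnet.model_io import make_dataset
from forestnet.regularize import (
    StabilityParams,
    discretize,
    prune_decisions,
    stability_q,
    stability_select,
)


def uniform_data(n=1000, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x": rng.uniform(0, 1, n)})
    if extra:
        for k, v in extra.items():
            X[k] = v(rng, n)
    y = (X["x"] > 0.5).astype(float).to_numpy()
    return make_dataset(X, y, "classification")


class TestDiscretize:
    def test_median_condition_maps_to_low_exactly(self):
        data = uniform_data()
        med = float(np.quantile(data.numeric("x"), 0.5))
        d = decision_from_rule(make_rule([Condition("x", hi=med)]), data)
        ens = DecisionEnsemble(decisions=[d], data=data)
        new_data, dmap, new_ens = discretize(data, ens, K=2)
        assert len(new_ens) == 1
        cond = new_ens.decisions[0].rule[0]
        assert cond.levels == ("Low",)
        # the rewritten support is exactly the Low level
        assert (new_ens.decisions[0].support ==
                (new_data.codes("x") == 0)).all()

    def test_majority_rule_includes_partially_covered_level(self):
        # x < q90 with K=3: ~70% of High-level samples satisfy it, so all
        # levels admitted and the condition is dropped from the rule
        data2 = uniform_data(extra={"x2": lambda rng, n: rng.uniform(0, 1, n)})
        q90 = float(np.quantile(data2.numeric("x"), 0.9))
        d = decision_from_rule(
            make_rule([Condition("x", hi=q90), Condition("x2", lo=0.5)]),
            data2,
        )
        ens = DecisionEnsemble(decisions=[d], data=data2)
        _, _, new_ens = discretize(data2, ens, K=3)
        feats = {c.feature for dec in new_ens.decisions for c in dec.rule}
        assert "x" not in feats  # full-domain after rewriting

    def test_minority_covered_level_not_selected(self):
        # condition covers all of Low but only a minority of Medium
        data = uniform_data()
        q45 = float(np.quantile(data.numeric("x"), 0.45))
        d = decision_from_rule(make_rule([Condition("x", hi=q45)]), data)
        ens = DecisionEnsemble(decisions=[d], data=data)
        _, _, new_ens = discretize(data, ens, K=3)
        assert new_ens.decisions[0].rule[0].levels == ("Low",)

    def test_too_few_distinct_values_kept_unsplit(self, caplog):
        import logging

        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"b": rng.integers(0, 2, 100).astype(float),
             "x": rng.uniform(0, 1, 100)}
        )
        y = (X["x"] > 0.5).astype(float).to_numpy()
        data = make_dataset(X, y, "classification")
        d = decision_from_rule(make_rule([Condition("b", lo=0.5)]), data)
        ens = DecisionEnsemble(decisions=[d], data=data)
        with caplog.at_level(logging.WARNING):
            new_data, dmap, new_ens = discretize(data, ens, K=3)
        assert "b" not in dmap.features
        assert new_data.is_numeric("b")
        assert new_ens.decisions[0].rule[0].lo == 0.5  # untouched

    def test_rf_threshold_method_clusters_split_points(self):
        data = uniform_data()
        rules = [
            make_rule([Condition("x", hi=t)])
            for t in (0.30, 0.31, 0.29, 0.70, 0.71, 0.69)
        ]
        ens = DecisionEnsemble(
            decisions=[decision_from_rule(r, data) for r in rules], data=data
        )
        _, dmap, _ = discretize(data, ens, K=3, method="rf-thresholds")
        bps = dmap.breakpoints["x"]
        assert len(bps) == 2
        assert abs(bps[0] - 0.30) < 0.02 and abs(bps[1] - 0.70) < 0.02

    def test_k_below_two_rejected(self):
        data = uniform_data()
        ens = DecisionEnsemble(decisions=[], data=data)
        with pytest.raises(ConfigError):
            discretize(data, ens, K=1)

    def test_multiplicity_conserved(self, fsd_small):
        from forestnet.decisions import extract_decisions, group_duplicate_rules
        from forestnet.simulate import fit_forest

        data, _ = fsd_small
        spec = fit_forest(data, n_trees=10, max_depth=3, seed=1)
        ens = group_duplicate_rules(extract_decisions(spec, data))
        total = ens.total_multiplicity()
        new_data, _, disc = discretize(data, ens, K=2)
        # decisions dropped with empty admitted sets are the only loss
        assert disc.total_multiplicity() <= total
        pruned = prune_decisions(disc, new_data, 0.05)
        assert pruned.total_multiplicity() == disc.total_multiplicity()


class TestPrune:
    def test_irrelevant_condition_removed(self):
        rng = np.random.default_rng(3)
        n = 2000
        X = pd.DataFrame(
            {"signal": rng.normal(size=n), "junk": rng.normal(size=n)}
        )
        y = (X["signal"] > 0).astype(float).to_numpy()
        data = make_dataset(X, y, "classification")
        d = decision_from_rule(
            make_rule([Condition("signal", lo=0.0), Condition("junk", lo=0.0)]),
            data,
        )
        ens = DecisionEnsemble(decisions=[d], data=data)
        pruned = prune_decisions(ens, data, 0.05)
        feats = {c.feature for dec in pruned.decisions for c in dec.rule}
        assert feats == {"signal"}

    def test_zero_tolerance_keeps_informative_conditions(self, toy_ensemble):
        pruned = prune_decisions(toy_ensemble, tolerance=0.0)
        # nothing with a strictly positive error increase may be removed
        for before, after in zip(toy_ensemble.decisions, pruned.decisions):
            assert len(after.rule) <= len(before.rule)

    def test_idempotent(self, fsd_small):
        from forestnet.decisions import extract_decisions, group_duplicate_rules
        from forestnet.simulate import fit_forest

        data, _ = fsd_small
        spec = fit_forest(data, n_trees=10, max_depth=3, seed=2)
        ens = group_duplicate_rules(extract_decisions(spec, data))
        once = prune_decisions(ens, data, 0.05)
        twice = prune_decisions(once, data, 0.05)

        def signature(e):
            return sorted(
                (rule_to_string(d.rule), d.multiplicity) for d in e.decisions
            )

        assert signature(once) == signature(twice)


class TestStabilityParams:
    def test_defaults_match_convention(self):
        p = StabilityParams()
        assert (p.pi_thr, p.alpha_reg, p.B, p.resample_fraction) == (
            0.7, 1.0, 10, 0.5
        )

    @pytest.mark.parametrize(
        "kwargs", [{"B": 0}, {"pi_thr": 0.5}, {"pi_thr": 1.2},
                   {"alpha_reg": 0.0}, {"resample_fraction": 0.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            StabilityParams(**kwargs).validate()


class TestQFormula:
    def test_worked_values(self):
        assert stability_q(0.7, 1.0, 100) == 40
        assert stability_q(0.7, 1.0, 1) == 1

    @given(
        st.floats(0.51, 1.0), st.floats(0.1, 10.0), st.integers(1, 10_000)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, pi, alpha, d):
        q = stability_q(pi, alpha, d)
        assert stability_q(min(pi + 0.05, 1.0), alpha, d) >= q
        assert stability_q(pi, alpha * 1.5, d) >= q
        assert stability_q(pi, alpha, d + 100) >= q
        assert q >= 1


class TestStabilitySelect:
    def test_single_bootstrap_keeps_top_q(self, toy_ensemble, toy_data):
        params = StabilityParams(B=1, pi_thr=0.7, alpha_reg=1.0, seed=4)
        stable = stability_select(toy_data, toy_ensemble, params)
        # with B=1 every selected decision has probability exactly 1 and the
        # stable set is the top-q of the single resample
        probs = stable.selection_probability
        assert set(np.unique(probs)) <= {0.0, 1.0}
        assert len(stable) == int((probs == 1.0).sum())
        assert len(stable) <= stable.q

    def test_same_seed_reproducible(self, toy_ensemble, toy_data):
        p = StabilityParams(B=5, seed=11)
        s1 = stability_select(toy_data, toy_ensemble, p)
        s2 = stability_select(toy_data, toy_ensemble, p)
        assert np.array_equal(
            s1.selection_probability, s2.selection_probability
        )
        assert s1.q == s2.q and s1.d_mean == s2.d_mean

    def test_decision_order_invariant(self, toy_ensemble, toy_data):
        p = StabilityParams(B=5, seed=11)
        s1 = stability_select(toy_data, toy_ensemble, p)
        reversed_ens = DecisionEnsemble(
            decisions=list(reversed(toy_ensemble.decisions)), data=toy_data
        )
        s2 = stability_select(toy_data, reversed_ens, p)
        probs1 = {
            rule_to_string(d.rule): s1.selection_probability[i]
            for i, d in enumerate(s1.pool.decisions)
        }
        probs2 = {
            rule_to_string(d.rule): s2.selection_probability[i]
            for i, d in enumerate(s2.pool.decisions)
        }
        assert probs1 == probs2

    def test_retained_probability_at_least_pi_thr(self, toy_ensemble, toy_data):
        stable = stability_select(
            toy_data, toy_ensemble, StabilityParams(B=10, seed=1)
        )
        for d in stable.decisions:
            assert d.selection_probability >= stable.params.pi_thr - 1e-12

    def test_per_bootstrap_pruning_mode_runs(self, fsd_small):
        from forestnet.decisions import extract_decisions, group_duplicate_rules
        from forestnet.simulate import fit_forest

        data, _ = fsd_small
        spec = fit_forest(data, n_trees=20, max_depth=3, seed=5)
        ens = group_duplicate_rules(extract_decisions(spec, data))
        new_data, dmap, disc = discretize(data, ens, K=2)
        stable = stability_select(
            new_data, disc, StabilityParams(B=5, seed=5), prune_tolerance=0.05
        )
        assert stable.d_mean > 0
        # averaged metrics exist for every pooled decision
        assert np.isfinite(stable.pool_metrics.importance).all()
        assert len(stable.pool) == len(stable.selection_probability)
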