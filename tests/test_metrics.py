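import numpy as np
import pandas as pd
import pytest

from oracle_utils import brute_force_metrics, random_mini_ensemble

from forestnet.decisions import (
    Condition,
    DecisionEnsemble,
    decision_from_rule,
    make_rule,
)
from forestnet.errors import DataError
from forestnet.metrics import (
    aggregate_metrics,
    complement_decision,
    compute_decision_metrics,
    decision_importance,
    direction_indicator,
    feature_delta,
    influence_delta,
    interaction_delta,
    removed_decision,
)
from forestnet.model_io import make_dataset


def single_decision(data, *conds):
    return decision_from_rule(make_rule(list(conds)), data)


class TestModifiedDecisions:
    def test_removed_feature_widens_support(self, toy_data):
        d = single_decision(
            toy_data, Condition("V1", lo=0.5), Condition("grp", levels=("a",))
        )
        rm = removed_decision(d, "V1", toy_data)
        assert set(c.feature for c in rm.rule) == {"grp"}
        grp_a = toy_data.X["grp"].eq("a").to_numpy()
        assert (rm.support == grp_a).all()
        assert rm.support.sum() >= d.n_support

    def test_removing_only_condition_gives_global_mean(self, toy_data):
        d = single_decision(toy_data, Condition("V1", lo=0.5))
        rm = removed_decision(d, "V1", toy_data)
        assert rm.support.all()
        assert rm.prediction == pytest.approx(toy_data.ybar)

    def test_removing_pair(self, toy_data):
        d = single_decision(
            toy_data,
            Condition("V1", lo=0.5),
            Condition("grp", levels=("a",)),
            Condition("V2", lo=0.0),
        )
        rm = removed_decision(d, ("V1", "grp"), toy_data)
        expect = Condition("V2", lo=0.0).mask(toy_data)
        assert (rm.support == expect).all()

    def test_removing_inactive_feature_rejected(self, toy_data):
        d = single_decision(toy_data, Condition("V1", lo=0.5))
        with pytest.raises(DataError):
            removed_decision(d, "V2", toy_data)

    def test_complement_partitions_removed_support(self, toy_data):
        d = single_decision(
            toy_data, Condition("V1", lo=0.5), Condition("grp", levels=("a",))
        )
        comp = complement_decision(d, "V1", toy_data)
        rm = removed_decision(d, "V1", toy_data)
        assert not (comp.support & d.support).any()
        assert ((comp.support | d.support) == rm.support).all()


class TestDecisionImportance:
    def test_hand_value(self):
        # |S|=10, alpha(S, yhat)=0.1, alpha(S, ybar)=0.5 -> I = 8
        # regression: support residuals give alpha exactly
        y = np.array(
            [1.0] * 5 + [-1.0] * 5 + [0.0] * 10
        )  # support = first 10, ybar over all = 0
        X = pd.DataFrame({"x": np.r_[np.ones(10), np.zeros(10)]})
        data = make_dataset(X, y, "regression")
        d = single_decision(data, Condition("x", lo=0.5))
        # on support: mean = 0, alpha(S, 0) = 1.0; craft importance formula
        assert decision_importance(d, data) == pytest.approx(
            (1 - 1.0 / 1.0) * 10
        )

    def test_perfect_prediction_gives_support_size(self):
        y = np.array([1.0] * 6 + [0.0] * 6)
        X = pd.DataFrame({"x": np.r_[np.ones(6), np.zeros(6)]})
        data = make_dataset(X, y, "classification")
        d = single_decision(data, Condition("x", lo=0.5))
        assert decision_importance(d, data) == pytest.approx(6.0)

    def test_linear_in_multiplicity(self, toy_data):
        d1 = single_decision(toy_data, Condition("V1", lo=0.5))
        d3 = decision_from_rule(d1.rule, toy_data, multiplicity=3)
        assert decision_importance(d3, toy_data) == pytest.approx(
            3 * decision_importance(d1, toy_data)
        )

    def test_constant_response_gives_zero_not_nan(self):
        # alpha(S, ybar) = 0 when the response is constant: importance is
        # defined as 0 rather than a division error
        y = np.ones(6)
        X = pd.DataFrame({"x": np.array([1.0, 1, 1, 0, 0, 0])})
        data = make_dataset(X, y, "classification")
        d = single_decision(data, Condition("x", lo=0.5))
        assert decision_importance(d, data) == 0.0

    def test_importance_can_be_negative(self):
        # support proportion 0.3 but global mean 0.1: kappa < 0
        y = np.array([1.0, 1, 1, 0, 0, 0, 0, 0, 0, 0] + [0.0] * 20)
        X = pd.DataFrame({"x": np.r_[np.ones(10), np.zeros(20)]})
        data = make_dataset(X, y, "classification")
        d = single_decision(data, Condition("x", lo=0.5))
        assert decision_importance(d, data) < 0
        # and a positive case on the same dataset
        d2 = single_decision(data, Condition("x", hi=0.5))
        assert decision_importance(d2, data) > 0


class TestFeatureDelta:
    def test_single_condition_identity(self, toy_data):
        from forestnet.decisions import error_on

        d = single_decision(toy_data, Condition("V1", lo=0.5))
        delta = feature_delta(d, "V1", toy_data)
        ys = toy_data.y[d.support]
        alpha_bar = error_on(ys, toy_data.ybar, "classification")
        identity = delta * d.n_support / alpha_bar
        assert identity == pytest.approx(
            decision_importance(d, toy_data) / d.multiplicity
        )

    def test_irrelevant_feature_has_tiny_delta(self):
        rng = np.random.default_rng(5)
        n = 4000
        X = pd.DataFrame(
            {"signal": rng.normal(size=n), "junk": rng.normal(size=n)}
        )
        y = (X["signal"] > 0).astype(float).to_numpy()
        data = make_dataset(X, y, "classification")
        d = single_decision(
            data, Condition("signal", lo=0.0), Condition("junk", lo=0.0)
        )
        assert abs(feature_delta(d, "junk", data)) < 0.02
        assert feature_delta(d, "signal", data) > 0.2


class TestInteractionDelta:
    def test_sqrt_of_product(self, monkeypatch):
        import forestnet.metrics as M

        deltas = {"a": 0.04, "b": 0.09}
        monkeypatch.setattr(
            M, "feature_delta", lambda D, j, data: deltas[j]
        )
        assert M.interaction_delta(None, "a", "b", None) == pytest.approx(0.06)

    def test_negative_product_clamped(self, monkeypatch):
        import forestnet.metrics as M

        deltas = {"a": -0.04, "b": 0.09}
        monkeypatch.setattr(M, "feature_delta", lambda D, j, data: deltas[j])
        assert M.interaction_delta(None, "a", "b", None) == 0.0

    def test_symmetric(self, toy_data):
        d = single_decision(
            toy_data, Condition("V1", lo=0.5), Condition("V2", lo=0.0)
        )
        assert interaction_delta(d, "V1", "V2", toy_data) == pytest.approx(
            interaction_delta(d, "V2", "V1", toy_data)
        )


class TestDirection:
    @pytest.fixture
    def leveled(self):
        X = pd.DataFrame(
            {
                "f2": pd.Categorical(
                    ["Low", "High"] * 6, categories=["Low", "High"],
                    ordered=True,
                ),
                "f3": pd.Categorical(
                    ["Low", "Med", "High"] * 4,
                    categories=["Low", "Med", "High"], ordered=True,
                ),
            }
        )
        y = np.tile([0.0, 1.0], 6)
        return make_dataset(X, y, "classification")

    def test_high_of_two_levels_is_positive(self, leveled):
        d = single_decision(leveled, Condition("f2", levels=("High",)))
        assert direction_indicator(d, "f2", leveled) == 1

    def test_low_of_two_levels_is_negative(self, leveled):
        d = single_decision(leveled, Condition("f2", levels=("Low",)))
        assert direction_indicator(d, "f2", leveled) == -1

    def test_top_two_of_three_levels_positive(self, leveled):
        d = single_decision(leveled, Condition("f3", levels=("Med", "High")))
        # mean rank 2.5 > 2
        assert direction_indicator(d, "f3", leveled) == 1

    def test_numeric_interval_direction(self, toy_data):
        hi = single_decision(toy_data, Condition("V1", lo=1.0))
        lo = single_decision(toy_data, Condition("V1", hi=0.0))
        assert direction_indicator(hi, "V1", toy_data) == 1
        assert direction_indicator(lo, "V1", toy_data) == -1


class TestInfluence:
    def test_direction_flips_sign(self, toy_data):
        d_hi = single_decision(toy_data, Condition("V1", lo=1.0))
        d_lo = single_decision(toy_data, Condition("V1", hi=0.0))
        g_hi = influence_delta(d_hi, "V1", toy_data)
        rm_hi = removed_decision(d_hi, "V1", toy_data)
        assert g_hi == pytest.approx(d_hi.prediction - rm_hi.prediction)
        rm_lo = removed_decision(d_lo, "V1", toy_data)
        g_lo = influence_delta(d_lo, "V1", toy_data)
        assert g_lo == pytest.approx(-(d_lo.prediction - rm_lo.prediction))

    def test_opposite_directions_zero_pair_influence(self, toy_data):
        d = single_decision(
            toy_data, Condition("V1", lo=1.0), Condition("V2", hi=0.0)
        )
        assert influence_delta(d, ("V1", "V2"), toy_data) == 0.0


class TestAggregates:
    def test_single_decision_sums(self, toy_data):
        d = single_decision(
            toy_data, Condition("V1", lo=0.5), Condition("grp", levels=("a",))
        )
        ens = DecisionEnsemble(decisions=[d], data=toy_data)
        dm = compute_decision_metrics(ens)
        fm, im = aggregate_metrics(ens, dm)
        I = dm.importance[0]
        row = fm.table.set_index("feature").loc["V1"]
        assert row["importance"] == pytest.approx(
            feature_delta(d, "V1", toy_data) * I
        )
        assert row["influence"] == pytest.approx(
            influence_delta(d, "V1", toy_data)
        )
        assert len(im.table) == 1

    def test_unused_feature_absent(self, toy_ensemble, toy_data):
        dm = compute_decision_metrics(toy_ensemble)
        fm, _ = aggregate_metrics(toy_ensemble, dm)
        assert set(fm.table["feature"]) <= {"V1", "V2", "grp"}

    def test_adding_unused_column_changes_nothing(self, toy_data, toy_ensemble):
        dm = compute_decision_metrics(toy_ensemble)
        fm1, im1 = aggregate_metrics(toy_ensemble, dm)
        X2 = toy_data.X.copy()
        X2["noise"] = np.linspace(0, 1, toy_data.n)
        data2 = make_dataset(X2, toy_data.y, "classification")
        ens2 = DecisionEnsemble(
            decisions=[
                decision_from_rule(d.rule, data2)
                for d in toy_ensemble.decisions
            ],
            data=data2,
        )
        dm2 = compute_decision_metrics(ens2)
        fm2, im2 = aggregate_metrics(ens2, dm2)
        pd.testing.assert_frame_equal(fm1.table, fm2.table)
        pd.testing.assert_frame_equal(im1.table, im2.table)

    def test_influence_is_importance_weighted_mean(self):
        y = np.array([1.0, 1, 0, 0, 1, 0, 1, 0])
        X = pd.DataFrame({"x": np.array([1.0, 1, 0, 0, 1, 1, 0, 0])})
        data = make_dataset(X, y, "classification")
        hi = single_decision(data, Condition("x", lo=0.5))
        lo = single_decision(data, Condition("x", hi=0.5))
        ens = DecisionEnsemble(decisions=[hi, lo], data=data)
        dm = compute_decision_metrics(ens)
        fm, _ = aggregate_metrics(ens, dm)
        g1 = influence_delta(hi, "x", data)
        g2 = influence_delta(lo, "x", data)
        I1 = decision_importance(hi, data)
        I2 = decision_importance(lo, data)
        expected = (g1 * I1 + g2 * I2) / (I1 + I2)
        assert fm.table.set_index("feature").loc["x", "influence"] == (
            pytest.approx(expected)
        )


class TestBruteForceOracle:
    """The vectorized engine agrees with a straight-line reimplementation."""

    @pytest.mark.parametrize("task", ["classification", "regression"])
    def test_random_mini_ensembles(self, task):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 30:
            ens = random_mini_ensemble(rng, task=task)
            if ens is None:
                continue
            checked += 1
            expected = brute_force_metrics(ens)
            dm = compute_decision_metrics(ens)
            for di, rec in expected["per_decision"].items():
                assert dm.importance[di] == pytest.approx(
                    rec["importance"], abs=1e-10
                )
                sub = dm.feat[dm.feat["decision"] == di]
                for _, r in sub.iterrows():
                    ref = rec["features"][r["feature"]]
                    assert r["delta"] == pytest.approx(ref["delta"], abs=1e-10)
                    assert r["direction"] == ref["direction"]
                    assert r["gamma"] == pytest.approx(ref["gamma"], abs=1e-10)
                subp = dm.pairs[dm.pairs["decision"] == di]
                for _, r in subp.iterrows():
                    key = tuple(sorted((r["feature_a"], r["feature_b"])))
                    ref = rec["pairs"][key]
                    assert r["delta"] == pytest.approx(ref["delta"], abs=1e-10)
                    assert r["gamma"] == pytest.approx(ref["gamma"], abs=1e-10)
            fm, im = aggregate_metrics(ens, dm)
            for _, r in fm.table.iterrows():
                assert r["importance"] == pytest.approx(
                    expected["F"][r["feature"]], abs=1e-10
                )
                assert r["influence"] == pytest.approx(
                    expected["Gamma"][r["feature"]], abs=1e-10
                )
            for _, r in im.table.iterrows():
                key = (r["feature_a"], r["feature_b"])
                assert r["importance"] == pytest.approx(
                    expected["F_pairs"][key], abs=1e-10
                )
                assert r["influence"] == pytest.approx(
                    expected["Gamma_pairs"][key], abs=1e-10
                )
                assert r["eta"] == expected["eta"][key]
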