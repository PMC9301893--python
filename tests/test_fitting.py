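"""Quantile summaries, the chi-square objective, and the DE fit contract."""

import numpy as np
import pandas as pd
import pytest

from vratio import FitConfig, fit_ddm, predict_summary
from vratio.confidence import ConfidenceScaleSpec
from vratio.ddm import TrialDataset
from vratio.fitting import (
    QuantileSummary,
    chisquare_distance,
    make_objective,
    quantile_summary,
    summary_from_arrays,
)

SIX = ConfidenceScaleSpec.six_point()


def _tiny_dataset(rt, accuracy, confidence, confidence_rt=None):
    n = len(rt)
    df = pd.DataFrame(
        {
            "stimulus": [1] * n,
            "choice": [1 if a else -1 for a in accuracy],
            "accuracy": list(accuracy),
            "rt": rt,
            "confidence": confidence,
            "confidence_rt": confidence_rt or [0.5] * n,
        }
    )
    return TrialDataset(trials=df)


class TestQuantileSummary:
    def test_ten_all_correct_rts(self):
        rt = [0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75]
        ds = _tiny_dataset(rt, [True] * 10, [4.0] * 10)
        s = quantile_summary(ds, SIX)
        np.testing.assert_allclose(s.rt_props_correct, [0.1, 0.2, 0.2, 0.2, 0.2, 0.1])
        # error class is empty -> single collapsed bin with zero mass
        np.testing.assert_allclose(s.rt_props_error, [0.0])

    def test_mass_conservation(self, small_dataset):
        _, ds = small_dataset
        s = quantile_summary(ds, SIX)
        assert s.rt_props_correct.sum() + s.rt_props_error.sum() == pytest.approx(1.0)
        assert s.conf_props_correct.sum() + s.conf_props_error.sum() == pytest.approx(1.0)
        for block in s.prop_blocks():
            assert np.all(np.asarray(block) >= 0)

    def test_six_bins_per_class(self, small_dataset):
        _, ds = small_dataset
        s = quantile_summary(ds, SIX)
        assert s.rt_props_correct.size == 6
        assert s.conf_props_correct.size == 6  # one per discrete level

    def test_sparse_class_collapses(self):
        rt = np.array([0.3] * 20 + [0.4] * 3)
        acc = np.array([True] * 20 + [False] * 3)
        s = summary_from_arrays(rt, acc, np.full(23, 3.0), SIX)
        assert s.rt_edges_error is None
        np.testing.assert_allclose(s.rt_props_error, [3 / 23])

    def test_continuous_confidence_uses_quantiles(self):
        rng = np.random.default_rng(3)
        s = summary_from_arrays(rng.uniform(0.3, 1.0, 100), rng.random(100) < 0.8,
                                rng.uniform(0, 100, 100),
                                ConfidenceScaleSpec.continuous(0, 100))
        assert s.conf_kind == "quantiles"
        assert s.conf_props_correct.size == 6


def _two_bin_summary(rt_correct_props):
    """Summary with one meaningful two-bin RT block; other blocks contribute 0."""
    return QuantileSummary(
        edges=(0.5,),
        rt_edges_correct=np.array([0.5]),
        rt_edges_error=None,
        rt_props_correct=np.asarray(rt_correct_props, float),
        rt_props_error=np.array([0.0]),
        conf_kind="levels",
        conf_levels=np.array([1.0]),
        conf_edges_correct=None,
        conf_edges_error=None,
        conf_props_correct=np.array([1.0]),
        conf_props_error=np.array([0.0]),
    )


class TestChisquareDistance:
    def test_zero_when_equal(self, small_dataset):
        _, ds = small_dataset
        s = quantile_summary(ds, SIX)
        assert chisquare_distance(s, s) == 0.0

    def test_hand_value(self):
        o = _two_bin_summary([0.5, 0.5])
        p = _two_bin_summary([0.25, 0.75])
        assert chisquare_distance(o, p) == pytest.approx(
            0.25**2 / 0.25 + 0.25**2 / 0.75, abs=1e-12
        )

    def test_quadratic_scaling(self):
        p = _two_bin_summary([0.25, 0.75])
        full = chisquare_distance(_two_bin_summary([0.5, 0.5]), p)
        half = chisquare_distance(_two_bin_summary([0.375, 0.625]), p)
        assert half == pytest.approx(full / 4.0, abs=1e-12)

    def test_structure_mismatch_rejected(self):
        o = _two_bin_summary([0.5, 0.5])
        bad = QuantileSummary(
            edges=(0.5,), rt_edges_correct=None, rt_edges_error=None,
            rt_props_correct=np.array([1.0]), rt_props_error=np.array([0.0]),
            conf_kind="levels", conf_levels=np.array([1.0]),
            conf_edges_correct=None, conf_edges_error=None,
            conf_props_correct=np.array([1.0]), conf_props_error=np.array([0.0]),
        )
        with pytest.raises(ValueError):
            chisquare_distance(o, bad)


class TestObjective:
    def test_deterministic_across_calls_and_builds(self, small_dataset):
        _, ds = small_dataset
        cfg = FitConfig(n_sim=1500, seed=9)
        theta = np.array([2.0, 1.5, 0.4, 0.7, 2.5, 1.2])
        obj1, _, _, _ = make_objective(ds, SIX, cfg)
        obj2, _, _, _ = make_objective(ds, SIX, cfg)
        assert obj1(theta) == obj1(theta)
        assert obj1(theta) == obj2(theta)

    def test_trial_order_invariance(self, small_dataset):
        _, ds = small_dataset
        cfg = FitConfig(n_sim=1500, seed=9)
        shuffled = TrialDataset(
            trials=ds.trials.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        theta = np.array([2.0, 1.5, 0.4, 0.7, 2.5, 1.2])
        obj1, _, _, _ = make_objective(ds, SIX, cfg)
        obj2, _, _, _ = make_objective(shuffled, SIX, cfg)
        assert obj1(theta) == pytest.approx(obj2(theta), abs=1e-12)

    def test_self_consistency_at_truth(self, small_dataset):
        params, ds = small_dataset
        cfg = FitConfig(n_sim=8000, seed=5)
        obj, _, _, _ = make_objective(ds, SIX, cfg)
        at_truth = obj(np.array([params.drift_v, params.boundary_a, params.ter,
                                 params.v_ratio, params.conf_M, params.conf_SD]))
        off = obj(np.array([params.drift_v * 2, params.boundary_a * 2, params.ter,
                            params.v_ratio, params.conf_M, params.conf_SD]))
        assert at_truth < off
        assert at_truth < 0.5  # near the sampling-noise floor for 200 trials

    def test_more_sim_trials_reduce_objective_variance(self, small_dataset):
        params, ds = small_dataset
        theta = np.array([params.drift_v, params.boundary_a, params.ter,
                          params.v_ratio, params.conf_M, params.conf_SD])
        variances = {}
        for n_sim in (500, 8000):
            vals = [
                make_objective(ds, SIX, FitConfig(n_sim=n_sim, seed=seed))[0](theta)
                for seed in range(1, 9)
            ]
            variances[n_sim] = np.var(vals)
        assert variances[8000] < variances[500]


class TestPredictSummary:
    def test_deterministic_and_mass_one(self, small_dataset):
        params, ds = small_dataset
        observed = quantile_summary(ds, SIX)
        a = predict_summary(params, 2000, ds.confidence_rt, 77, SIX, observed)
        b = predict_summary(params, 2000, ds.confidence_rt, 77, SIX, observed)
        for x, y in zip(a.prop_blocks(), b.prop_blocks()):
            np.testing.assert_array_equal(x, y)
        assert a.rt_props_correct.sum() + a.rt_props_error.sum() == pytest.approx(1.0)
        assert a.conf_props_correct.sum() + a.conf_props_error.sum() == pytest.approx(1.0)


class TestFitDDM:
    def test_small_fit_contract(self, small_dataset):
        """A short DE run returns a valid result that dominates the generating
        parameters under the frozen objective."""
        params, ds = small_dataset
        cfg = FitConfig(n_sim=2000, population=42, max_generations=50,
                        stall_generations=50, seed=3)
        res = fit_ddm(ds, SIX, cfg)
        assert res.objective_value >= 0
        assert res.n_evaluations > 0
        assert len(res.drifts) == 1
        obj, _, _, _ = make_objective(ds, SIX, cfg)
        at_truth = obj(np.array([params.drift_v, params.boundary_a, params.ter,
                                 params.v_ratio, params.conf_M, params.conf_SD]))
        assert res.objective_value <= at_truth

    def test_fit_is_reproducible(self, small_dataset):
        _, ds = small_dataset
        cfg = FitConfig(n_sim=800, population=24, max_generations=6,
                        stall_generations=6, seed=11)
        r1 = fit_ddm(ds, SIX, cfg)
        r2 = fit_ddm(ds, SIX, cfg)
        assert r1.objective_value == r2.objective_value
        assert r1.params == r2.params

    def test_per_condition_drifts(self, small_dataset):
        _, ds = small_dataset
        df = ds.trials.copy()
        df["condition"] = np.where(np.arange(len(df)) % 2 == 0, "easy", "hard")
        ds2 = TrialDataset(trials=df)
        cfg = FitConfig(n_sim=600, population=21, max_generations=4,
                        stall_generations=4, seed=13)
        res = fit_ddm(ds2, SIX, cfg, condition_column="condition")
        assert len(res.drifts) == 2
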