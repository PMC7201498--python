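import math

import numpy as np
import pytest

import oracles
from pssmloc.errors import ParameterError, UsageError
from pssmloc.imbalance import (
    LabeledFeatureSet,
    Method,
    Placement,
    ResamplingPlan,
    Strategy,
)
from pssmloc.model_eval import (
    SvmConfig,
    confusion,
    grid_search_svm,
    jackknife,
    metrics,
    run_strategy,
)
from pssmloc.pssm_io import sigmoid_scale
from pssmloc.synthetic import SyntheticSpec, generate_feature_blobs, generate_pssms

FAST_CFG = SvmConfig(c_grid=(1.0, 32.0), gamma_grid=(0.01, 0.1), grid_mode="global")


def blobs(n_per_class, noise_sd=1.0, separation=10.0, seed=0, dim=5):
    spec = SyntheticSpec(n_per_class=n_per_class, noise_sd=noise_sd, seed=seed)
    return generate_feature_blobs(spec, dim=dim, separation=separation)


class TestConfusion:
    def test_perfect_prediction(self):
        y = ["a", "b", "b", "c"]
        cc = confusion(y, y)
        for lab in cc.labels:
            tp, fp, tn, fn = cc[lab]
            assert fp == 0 and fn == 0
            assert tp + fp + tn + fn == 4

    def test_constructed_binary_counts(self):
        y_true = ["p"] * 10 + ["n"] * 10
        y_pred = ["p"] * 9 + ["n"] + ["p"] * 2 + ["n"] * 8
        cc = confusion(y_true, y_pred)
        assert cc["p"] == (9, 2, 8, 1)  # TP, FP, TN, FN

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            confusion(["a"], ["a", "b"])

    def test_single_class_degenerate_sp(self):
        cc = confusion(["a", "a"], ["a", "a"])
        rep = metrics(cc)
        assert rep.per_class["a"]["Sp"] is None
        assert rep.undefined_counts["Sp"] == 1


class TestMetrics:
    def test_perfect_is_all_ones(self):
        rep = metrics(confusion(["a", "b", "a"], ["a", "b", "a"]))
        for m in rep.per_class.values():
            assert all(m[k] == pytest.approx(1.0) for k in ("Sn", "Sp", "F-m", "Mcc", "G-mean"))
        assert rep.oa == 1.0

    def test_hand_computed_binary_case(self):
        y_true = ["p"] * 10 + ["n"] * 10
        y_pred = ["p"] * 9 + ["n"] + ["p"] * 2 + ["n"] * 8
        rep = metrics(confusion(y_true, y_pred))
        m = rep.per_class["p"]
        assert m["Sn"] == pytest.approx(0.9)
        assert m["Sp"] == pytest.approx(0.8)
        assert m["G-mean"] == pytest.approx(math.sqrt(0.72), abs=1e-4)
        assert m["Mcc"] == pytest.approx((72 - 2) / math.sqrt(11 * 10 * 10 * 9), abs=1e-4)
        assert m["Mcc"] == pytest.approx(0.7035, abs=1e-4)

    def test_all_one_class_predictions_undefined_mcc(self):
        rep = metrics(confusion(["a", "b"], ["a", "a"]))
        assert rep.per_class["a"]["Mcc"] is None

    def test_oa_is_mean_correct_indicator(self, rng):
        y_true = rng.choice(list("abcd"), size=200)
        y_pred = rng.choice(list("abcd"), size=200)
        rep = metrics(confusion(y_true, y_pred))
        assert rep.oa == pytest.approx(float(np.mean(y_true == y_pred)))

    def test_macro_sn_is_mean_of_per_class(self, rng):
        y_true = rng.choice(list("abc"), size=100)
        y_pred = rng.choice(list("abc"), size=100)
        rep = metrics(confusion(y_true, y_pred))
        vals = [m["Sn"] for m in rep.per_class.values() if m["Sn"] is not None]
        assert rep.macro["Sn"] == pytest.approx(float(np.mean(vals)))

    def test_bruteforce_recount_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(2, 5))
            y_true = rng.integers(0, k, size=n).tolist()
            y_pred = rng.integers(0, k, size=n).tolist()
            rep = metrics(confusion(y_true, y_pred))
            exp_pc, exp_oa = oracles.naive_metrics(y_true, y_pred)
            assert rep.oa == pytest.approx(exp_oa)
            for lab, em in exp_pc.items():
                for name, v in em.items():
                    got = rep.per_class[lab][name]
                    if v is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(v, abs=1e-12)


class TestGridSearch:
    def test_separable_blobs_perfect_training(self):
        data = blobs((20, 20), noise_sd=0.5, separation=20.0)
        model, (c, g) = grid_search_svm(data, FAST_CFG)
        assert float(np.mean(model.predict(data.X) == data.y)) == 1.0
        assert c in FAST_CFG.c_grid and g in FAST_CFG.gamma_grid

    def test_degenerate_grid_returned(self):
        data = blobs((10, 10))
        cfg = SvmConfig(c_grid=(7.0,), gamma_grid=(0.3,))
        _, pair = grid_search_svm(data, cfg)
        assert pair == (7.0, 0.3)

    def test_single_class_rejected(self):
        data = blobs((10,))
        with pytest.raises(ParameterError):
            grid_search_svm(data, FAST_CFG)

    def test_dominated_cell_does_not_change_selection(self):
        data = blobs((15, 15), noise_sd=1.0, separation=8.0, seed=3)
        cfg_a = SvmConfig(c_grid=(1.0, 32.0), gamma_grid=(0.01,))
        # appended cell with absurd gamma cannot beat earlier cells
        cfg_b = SvmConfig(c_grid=(1.0, 32.0), gamma_grid=(0.01, 1e6))
        _, pa = grid_search_svm(data, cfg_a)
        _, pb = grid_search_svm(data, cfg_b)
        assert pa == pb


class TestJackknife:
    def test_separated_gaussians_high_oa(self):
        data = blobs((20, 20, 20), noise_sd=1.0, separation=10.0, seed=1)
        rep = jackknife(data, FAST_CFG)
        assert rep.oa >= 0.95
        assert rep.metadata["n_models"] == 60

    def test_byte_identical_reports(self):
        data = blobs((12, 12), noise_sd=1.5, separation=5.0, seed=2)
        plan = ResamplingPlan(method=Method.SMOTEENN, seed=7,
                              placement=Placement.BEFORE_CV)
        a = jackknife(data, FAST_CFG, plan).to_json()
        b = jackknife(data, FAST_CFG, plan).to_json()
        assert a == b

    def test_singleton_class_flagged(self):
        data = blobs((10, 10), seed=3)
        X = np.vstack([data.X, [[50.0] * 5]])
        y = np.append(data.y, "lonely")
        data2 = LabeledFeatureSet(X=X, y=y)
        rep = jackknife(data2, FAST_CFG)
        assert "lonely" in rep.metadata["singleton_classes"]
        assert rep.n == 21  # the singleton was still predicted

    def test_too_few_samples_rejected(self):
        data = blobs((1, 1, 1), dim=3)
        with pytest.raises(ParameterError):
            jackknife(data, FAST_CFG)

    def test_chance_level_on_pure_noise(self):
        data = blobs((60, 60), noise_sd=1.0, separation=0.0, seed=4)
        rep = jackknife(data, FAST_CFG)
        # 3-sigma binomial band around 0.5 at n=120 is about +/- 0.14
        assert abs(rep.oa - 0.5) < 0.15

    def test_train_fold_only_resampling(self):
        data = blobs((25, 8), noise_sd=1.0, separation=8.0, seed=5)
        plan = ResamplingPlan(method=Method.SMOTE, seed=5,
                              placement=Placement.TRAIN_FOLD_ONLY)
        rep = jackknife(data, FAST_CFG, plan)
        assert rep.oa >= 0.9
        assert rep.metadata["plan"]["placement"] == "TRAIN_FOLD_ONLY"


class TestRunStrategy:
    @pytest.fixture(scope="class")
    @staticmethod
    def collection():
        spec = SyntheticSpec(
            n_per_class=(14, 9, 7), length_range=(25, 45), noise_sd=1.5, seed=6
        )
        coll = generate_pssms(spec)
        mats = [sigmoid_scale(m) for m, _ in coll]
        labels = [lab for _, lab in coll]
        return mats, labels

    def test_none_plan_strategies_agree(self, collection):
        mats, labels = collection
        cfg = SvmConfig(c_grid=(1.0,), gamma_grid=(0.001,), grid_mode="global")
        a = run_strategy(mats, labels, xi=3, S=1,
                         plan=ResamplingPlan(strategy=Strategy.RESAMPLE_THEN_FUSE),
                         cfg=cfg)
        b = run_strategy(mats, labels, xi=3, S=1,
                         plan=ResamplingPlan(strategy=Strategy.FUSE_THEN_RESAMPLE),
                         cfg=cfg)
        assert a.y_pred == b.y_pred
        assert a.per_class == b.per_class
        assert a.oa == b.oa

    def test_strategy1_fused_width_589(self, collection):
        mats, labels = collection
        cfg = SvmConfig(c_grid=(1.0,), gamma_grid=(0.001,), grid_mode="global")
        plan = ResamplingPlan(method=Method.SMOTE, seed=1,
                              strategy=Strategy.RESAMPLE_THEN_FUSE,
                              placement=Placement.BEFORE_CV)
        rep = run_strategy(mats, labels, xi=13, S=1, plan=plan, cfg=cfg)
        assert rep.metadata["feature_widths"]["fused"] == 589

    def test_resampling_improves_macro_fm(self):
        # overlapping, imbalanced classes: fuse-then-resample should not hurt
        spec = SyntheticSpec(
            n_per_class=(30, 8), length_range=(25, 40), noise_sd=6.0, seed=7
        )
        coll = generate_pssms(spec)
        mats = [sigmoid_scale(m) for m, _ in coll]
        labels = [lab for _, lab in coll]
        cfg = SvmConfig(c_grid=(1.0, 32.0), gamma_grid=(1e-4, 1e-3), grid_mode="global")
        base = run_strategy(mats, labels, xi=3, S=1, plan=ResamplingPlan(), cfg=cfg)
        plan = ResamplingPlan(method=Method.SMOTEENN, seed=7,
                              strategy=Strategy.FUSE_THEN_RESAMPLE,
                              placement=Placement.BEFORE_CV)
        res = run_strategy(mats, labels, xi=3, S=1, plan=plan, cfg=cfg)
        assert res.macro["F-m"] >= base.macro["F-m"]
        assert res.macro["G-mean"] >= base.macro["G-mean"]
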