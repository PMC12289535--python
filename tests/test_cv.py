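import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icolike import Dataset
from icolike.cv import (
    CVSettings,
    FoldPlan,
    compute_metrics,
    force_always_train,
    make_fold_plan,
    restrict_fold_plan,
    run_outer_cv,
)
from icolike.exceptions import InputError

from .conftest import random_dataset
from .oracles import naive_loo_predictions


class TestMakeFoldPlan:
    def test_loo_gives_singleton_folds(self):
        plan = make_fold_plan(["a", "b", "c", "d"], 4, seed=0)
        assert plan.is_loo
        assert sorted(len(plan.fold_members(f)) for f in range(4)) == [1] * 4

    def test_k2_partitions_all_samples(self):
        plan = make_fold_plan(["a", "b", "c", "d"], 2, seed=0)
        members = [set(plan.fold_members(f)) for f in range(2)]
        assert all(len(m) == 2 for m in members)
        assert members[0] | members[1] == {"a", "b", "c", "d"}
        assert not members[0] & members[1]

    def test_always_train_never_held_out(self):
        plan = make_fold_plan(["a", "b", "c", "d"], 3, seed=0,
                              always_train={"d"})
        held_out = {s for f in range(3) for s in plan.fold_members(f)}
        assert held_out == {"a", "b", "c"}
        assert "d" in plan.universe

    def test_loo_string_alias(self):
        plan = make_fold_plan(["a", "b", "c"], "loo", seed=1)
        assert plan.k == 3 and plan.is_loo

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(11)]
        p1 = make_fold_plan(ids, 3, seed=42)
        p2 = make_fold_plan(ids, 3, seed=42)
        p3 = make_fold_plan(ids, 3, seed=43)
        assert p1.assignment == p2.assignment
        assert p1.assignment != p3.assignment

    def test_input_errors(self):
        with pytest.raises(InputError):
            make_fold_plan(["a", "b"], 3, seed=0)
        with pytest.raises(InputError):
            make_fold_plan(["a", "a", "b"], 2, seed=0)
        with pytest.raises(InputError):
            make_fold_plan(["a", "b", "c"], 2, seed=0, always_train={"z"})

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(4, 25), k=st.integers(2, 8), seed=st.integers(0, 99))
    def test_fold_sizes_differ_by_at_most_one(self, n, k, seed):
        if k > n:
            return
        plan = make_fold_plan([f"s{i}" for i in range(n)], k, seed=seed)
        sizes = [len(plan.fold_members(f)) for f in range(k)]
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1


class TestRestrictAndForce:
    def test_restrict_preserves_fold_indices(self):
        plan = make_fold_plan(["a", "b", "c", "d"], 2, seed=0)
        for excluded in ["a", "b", "c", "d"]:
            sub = restrict_fold_plan(plan, excluded)
            assert excluded not in sub.assignment
            for sid, fold in sub.assignment.items():
                assert fold == plan.assignment[sid]

    def test_restrict_loo(self):
        plan = make_fold_plan(["a", "b", "c"], 3, seed=0)
        sub = restrict_fold_plan(plan, "c")
        assert set(sub.assignment) == {"a", "b"}
        assert all(sub.assignment[s] == plan.assignment[s] for s in "ab")

    def test_restrict_commutes(self):
        plan = make_fold_plan([f"s{i}" for i in range(5)], 3, seed=7)
        ab = restrict_fold_plan(restrict_fold_plan(plan, "s0"), "s3")
        ba = restrict_fold_plan(restrict_fold_plan(plan, "s3"), "s0")
        assert ab.assignment == ba.assignment

    def test_restrict_unknown_id(self):
        plan = make_fold_plan(["a", "b", "c"], 3, seed=0)
        with pytest.raises(InputError):
            restrict_fold_plan(plan, "z")

    def test_force_always_train(self):
        plan = make_fold_plan(["a", "b", "c", "d", "e"], 2, seed=0)
        forced = force_always_train(plan, "c")
        assert "c" in forced.always_train
        assert "c" not in forced.assignment
        for sid, fold in forced.assignment.items():
            assert fold == plan.assignment[sid]
        assert forced.universe == plan.universe


class TestRunOuterCV:
    def test_noiseless_linear_loo_is_exact(self, linear_dataset, ols_config):
        plan = make_fold_plan(linear_dataset.ids, 10, seed=0)
        preds = run_outer_cv(linear_dataset, plan, ols_config)
        assert preds.ids == frozenset(linear_dataset.ids)
        assert max(preds.abs_error.values()) <= 1e-10

    def test_three_point_toy_hand_computed(self, ols_config):
        # LOO straight-line fits: errors 2, 1, 2 -> MAE = 5/3
        ds = Dataset(ids=("a", "b", "c"), X=np.array([[0.0], [1.0], [2.0]]),
                     y=np.array([0.0, 1.0, 4.0]))
        plan = make_fold_plan(ds.ids, 3, seed=0)
        preds = run_outer_cv(ds, plan, ols_config)
        assert preds.abs_error["a"] == pytest.approx(2.0, abs=1e-10)
        assert preds.abs_error["b"] == pytest.approx(1.0, abs=1e-10)
        assert preds.abs_error["c"] == pytest.approx(2.0, abs=1e-10)
        m = compute_metrics(preds, ds)
        assert m.mae == pytest.approx(5.0 / 3.0, abs=1e-10)

    def test_each_sample_predicted_exactly_once(self, ols_config):
        ds = random_dataset(np.random.default_rng(0), n=9)
        for k in (3, 9):
            plan = make_fold_plan(ds.ids, k, seed=1)
            preds = run_outer_cv(ds, plan, ols_config)
            assert preds.ids == frozenset(ds.ids)

    def test_always_train_sample_not_predicted(self, ols_config):
        ds = random_dataset(np.random.default_rng(1), n=8)
        plan = make_fold_plan(ds.ids, 3, seed=0, always_train={ds.ids[0]})
        preds = run_outer_cv(ds, plan, ols_config)
        assert ds.ids[0] not in preds.ids
        assert preds.ids == frozenset(ds.ids[1:])

    def test_matches_naive_loo_oracle(self, ols_config):
        for trial in range(5):
            ds = random_dataset(np.random.default_rng(100 + trial))
            plan = make_fold_plan(ds.ids, ds.n_samples, seed=trial)
            preds = run_outer_cv(ds, plan, ols_config)
            oracle = naive_loo_predictions(ds, ols_config)
            diff = max(abs(preds.predicted[s] - oracle[s]) for s in ds.ids)
            assert diff <= 1e-10

    def test_seeded_plans_give_identical_predictions(self, ols_config):
        ds = random_dataset(np.random.default_rng(2), n=10)
        p1 = run_outer_cv(ds, make_fold_plan(ds.ids, 5, seed=9), ols_config)
        p2 = run_outer_cv(ds, make_fold_plan(ds.ids, 5, seed=9), ols_config)
        assert p1.predicted == p2.predicted

    def test_unknown_plan_samples_rejected(self, ols_config, linear_dataset):
        plan = make_fold_plan(list(linear_dataset.ids) + ["ghost"], 11, seed=0)
        with pytest.raises(InputError):
            run_outer_cv(linear_dataset, plan, ols_config)


class TestComputeMetrics:
    def _preds(self, ds, values):
        from icolike.cv import OuterPredictions
        return OuterPredictions(
            predicted={s: v for s, v in zip(ds.ids, values)},
            abs_error={s: abs(ds.y_of(s) - v) for s, v in zip(ds.ids, values)},
        )

    def test_perfect_predictions(self, linear_dataset):
        preds = self._preds(linear_dataset, linear_dataset.y)
        m = compute_metrics(preds, linear_dataset)
        assert m.mae == 0.0
        assert m.r2 == pytest.approx(1.0)
        assert m.n_evaluated == 10

    def test_mean_predictor_gives_r2_zero(self, linear_dataset):
        mean = float(linear_dataset.y.mean())
        preds = self._preds(linear_dataset, [mean] * 10)
        m = compute_metrics(preds, linear_dataset)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_subset_uses_subset_mean(self, linear_dataset):
        preds = self._preds(linear_dataset, linear_dataset.y + 1.0)
        subset = list(linear_dataset.ids[:4])
        m = compute_metrics(preds, linear_dataset, subset)
        assert m.n_evaluated == 4
        assert m.mae == pytest.approx(1.0)
        y = linear_dataset.y[:4]
        expected_r2 = 1.0 - 4.0 / float(np.sum((y - y.mean()) ** 2))
        assert m.r2 == pytest.approx(expected_r2)

    def test_zero_variance_subset_r2_undefined(self):
        ds = Dataset(ids=("a", "b", "c"), X=np.zeros((3, 1)),
                     y=np.array([2.0, 2.0, 2.0]))
        preds = self._preds(ds, [2.5, 2.5, 2.5])
        m = compute_metrics(preds, ds)
        assert m.mae == pytest.approx(0.5)
        assert np.isnan(m.r2)

    def test_empty_subset_rejected(self, linear_dataset):
        preds = self._preds(linear_dataset, linear_dataset.y)
        with pytest.raises(InputError):
            compute_metrics(preds, linear_dataset, [])


def test_cv_settings_validation():
    assert CVSettings("loo").resolve_k(7) == 7
    assert CVSettings(5).resolve_k(7) == 5
    with pytest.raises(InputError):
        CVSettings("half")
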