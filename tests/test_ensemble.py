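import numpy as np
import pytest

from neurodiff.datamodel import Diagnosis
from neurodiff.ensemble import (
    compare_runs,
    compute_metrics,
    ensemble_vote,
    make_fold_plan,
    paired_one_tailed_t,
    run_crossval,
    run_ensemble_fold,
)
from neurodiff.gan import GanConfig
from neurodiff.mmdnn import TrainConfig
from neurodiff.synthetic import CohortSpec, generate_cohort, make_disjoint_effect_maps
from tests.conftest import TINY_SPECS, make_record

CV_TRAIN = TrainConfig(
    lr=5e-3, batch_size=32, dropout=0.5, patience=4,
    pretrain_epochs=6, fusion_epochs=8, finetune_epochs=4, max_epochs=8,
    fusion_hidden=(60, 30), seed=0,
)


def balanced_records(n_per_class, scans=1):
    records = []
    i = 0
    for dx in ("NC", "AD", "FTD"):
        for _ in range(n_per_class):
            for v in range(scans):
                records.append(
                    make_record(sid=f"{dx}{i}", visit=f"v{v}", diagnosis=Diagnosis(dx))
                )
            i += 1
    return records


class TestFoldPlan:
    def test_partition_of_subjects(self):
        records = balanced_records(12)
        plan = make_fold_plan(records, k_outer=4, k_inner=3, seed=0)
        all_test = [s for f in plan.folds for s in f.test_subjects]
        assert len(all_test) == len(set(all_test)) == 36

    def test_multivisit_subject_stays_in_one_fold(self):
        records = balanced_records(12, scans=3)
        plan = make_fold_plan(records, k_outer=4, k_inner=3, seed=1)
        sid = records[0].subject_id
        containing = [f for f in plan.folds if sid in f.test_subjects]
        assert len(containing) == 1

    def test_stratified_30_subjects_10_folds(self):
        records = balanced_records(10)
        plan = make_fold_plan(records, k_outer=10, k_inner=3, seed=2)
        for fold in plan.folds:
            assert len(fold.test_subjects) == 3
            dx = sorted(s[:2] for s in fold.test_subjects)
            assert dx == ["AD", "FT", "NC"]

    def test_inner_splits_disjoint_from_test(self):
        records = balanced_records(12)
        plan = make_fold_plan(records, k_outer=4, k_inner=3, seed=3)
        for fold in plan.folds:
            test = set(fold.test_subjects)
            for tr, va in fold.inner_splits:
                assert not (set(tr) | set(va)) & test
                assert not set(tr) & set(va)

    def test_too_few_subjects_in_class(self):
        records = balanced_records(5)
        with pytest.raises(ValueError, match="fewer than"):
            make_fold_plan(records, k_outer=10)

    def test_converter_rejected(self):
        records = [
            make_record(sid="S1", visit="v0", diagnosis=Diagnosis.NC),
            make_record(sid="S1", visit="v1", diagnosis=Diagnosis.AD),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            make_fold_plan(records, k_outer=2)


class TestMetrics:
    def test_frozen_confusion_example(self):
        # confusion [[8,1,1],[2,7,1],[0,2,8]] -> accuracy 23/30,
        # sensitivities (0.8, 0.7, 0.8)
        truth, pred = [], []
        for t_cls, row in enumerate([[8, 1, 1], [2, 7, 1], [0, 2, 8]]):
            for p_cls, count in enumerate(row):
                truth += [t_cls] * count
                pred += [p_cls] * count
        m = compute_metrics(truth, pred)
        assert m.accuracy == pytest.approx(23 / 30)
        assert np.allclose(m.sensitivity, [0.8, 0.7, 0.8])
        assert np.array_equal(m.confusion, [[8, 1, 1], [2, 7, 1], [0, 2, 8]])

    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 2, 1], [0, 1, 2, 1])
        assert m.accuracy == 1.0
        assert np.allclose(m.sensitivity, 1.0)

    def test_single_class_truth(self):
        m = compute_metrics([1, 1, 1], [1, 0, 1])
        assert m.accuracy == m.sensitivity[1]

    def test_accuracy_is_count_weighted_mean_of_sensitivities(self, rng):
        truth = rng.integers(0, 3, size=100)
        pred = rng.integers(0, 3, size=100)
        m = compute_metrics(truth, pred)
        counts = np.bincount(truth, minlength=3)
        weighted = np.nansum(m.sensitivity * counts) / counts.sum()
        assert m.accuracy == pytest.approx(weighted)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestEnsembleVote:
    def test_identical_networks_equal_single(self):
        p = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
        mean, final, pred = ensemble_vote(np.stack([p, p, p]))
        assert np.allclose(mean, p)
        assert np.array_equal(pred, p.argmax(axis=1))

    def test_two_network_tie_resolved_to_lowest_index(self):
        a = np.array([[0.6, 0.3, 0.1]])
        b = np.array([[0.2, 0.5, 0.3]])
        mean, final, pred = ensemble_vote(np.stack([a, b]))
        assert np.allclose(mean, [[0.4, 0.4, 0.2]])
        assert final[0, 0] == final[0, 1]  # softmax preserves the tie
        assert pred[0] == 0  # NC wins the tie

    def test_softmax_preserves_argmax(self, rng):
        stack = rng.dirichlet(np.ones(3), size=(4, 10))
        mean, final, pred = ensemble_vote(stack)
        assert np.array_equal(pred, mean.argmax(axis=1))


class TestCompareRuns:
    def test_identical_vectors_not_significant(self):
        acc = [0.8] * 10
        df = compare_runs({"same": (acc, acc)})
        assert not df.loc["same", "reject"]
        assert df.loc["same", "zero_variance"]
        assert df.loc["same", "p"] == 1.0

    def test_constant_improvement_with_jitter_significant(self):
        rng = np.random.default_rng(0)
        base = 0.8 + rng.normal(0, 1e-4, size=10)
        better = base + 0.05
        df = compare_runs({"imp": (base, better + rng.normal(0, 1e-5, size=10))})
        assert df.loc["imp", "reject"]

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(1)
        base = 0.7 + rng.normal(0, 0.01, size=10)
        better = base + 0.05 + rng.normal(0, 0.01, size=10)
        t_fwd, p_fwd, _ = paired_one_tailed_t(base, better)
        t_rev, p_rev, _ = paired_one_tailed_t(better, base)
        assert t_fwd > 0 > t_rev
        assert p_fwd < 0.05 < p_rev

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_one_tailed_t([0.1, 0.2], [0.1])


@pytest.fixture(scope="module")
def small_cohort():
    n_feat = sum(s.dimension for s in TINY_SPECS)
    maps = make_disjoint_effect_maps(n_feat, 0.3, 2.5, seed=5)
    spec = CohortSpec(
        n_per_group={"NC": 12, "AD": 9, "FTD": 9},
        covariate_effects={"age": -1.0},
        group_effect_maps=maps,
        seed=5,
    )
    return generate_cohort(spec, TINY_SPECS)


class TestRunEnsembleFold:
    def test_fold_probabilities_and_metrics(self, small_cohort):
        records, table = small_cohort
        plan = make_fold_plan(records, k_outer=3, k_inner=3, seed=0)
        res = run_ensemble_fold(
            plan, 0, table, records, CV_TRAIN,
            n_networks=2, covariates=("age",),
        )
        assert res.per_network_probs.shape[0] == 2
        assert np.allclose(res.per_network_probs.sum(axis=2), 1.0, atol=1e-6)
        assert np.allclose(res.final_probs.sum(axis=1), 1.0, atol=1e-6)
        assert res.metrics.n == len(res.truth)
        # confusion row sums equal per-class test counts
        assert np.array_equal(
            res.metrics.confusion.sum(axis=1), np.bincount(res.truth, minlength=3)
        )

    def test_requires_raw_features(self, small_cohort):
        records, table = small_cohort
        plan = make_fold_plan(records, k_outer=3, k_inner=3, seed=0)
        wtable = table.with_values(table.values, kind="wscore")
        with pytest.raises(ValueError, match="raw"):
            run_ensemble_fold(plan, 0, wtable, records, CV_TRAIN, covariates=("age",))

    def test_gan_fold_smoke(self, small_cohort):
        records, table = small_cohort
        plan = make_fold_plan(records, k_outer=3, k_inner=3, seed=0)
        res = run_ensemble_fold(
            plan, 0, table, records, CV_TRAIN,
            use_gan=True, gan_cfg=GanConfig(noise_dim=8, hidden=16, epochs=4),
            n_networks=2, covariates=("age",),
        )
        assert np.allclose(res.final_probs.sum(axis=1), 1.0, atol=1e-6)


class TestRunCrossval:
    def test_full_crossval_and_determinism(self, small_cohort):
        records, table = small_cohort
        kwargs = dict(
            k_outer=3, k_inner=2, n_networks=1, covariates=("age",), seed=4
        )
        r1 = run_crossval(table, records, CV_TRAIN, **kwargs)
        r2 = run_crossval(table, records, CV_TRAIN, **kwargs)
        assert r1.overall.accuracy == r2.overall.accuracy
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)
        # every test row appears exactly once across folds
        n_rows = sum(len(r.test_row_index) for r in r1.fold_results)
        assert n_rows == table.n_rows
        assert r1.overall.n == table.n_rows

    def test_to_dict_serializable(self, small_cohort):
        import json

        records, table = small_cohort
        r = run_crossval(
            table, records, CV_TRAIN,
            k_outer=3, k_inner=2, n_networks=1, covariates=("age",), seed=4,
        )
        payload = json.dumps(r.to_dict())
        assert "overall_accuracy" in payload
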