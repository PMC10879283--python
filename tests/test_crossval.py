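import numpy as np
import pytest

from ftdx import make_nested_splits, ensemble_predict
from ftdx.classifier import ParallelEmbeddingClassifier
from ftdx.crossval import (
    N_INNER,
    SplitError,
    TrainedEnsemble,
    fit_outer_fold,
    run_nested_cv,
)


def _labels(counts=(173, 63, 41)):
    names = ("bvFTD", "nfvPPA", "svPPA")
    return np.concatenate([[n] * c for n, c in zip(names, counts)])


class TestNestedSplits:
    def test_outer_fold_sizes_for_277(self):
        splits = make_nested_splits(_labels(), k=10, seed=0)
        sizes = sorted(len(f.test_idx) for f in splits.folds)
        assert set(sizes) <= {27, 28}
        assert sum(sizes) == 277

    def test_outer_tests_partition_all_subjects(self):
        splits = make_nested_splits(_labels(), k=10, seed=1)
        all_test = np.concatenate([f.test_idx for f in splits.folds])
        assert len(all_test) == 277
        assert len(np.unique(all_test)) == 277

    def test_inner_validation_partitions_trainval(self):
        splits = make_nested_splits(_labels(), k=10, seed=2)
        for fold in splits.folds:
            trainval = np.setdiff1d(np.arange(277), fold.test_idx)
            assert len(fold.inner_splits) == N_INNER
            vals = np.concatenate([va for _, va in fold.inner_splits])
            np.testing.assert_array_equal(np.sort(vals), trainval)
            for tr, va in fold.inner_splits:
                assert len(np.intersect1d(tr, va)) == 0
                assert len(np.intersect1d(tr, fold.test_idx)) == 0

    def test_stratification_within_one_subject(self):
        labels = _labels()
        splits = make_nested_splits(labels, k=10, seed=3)
        for dx, count in (("bvFTD", 173), ("nfvPPA", 63), ("svPPA", 41)):
            per_fold = [
                (labels[f.test_idx] == dx).sum() for f in splits.folds
            ]
            assert max(per_fold) - min(per_fold) <= 1
            assert sum(per_fold) == count

    def test_deterministic_and_seed_sensitive(self):
        a = make_nested_splits(_labels(), k=10, seed=5)
        b = make_nested_splits(_labels(), k=10, seed=5)
        c = make_nested_splits(_labels(), k=10, seed=6)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.test_idx, fb.test_idx)
        assert any(
            not np.array_equal(fa.test_idx, fc.test_idx)
            for fa, fc in zip(a.folds, c.folds)
        )

    def test_small_class_rejected(self):
        with pytest.raises(SplitError, match="svPPA"):
            make_nested_splits(_labels((50, 30, 5)), k=10, seed=0)


class TestEnsemble:
    def _make_members(self, n=N_INNER, seed0=0):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 735))
        X[:10, :20] -= 3; X[10:20, 400:420] -= 3; X[20:, 100:120] -= 3
        y = np.array(["bvFTD"] * 10 + ["nfvPPA"] * 10 + ["svPPA"] * 10)
        return [
            ParallelEmbeddingClassifier(max_epochs=2, random_state=s).fit(X, y)
            for s in range(seed0, seed0 + n)
        ]

    def test_member_count_enforced(self):
        with pytest.raises(ValueError, match="9"):
            TrainedEnsemble(self._make_members(3), None, 0)

    def test_identical_members_equal_single_member(self, rng):
        members = [self._make_members(1, seed0=4)[0]] * N_INNER
        ens = TrainedEnsemble(members, None, 0)
        X = rng.standard_normal((5, 735))
        p, labels = ensemble_predict(ens, X)
        np.testing.assert_allclose(p, members[0].predict_proba(X), atol=1e-12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_mean_probability_decides(self):
        """Two confident members voting for different classes plus seven
        uniform abstainers: the mean decides by the larger confidence."""
        p1 = np.array([[0.8, 0.1, 0.1]])
        p2 = np.array([[0.05, 0.9, 0.05]])
        uniform = np.full((1, 3), 1 / 3)
        probs = np.mean([p1, p2] + [uniform] * 7, axis=0)
        # hand arithmetic: mean = ([0.85, 1.0, 0.15]/9 + 7/27)
        expected = (p1 + p2 + 7 * uniform)[0] / 9
        np.testing.assert_allclose(probs[0], expected)
        assert probs[0].argmax() == 1


@pytest.fixture(scope="module")
def tiny_run(small_cohort):
    table, _ = small_cohort
    # small cohort: smaller batches keep the SGD step count adequate
    return run_nested_cv(
        table, seed=0, k=4, max_epochs=150, patience=150, batch_size=8
    )


class TestNestedCVRun:

    def test_every_subject_predicted_once(self, tiny_run, small_cohort):
        table, _ = small_cohort
        assert len(tiny_run.y_pred) == table.n_subjects
        assert not np.isnan(tiny_run.proba).any()
        assert tiny_run.report["confusion"].sum() == table.n_subjects

    def test_per_fold_values_reported(self, tiny_run):
        assert len(tiny_run.per_fold_overall_ba) == 4
        assert all(0 <= v <= 1 for v in tiny_run.per_fold_overall_ba)

    def test_ensembles_carry_harmonizers(self, tiny_run):
        assert all(e.harmonizer is not None for e in tiny_run.ensembles)
        assert all(len(e.members) == N_INNER for e in tiny_run.ensembles)

    def test_signal_beats_chance(self, tiny_run):
        # d=2 planted atrophy: far above the 1/2 chance level
        assert tiny_run.report["overall_balanced_accuracy"] > 0.8


class TestSignalResponse:
    def test_accuracy_monotone_in_effect_size(self):
        """Overall balanced accuracy does not decrease as the planted
        effect size grows (within one fold-SD), from chance at d=0."""
        from ftdx import SimulationConfig, generate_cohort

        bas, sds = [], []
        for d in (0.0, 1.0, 2.0):
            cfg = SimulationConfig(
                n_per_class={"bvFTD": 30, "nfvPPA": 16, "svPPA": 14},
                atrophy_effect_size=d, seed=31,
            )
            table, _ = generate_cohort(cfg)
            res = run_nested_cv(
                table, seed=3, k=3, max_epochs=100, patience=100,
                batch_size=8,
            )
            bas.append(res.report["overall_balanced_accuracy"])
            sds.append(np.std(res.per_fold_overall_ba))
        assert bas[0] < 0.7  # near chance without signal
        for lo, hi, sd in zip(bas, bas[1:], sds):
            assert hi >= lo - sd

class TestLeakage:
    def test_outer_fold_ignores_test_rows(self, small_cohort):
        """Perturbing test-set features leaves harmonization coefficients
        and all trained parameters bit-identical."""
        from ftdx import audit_leakage

        table, _ = small_cohort
        report = audit_leakage(
            table, seed=0, k=4, max_epochs=4, fold_index=0
        )
        assert report["passed"]
        assert report["harmonizer_identical"]
        assert all(report["members_identical"])
        assert len(report["perturbed_subjects"]) > 0

    def test_negative_control_fails(self, small_cohort):
        from ftdx import audit_leakage

        table, _ = small_cohort
        report = audit_leakage(
            table, seed=0, k=4, max_epochs=4, fold_index=0,
            leaky_harmonization=True,
        )
        assert not report["passed"]
        assert not report["harmonizer_identical"]
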