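import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multistress.dataset import normalize_per_session, windows_from_cohort
from multistress.evaluate import (
    bland_altman,
    evaluate_subject_dependent,
    loocv_subject_independent,
    metrics,
    r_squared,
)
from multistress.model import (
    FusionConfig,
    InceptionBlockConfig,
    TrainHyperparams,
    TrainedModel,
    StressNet,
)

SMALL_CFG = FusionConfig(embedding_dim=8, attention_dim=8, head_hidden=16, input_len=24, seed=0)
SMALL_BLK = InceptionBlockConfig(n_filters=4)
SMALL_HP = TrainHyperparams(lr=5e-3, batch_size=64, max_epochs=3, patience=3)


class TestRSquared:
    def test_identity_and_affine_are_perfect(self):
        x = np.array([1.0, 2, 3, 4])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(x, -2 * x + 7) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Pearson^2 by hand: cov=6.5, ssx=5, ssy=8.75 -> 42.25/43.75
        assert r_squared([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(42.25 / 43.75, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert r_squared(a * x + b, y) == pytest.approx(r_squared(x, y), abs=1e-9)

    def test_matches_numpy_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x, y = rng.normal(size=(2, 30))
            assert r_squared(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-9)


class TestBlandAltman:
    def test_constant_difference_collapses_loa(self):
        x = np.array([1.0, 2, 3, 4])
        rep = bland_altman(x, x + 2.5)
        assert rep.mean_difference == pytest.approx(2.5)
        assert rep.sd_differences == 0.0
        assert rep.loa_lower == rep.loa_upper == pytest.approx(2.5)

    def test_closed_form_unit_sd(self):
        rep = bland_altman([0.0, 0, 0], [-1.0, 0, 1])
        assert rep.mean_difference == pytest.approx(0.0)
        assert rep.sd_differences == pytest.approx(1.0)
        assert rep.loa_upper == pytest.approx(1.96)
        assert rep.loa_lower == pytest.approx(-1.96)

    def test_half_width_ratio_is_196(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, y = rng.normal(size=(2, 25))
            rep = bland_altman(x, y)
            assert (rep.loa_upper - rep.mean_difference) / rep.sd_differences == pytest.approx(1.96)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(3, 50)
            x, y = rng.normal(size=(2, n))
            rep = bland_altman(x, y)
            d = y - x
            assert rep.mean_difference == pytest.approx(d.sum() / n, abs=1e-9)
            sd = np.sqrt(((d - d.sum() / n) ** 2).sum() / (n - 1))
            assert rep.sd_differences == pytest.approx(sd, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_antisymmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        a, b = bland_altman(x, y), bland_altman(y, x)
        assert a.mean_difference == pytest.approx(-b.mean_difference, abs=1e-12)
        assert a.sd_differences == pytest.approx(b.sd_differences, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])


class TestMetrics:
    def test_perfect_prediction(self):
        acc, f1, cm = metrics(["a", "b", "a"], ["a", "b", "a"])
        assert acc == 100.0 and f1 == 100.0
        assert np.trace(cm) == 3

    def test_single_class_predictor_on_balanced_binary(self):
        acc, _, _ = metrics(["a", "b"] * 10, ["a"] * 20)
        assert acc == pytest.approx(50.0)

    def test_two_by_two_hand_count(self):
        t = ["p", "p", "p", "n", "n", "n"]
        p = ["p", "p", "n", "n", "n", "p"]
        acc, f1, cm = metrics(t, p, class_names=["n", "p"])
        assert acc == pytest.approx(100 * 4 / 6)
        # hand: precision_p=2/3, recall_p=2/3 -> F1_p=2/3; same for n
        assert f1 == pytest.approx(100 * 2 / 3)
        assert cm.tolist() == [[2, 1], [1, 2]]

    def test_confusion_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(0)
        t = rng.choice(["a", "b", "c"], 60)
        p = rng.choice(["a", "b", "c"], 60)
        _, _, cm = metrics(t, p, class_names=["a", "b", "c"])
        for i, c in enumerate(["a", "b", "c"]):
            assert cm[i].sum() == (t == c).sum()


def _stub_trainer_factory(record):
    """A fake trainer recording what it sees; predicts the majority class."""

    def stub(train_ds, val_ds, seed, task):
        record.append(
            {
                "train_subjects": set(train_ds.subject_ids),
                "val_subjects": set(val_ds.subject_ids),
                "train_labels": train_ds.labels.copy(),
            }
        )
        net = StressNet(SMALL_CFG, SMALL_BLK, 2)  # untrained: structure only
        return TrainedModel(net, SMALL_CFG, SMALL_BLK, ["rest", "stress"], task)

    return stub


class TestLoocvStructure:
    @pytest.fixture(scope="class")
    def five_subject_windows(self, tiny_rates):
        from multistress.schedule import make_protocol_schedule
        from multistress.simulate import SubjectVariability, simulate_cohort

        sched = make_protocol_schedule(2, 30, 30)
        cohort = simulate_cohort(5, 1, sched, SubjectVariability.low_noise(),
                                 rates=tiny_rates, seed=11)
        return normalize_per_session(windows_from_cohort(cohort, 5, 0.0))

    def test_one_fold_per_subject_disjoint_by_subject(self, five_subject_windows):
        ds = five_subject_windows
        seen = []

        def trainer(train_ds, val_ds, seed, task):
            seen.append((set(train_ds.subject_ids), set(val_ds.subject_ids)))
            from multistress.model import train as real_train

            return real_train(train_ds, task=task, hyperparams=SMALL_HP, seed=seed,
                              fusion_config=SMALL_CFG, block_config=SMALL_BLK,
                              val_dataset=val_ds)

        report = loocv_subject_independent(ds, task="binary", trainer=trainer, seed=0)
        assert len(report.fold_accuracy_pct) == 5
        all_subjects = set(ds.subject_ids)
        for (train_subj, val_subj), held in zip(seen, report.fold_subjects):
            assert held not in train_subj
            assert held not in val_subj
            assert train_subj | val_subj == all_subjects - {held}
            assert len(val_subj) == 1

    def test_too_few_subjects_rejected(self, tiny_cohort):
        ds = windows_from_cohort(tiny_cohort[:2], 5, 0.0)  # one subject only
        with pytest.raises(ValueError):
            loocv_subject_independent(ds, task="binary", seed=0)

    def test_held_out_label_permutation_does_not_change_training(self, five_subject_windows):
        """Leakage control: permuting the held-out subject's labels must not
        alter what any fold's trainer sees."""
        ds = five_subject_windows
        rec1, rec2 = [], []
        loocv_subject_independent(
            ds, task="binary", trainer=_stub_trainer_factory(rec1), seed=3,
            subjects_subset=["S02"],
        )
        # permute S02's labels only
        from dataclasses import replace

        rng = np.random.default_rng(0)
        labels = ds.labels.copy()
        m = ds.subject_ids == "S02"
        labels[m] = rng.permutation(labels[m])
        ds2 = replace(ds, labels=labels)
        loocv_subject_independent(
            ds2, task="binary", trainer=_stub_trainer_factory(rec2), seed=3,
            subjects_subset=["S02"],
        )
        assert np.array_equal(rec1[0]["train_labels"], rec2[0]["train_labels"])
        assert rec1[0]["train_subjects"] == rec2[0]["train_subjects"]


class TestSubjectDependent:
    def test_requires_two_sessions(self, tiny_cohort):
        ds = normalize_per_session(windows_from_cohort(tiny_cohort, 5, 0.0))
        one_session = ds.select(ds.session_ids == "sess1")
        with pytest.raises(ValueError, match="sessions"):
            evaluate_subject_dependent(one_session, "S01", task="binary", seed=0,
                                       hyperparams=SMALL_HP,
                                       fusion_config=SMALL_CFG, block_config=SMALL_BLK)

    def test_fine_tune_keeps_encoder_and_tests_on_second_session(self, tiny_cohort):
        ds = normalize_per_session(windows_from_cohort(tiny_cohort, 5, 0.0))
        report = evaluate_subject_dependent(
            ds, "S01", task="binary", seed=0, hyperparams=SMALL_HP,
            fusion_config=SMALL_CFG, block_config=SMALL_BLK, fine_tune_epochs=2,
        )
        assert len(report.fold_accuracy_pct) == 1
        assert 0 <= report.fold_accuracy_pct[0] <= 100
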