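import numpy as np
import pandas as pd
import pytest
from fractions import Fraction

from weakfoot import (
    BranchFallback,
    GaitSimConfig,
    RunConfig,
    UndefinedMetricsError,
    count_sweep_runs,
    evaluate_loso,
    fit_two_stage,
    metrics,
    prepare_subjects,
    select_features,
    simulate_cohort,
    tune_branch,
)
from weakfoot.io import UndefinedMetricWarning
from weakfoot.model import SubjectData, _FitCache

FEATURES = tuple("f%d" % i for i in range(10))


def _fast_config(**kw):
    kw.setdefault("inner_cv", 3)
    return RunConfig(**kw)


def separable_windows(n_per_class=20, n_features=10, seed=0, subjects_per_class=5):
    """One perfectly separating feature, the rest pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.repeat([0, 1], n_per_class)
    X[:, 0] = y * 4.0 + rng.normal(scale=0.2, size=2 * n_per_class)
    groups = np.concatenate([
        np.repeat([f"lr{i}" for i in range(subjects_per_class)],
                  n_per_class // subjects_per_class),
        np.repeat([f"hr{i}" for i in range(subjects_per_class)],
                  n_per_class // subjects_per_class),
    ])
    return X, y, groups


class TestMetrics:
    def test_printed_counts_identity(self):
        # 21/20/4/3 pools to 41 correct of 48
        rep = metrics(21, 20, 4, 3)
        assert rep.accuracy == pytest.approx(41 / 48)
        assert round(100 * rep.accuracy, 1) == 85.4
        assert rep.sensitivity == pytest.approx(21 / 24)
        assert round(100 * rep.sensitivity, 1) == 87.5

    def test_degenerate_counts(self):
        rep = metrics(1, 0, 0, 0)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0
        with pytest.warns(UndefinedMetricWarning):
            assert metrics(0, 10, 0, 0).f1 == 0.0
        rep = metrics(0, 5, 3, 2)
        assert rep.accuracy == pytest.approx(0.5)
        assert metrics(5, 5, 5, 5).f1 == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedMetricsError):
            metrics(0, 0, 0, 0)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            rep = metrics(tp, tn, fp, fn)
            acc = Fraction(tp + tn, tp + tn + fp + fn)
            assert rep.accuracy == pytest.approx(float(acc), abs=1e-15)
            if 2 * tp + fp + fn:
                f1 = Fraction(2 * tp, 2 * tp + fp + fn)
                assert rep.f1 == pytest.approx(float(f1), abs=1e-15)


class TestSelectFeatures:
    def test_separating_feature_dominates_nominations(self):
        X, y, groups = separable_windows(seed=1)
        config = _fast_config()
        selected, trace = select_features(X, y, groups, FEATURES, config, seed=1)
        assert "f0" in selected
        first_counts = sum("f0" in noms[:1] or noms[0] == "f0"
                           for noms in trace["nominations"].values())
        assert first_counts >= 9  # at least 9 of the 11 selectors rank it first

    def test_no_signal_triggers_relaxation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = np.repeat([0, 1], 20)
        groups = np.repeat([f"s{i}" for i in range(8)], 5)
        # identical class distributions: expect the relaxation path (its
        # seed is fixed, so the t-test outcome is deterministic here)
        _, trace = select_features(X, y, groups, FEATURES[:6], _fast_config(),
                                   seed=3)
        assert trace["relaxed"] is True

    def test_unanimous_nomination_returned_unchanged(self):
        # two informative features, zero-variance remainder: every selector
        # must nominate the informative pair first
        rng = np.random.default_rng(4)
        X = np.zeros((40, 4))
        y = np.repeat([0, 1], 20)
        X[:, 0] = y * 3 + rng.normal(scale=0.1, size=40)
        X[:, 1] = -y * 3 + rng.normal(scale=0.1, size=40)
        groups = np.repeat([f"s{i}" for i in range(8)], 5)
        selected, trace = select_features(X, y, groups, FEATURES[:4],
                                          _fast_config(n_nominate=2), seed=4)
        assert set(selected) <= {"f0", "f1"}


class TestTuneBranch:
    def test_separable_fixture_reaches_perfect_cv(self):
        X, y, groups = separable_windows(n_per_class=30, seed=5,
                                         subjects_per_class=6)
        name, params, score = tune_branch(X[:, :2], y, groups,
                                          _fast_config(), seed=5)
        assert score == pytest.approx(1.0)

    def test_tuned_parameters_are_the_documented_pair(self):
        from weakfoot.model import HYPER_GRIDS
        X, y, groups = separable_windows(n_per_class=30, seed=6,
                                         subjects_per_class=6)
        name, params, _ = tune_branch(X, y, groups, _fast_config(), seed=6)
        assert name in HYPER_GRIDS
        assert set(params) == set(HYPER_GRIDS[name])

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(7)
        X, y, groups = separable_windows(n_per_class=100, seed=7,
                                         subjects_per_class=10)
        y_perm = rng.permutation(y)
        from weakfoot.model import HYPER_GRIDS, grouped_cv, make_classifier
        folds = grouped_cv(y_perm, groups, 3, 7)
        for clf_name in RunConfig().roster:
            params = {k: v[0] for k, v in HYPER_GRIDS[clf_name].items()}
            accs = []
            for tr, te in folds:
                clf = make_classifier(clf_name, params, seed=7)
                clf.fit(X[tr], y_perm[tr])
                accs.append(np.mean(clf.predict(X[te]) == y_perm[te]))
            assert 0.35 <= np.mean(accs) <= 0.65

    def test_single_class_branch_signals_fallback(self):
        X = np.random.default_rng(8).normal(size=(20, 3))
        y = np.ones(20, dtype=int)
        groups = np.repeat([f"s{i}" for i in range(4)], 5)
        with pytest.raises(BranchFallback):
            tune_branch(X, y, groups, _fast_config(), seed=8)

    def test_two_subject_branch_signals_fallback(self):
        X = np.random.default_rng(9).normal(size=(10, 3))
        y = np.repeat([0, 1], 5)
        groups = np.repeat(["a", "b"], 5)
        with pytest.raises(BranchFallback):
            tune_branch(X, y, groups, _fast_config(), seed=9)


@pytest.fixture(scope="module")
def small_cohort():
    """12 subjects, short walks: fast but realistic end-to-end fixture."""
    config = RunConfig(high_length=60, inner_cv=3)
    recs, truths = simulate_cohort({"DWF_LR": 5, "DWF_HR": 4, "RWF": 3},
                                   GaitSimConfig(total_steps=82), seed=13)
    return prepare_subjects(recs, config), truths, config


class TestFitTwoStage:
    def test_alpha_grid_evaluates_fourteen_thresholds(self, small_cohort):
        subjects, _, config = small_cohort
        model, trace = fit_two_stage(subjects, config, seed=13)
        assert len(trace.alpha_scores) == 14
        assert [a for a, _, _ in trace.alpha_scores] == pytest.approx(
            list(config.alphas))

    def test_chosen_alpha_attains_best_recorded_accuracy(self, small_cohort):
        subjects, _, config = small_cohort
        model, trace = fit_two_stage(subjects, config, seed=13)
        best = trace.best_recorded_accuracy
        chosen = [acc for a, _, acc in trace.alpha_scores
                  if a == pytest.approx(trace.chosen_alpha)]
        assert chosen[0] == pytest.approx(best)

    def test_all_dwf_cohort_reduces_to_one_stage(self):
        config = RunConfig(high_length=60, inner_cv=3)
        recs, _ = simulate_cohort({"DWF_LR": 4, "DWF_HR": 4},
                                  GaitSimConfig(total_steps=82), seed=3)
        subjects = prepare_subjects(recs, config)
        # force every reference below any threshold: nobody is flagged RWF
        refs = {s.subject_id: 0.5 for s in subjects}
        refs[subjects[0].subject_id] = 0.6
        model, _ = fit_two_stage(subjects, config, seed=3, reference=refs)
        assert model.branches["RWF"].is_fallback

    def test_rwf_count_nonincreasing_along_grid(self, small_cohort):
        subjects, _, config = small_cohort
        _, trace = fit_two_stage(subjects, config, seed=13)
        counts = [n for _, n, _ in trace.alpha_scores]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEvaluateLOSO:
    def test_no_leakage_fingerprints(self, small_cohort):
        subjects, _, config = small_cohort
        report, preds, fingerprints = evaluate_loso(subjects, config, seed=13,
                                                    stage="two")
        all_ids = {s.subject_id for s in subjects}
        assert len(fingerprints) == len(subjects)
        for fp in fingerprints:
            assert fp["held_out"] not in fp["training_ids"]
            assert fp["training_ids"] == all_ids - {fp["held_out"]}

    def test_report_counts_cover_all_subjects(self, small_cohort):
        subjects, _, config = small_cohort
        report, preds, _ = evaluate_loso(subjects, config, seed=13, stage="two")
        assert report.total == len(subjects)
        assert set(preds["subject"]) == {s.subject_id for s in subjects}
        branch_total = sum(r.total for r in report.sub_reports.values())
        assert branch_total == report.total


class TestLengthSweep:
    def test_combinatorics(self):
        lengths = list(range(20, 181, 10))
        assert len(lengths) == 17
        assert count_sweep_runs(48, lengths) == 816

    def test_scaled_sweep_runs_real_pipeline(self):
        from weakfoot.model import length_sweep
        config = RunConfig(high_length=60, inner_cv=3)
        recs, _ = simulate_cohort({"DWF_LR": 3, "DWF_HR": 3},
                                  GaitSimConfig(total_steps=82), seed=21)
        acc, counts = length_sweep(recs, config, seed=21, lengths=[20, 40, 60])
        assert set(acc["length"]) == {20, 40, 60}
        assert len(acc) == 18  # 6 subjects x 3 lengths
        assert (acc["window_accuracy"] >= 0).all()
        assert counts["count"].sum() > 0

    def test_length_equal_to_step_count_gives_one_window(self):
        from weakfoot.model import recording_table
        config = RunConfig()
        recs, _ = simulate_cohort({"DWF_LR": 1}, GaitSimConfig(total_steps=42),
                                  seed=2)
        table = recording_table(recs[0], config, 40)
        assert len(table) == 1
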