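import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weakfoot import (
    FeatureExtractor,
    FootSummary,
    SensorLayout,
    Standardizer,
    UndefinedCOPError,
    UndefinedFeatureError,
    compute_cop,
    cosine_similarity,
    cut_windows,
    discard_startup,
    js_divergence,
    plan_windows,
    segment_steps,
    select_weak_foot,
    simulate_subject,
    weak_vector,
)
from weakfoot.features import FeatureVector


class TestComputeCOP:
    def test_symmetric_forces_give_midpoint(self):
        lay = SensorLayout("left", ((0.0, 0.0), (2.0, 2.0)))
        traj = compute_cop(np.array([[1.0, 1.0]]), lay)
        np.testing.assert_allclose(traj.points, [[1.0, 1.0]])

    def test_weighted_mean_hand_oracle(self):
        # (0*3 + 4*1) / 4 = 1
        lay = SensorLayout("left", ((0.0, 0.0), (4.0, 0.0)))
        traj = compute_cop(np.array([[3.0, 1.0]]), lay)
        np.testing.assert_allclose(traj.points, [[1.0, 0.0]])

    def test_all_zero_frames_undefined(self):
        lay = SensorLayout("left", ((0.0, 0.0), (4.0, 0.0)))
        with pytest.raises(UndefinedCOPError):
            compute_cop(np.zeros((5, 2)), lay)

    def test_scale_invariance_of_forces(self):
        rng = np.random.default_rng(0)
        lay = SensorLayout("left", tuple(map(tuple, rng.random((6, 2)) * 100)))
        frames = rng.random((20, 6)) + 0.1
        a = compute_cop(frames, lay).points
        b = compute_cop(frames * 7.3, lay).points
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_containment_in_sensor_hull(self):
        # every COP is a convex combination of sensor coordinates
        rng = np.random.default_rng(1)
        lay = SensorLayout("left", tuple(map(tuple, rng.random((8, 2)) * 100)))
        frames = rng.random((1000, 8))
        pts = compute_cop(frames, lay, eps=1e-9).points
        xy = lay.xy
        assert pts[:, 0].min() >= xy[:, 0].min() - 1e-9
        assert pts[:, 0].max() <= xy[:, 0].max() + 1e-9
        assert pts[:, 1].min() >= xy[:, 1].min() - 1e-9
        assert pts[:, 1].max() <= xy[:, 1].max() + 1e-9


class TestWeakFootRule:
    def test_smaller_left_selects_left(self):
        assert select_weak_foot(FootSummary(2.0), FootSummary(5.0)) == "left"

    def test_smaller_right_selects_right(self):
        assert select_weak_foot(FootSummary(5.0), FootSummary(2.0)) == "right"

    def test_tie_selects_right(self):
        assert select_weak_foot(FootSummary(3.0), FootSummary(3.0)) == "right"

    def test_simulated_weak_side_recovered_in_every_window(self, quiet_cfg):
        from dataclasses import replace
        for side in ("left", "right"):
            cfg = replace(quiet_cfg, phenotype="DWF_HR", weak_side=side,
                          attenuation=0.5, total_steps=62)
            rec, _ = simulate_subject(cfg, seed=4)
            idx = discard_startup(segment_steps(rec), 2)
            ex = FeatureExtractor(rec, idx)
            plan = plan_windows(len(idx), 20, 10)
            for win in cut_windows(rec, idx, plan):
                assert ex.extract(win, ("Std_y",)).weak_side == side

    def test_weak_side_mostly_recovered_with_default_noise(self):
        # stochastic check at the default attenuation effect, fixed seed
        from weakfoot import GaitSimConfig
        hits = total = 0
        for seed in range(4):
            cfg = GaitSimConfig(phenotype="DWF_HR", weak_side="left",
                                total_steps=102)
            rec, _ = simulate_subject(cfg, seed=seed)
            idx = discard_startup(segment_steps(rec), 2)
            ex = FeatureExtractor(rec, idx)
            plan = plan_windows(len(idx), 20, 10)
            for win in cut_windows(rec, idx, plan):
                hits += ex.extract(win, ("Std_y",)).weak_side == "left"
                total += 1
        assert hits / total >= 0.95


class TestComparators:
    def test_jsd_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p, q = rng.random(8), rng.random(8)
            a, b = js_divergence(p, q), js_divergence(q, p)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= np.log(2) + 1e-12

    def test_jsd_disjoint_support_hits_ln2(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        assert js_divergence(p, q) == pytest.approx(np.log(2))

    def test_sim_equals_one_iff_proportional(self):
        p = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(p, 5 * p) == pytest.approx(1.0)
        q = np.array([3.0, 2.0, 1.0])
        assert cosine_similarity(p, q) < 1.0

    def test_zero_distribution_is_nan(self):
        assert np.isnan(cosine_similarity(np.zeros(3), np.ones(3)))
        assert np.isnan(js_divergence(np.zeros(3), np.ones(3)))


class TestWindowFeatures:
    def test_two_point_trajectory_hand_oracle(self):
        # COP points (0,0) and (0,2): population stats by hand
        pts = np.array([[0.0, 0.0], [0.0, 2.0]])
        mean = pts.mean(axis=0)
        rd = np.linalg.norm(pts - mean, axis=1)
        assert mean[1] == pytest.approx(1.0)
        assert np.std(pts[:, 1]) == pytest.approx(1.0)
        assert rd.mean() == pytest.approx(1.0)       # MRD
        assert rd.std() == pytest.approx(0.0)        # SRD
        totex = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert totex == pytest.approx(2.0)
        cca = np.pi * (rd.mean() + 1.645 * rd.std()) ** 2
        assert cca == pytest.approx(np.pi)

    def test_perfect_symmetry_and_consistency(self, quiet_cfg):
        # identical deterministic feet: GA = 0, JSD = 0, SIM = 1, and the
        # consecutive-step comparators degenerate the same way
        from dataclasses import replace
        cfg = replace(quiet_cfg, phenotype="DWF_LR", total_steps=42)
        rec, _ = simulate_subject(cfg, seed=0)
        idx = segment_steps(rec)
        ex = FeatureExtractor(rec, idx)
        plan = plan_windows(len(idx), len(idx), 10)
        (win,) = cut_windows(rec, idx, plan)
        fv = ex.extract(win)
        # frame-grid quantisation leaves ~1e-7 residuals even at zero noise
        assert fv.values["GA"] == pytest.approx(0.0, abs=1e-5)
        assert fv.values["JSD"] == pytest.approx(0.0, abs=1e-5)
        assert fv.values["SIM"] == pytest.approx(1.0, abs=1e-5)
        assert fv.values["GIC"] == pytest.approx(0.0, abs=1e-5)
        assert fv.values["SSIM"] == pytest.approx(1.0, abs=1e-4)
        assert fv.values["SJSD"] == pytest.approx(0.0, abs=1e-5)

    def test_translation_and_scaling_of_coordinates(self, quiet_cfg):
        from dataclasses import replace
        from weakfoot import SensorLayout, default_layout
        cfg = replace(quiet_cfg, total_steps=42)
        rec, _ = simulate_subject(cfg, seed=5)
        idx = segment_steps(rec)

        def feats(rec):
            ex = FeatureExtractor(rec, idx)
            plan = plan_windows(len(idx), len(idx), 10)
            (win,) = cut_windows(rec, idx, plan)
            return ex.extract(win, ("Std_x", "Std_y", "MRD", "TOTEX")).values

        base = feats(rec)
        shifted = {s: SensorLayout(s, tuple((x + 11.0, y - 7.0)
                                            for x, y in rec.layout[s].coords))
                   for s in ("left", "right")}
        rec_shift = rec.__class__(subject_id="s", label=rec.label, rate=rec.rate,
                                  left=rec.left, right=rec.right, layout=shifted)
        moved = feats(rec_shift)
        for name in ("Std_x", "Std_y", "MRD", "TOTEX"):
            assert moved[name] == pytest.approx(base[name], rel=1e-9)

        scaled = {s: SensorLayout(s, tuple((3.0 * x, 3.0 * y)
                                           for x, y in rec.layout[s].coords))
                  for s in ("left", "right")}
        rec_scaled = rec.__class__(subject_id="s", label=rec.label, rate=rec.rate,
                                   left=rec.left, right=rec.right, layout=scaled)
        big = feats(rec_scaled)
        for name in ("Std_x", "Std_y", "MRD", "TOTEX"):
            assert big[name] == pytest.approx(3.0 * base[name], rel=1e-9)


class TestWeakVector:
    NAMES = ("a", "b", "c", "d", "e")

    def _fv(self, values):
        return FeatureVector(subject="s", label="HR", length=20, start=0,
                             weak_side="left",
                             values=dict(zip(self.NAMES, values)))

    def test_identity_scaler_returns_raw(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = weak_vector(self._fv(vals), self.NAMES,
                          Standardizer.identity(self.NAMES))
        np.testing.assert_allclose(out, vals)

    def test_scaler_centred_at_value_gives_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scaler = Standardizer(self.NAMES, mean=vals, scale=np.ones(5))
        out = weak_vector(self._fv(vals), self.NAMES, scaler)
        np.testing.assert_allclose(out, np.zeros(5))

    @given(st.lists(st.floats(-100, 100), min_size=10, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_zscore_matches_formula(self, raw):
        import pandas as pd
        table = pd.DataFrame({n: raw for n in self.NAMES})
        scaler = Standardizer.fit(table, self.NAMES)
        arr = np.asarray(raw)
        sd = arr.std() if arr.std() > 0 else 1.0
        expected = (arr[0] - arr.mean()) / sd
        out = weak_vector(self._fv([raw[0]] * 5), self.NAMES, scaler)
        np.testing.assert_allclose(out, [expected] * 5, atol=1e-9)

    def test_missing_value_propagates_with_name(self):
        fv = self._fv([1.0, float("nan"), 3.0, 4.0, 5.0])
        with pytest.raises(UndefinedFeatureError) as err:
            weak_vector(fv, self.NAMES, Standardizer.identity(self.NAMES))
        assert "b" in err.value.features
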