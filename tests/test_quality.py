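import numpy as np
import pytest

import gazeval as gv
from gazeval.fixations import Fixation
from gazeval.quality import (
    DataQualityResult,
    accuracy,
    fixed_distance_error_ratio,
    gaze_range,
    match_targets,
    precision,
    summarize,
)

from conftest import make_series


def fixation_at(xy, start=0.0, dur=800.0, first=0, last=39):
    return Fixation(start=start, end=start + dur, centroid_xy=tuple(xy),
                    member_indices=(first, last))


class TestMatchTargets:
    def test_perfect_bijection(self, poster):
        rng = np.random.default_rng(3)
        fixes = [
            fixation_at((t.x + rng.uniform(-5, 5), t.y + rng.uniform(-5, 5)),
                        start=i * 1000.0)
            for i, t in enumerate(poster.targets)
        ]
        matches = match_targets(fixes, poster)
        assert all(m.matched for m in matches)
        assigned = {id(m.fixation) for m in matches}
        assert len(assigned) == 9  # injective

    def test_short_fixation_never_matched(self, poster):
        fixes = [fixation_at((poster.targets[0].x, poster.targets[0].y), dur=40.0)]
        matches = match_targets(fixes, poster)
        assert not any(m.matched for m in matches)

    def test_greedy_nearest_assignment(self):
        from gazeval.poster import MarkerSpec, PosterSpec, TargetSpec

        p = PosterSpec(
            targets=[TargetSpec(id=1, x=0, y=0), TargetSpec(id=2, x=40, y=0)],
            markers=[MarkerSpec(id=0, center_x=0, center_y=200, size=40)],
        )
        matches = match_targets([fixation_at((10.0, 0.0))], p)
        by_id = {m.target_id: m for m in matches}
        assert by_id[1].matched and by_id[1].distance_mm == pytest.approx(10.0)
        assert not by_id[2].matched

    def test_empty_input_all_unmatched(self, poster):
        assert not any(m.matched for m in match_targets([], poster))

    def test_total_over_min_count(self, poster):
        """With fewer eligible fixations than targets, every fixation
        is used exactly once."""
        fixes = [fixation_at((poster.targets[i].x, poster.targets[i].y))
                 for i in range(4)]
        matches = match_targets(fixes, poster)
        assert sum(m.matched for m in matches) == 4


class TestAccuracy:
    @pytest.mark.parametrize(
        "eye,expected",
        [((0, 0, -600.0), np.degrees(np.arctan(10.47 / 600))),
         ((0, 0, -300.0), np.degrees(np.arctan(10.47 / 300)))],
    )
    def test_known_offset_angle(self, eye, expected):
        assert accuracy((10.47, 0.0), (0.0, 0.0), eye) == pytest.approx(expected, abs=1e-6)

    def test_zero_when_centroid_on_target(self):
        assert accuracy((30.0, -20.0), (30.0, -20.0), (0, 0, -600.0)) == 0.0


class TestPrecision:
    def test_identical_samples_zero(self):
        s = make_series([(10.0, 5.0)] * 20)
        f = fixation_at((10.0, 5.0), first=0, last=19)
        rms, std = precision(s, f, (0.0, 0.0))
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_alternating_offset_closed_form(self):
        """Azimuth alternating +-0.1 deg: RMS-S2S 0.2, STD 0.1."""
        d = 600.0 * np.tan(np.radians(0.1))
        xy = [(d if i % 2 == 0 else -d, 0.0) for i in range(50)]
        s = make_series(xy)
        rms, std = precision(s, fixation_at((0, 0), first=0, last=49), (0.0, 0.0))
        assert rms == pytest.approx(0.2, abs=1e-4)
        assert std == pytest.approx(0.1, abs=1e-4)

    def test_white_noise_expectations(self):
        """White az/el noise sigma=0.1 deg: E[RMS-S2S]=2 sigma,
        E[STD]=sigma*sqrt(2), ratio sqrt(2), each within 10% at n=500."""
        rng = np.random.default_rng(11)
        az = rng.normal(0, 0.1, 500)
        el = rng.normal(0, 0.1, 500)
        x = 600.0 * np.tan(np.radians(az))
        y = -600.0 * np.tan(np.radians(el))
        s = make_series(np.column_stack([x, y]))
        rms, std = precision(s, fixation_at((0, 0), first=0, last=499), (0.0, 0.0))
        assert rms == pytest.approx(0.2, rel=0.10)
        assert std == pytest.approx(0.1 * np.sqrt(2), rel=0.10)
        assert rms / std == pytest.approx(np.sqrt(2), rel=0.10)

    def test_rms_std_ratio_direction(self):
        """Anti-correlated jitter drives RMS/STD above sqrt(2); slow
        drift drives it below."""
        d = 600.0 * np.tan(np.radians(0.1))
        anti = make_series([(d * (-1) ** i, 0.0) for i in range(100)])
        f = fixation_at((0, 0), first=0, last=99)
        rms_a, std_a = precision(anti, f, (0.0, 0.0))
        assert rms_a / std_a > np.sqrt(2)
        drift = make_series([(i * 0.05, 0.0) for i in range(100)])
        rms_d, std_d = precision(drift, f, (0.0, 0.0))
        assert rms_d / std_d < np.sqrt(2)

    def test_single_sample_missing_precision(self):
        s = make_series([(0.0, 0.0)])
        rms, std = precision(s, fixation_at((0, 0), first=0, last=0), (0.0, 0.0))
        assert np.isnan(rms) and np.isnan(std)


class TestGazeRange:
    def test_still_head_spans_target_grid(self, clean_summary_pose):
        h, v = clean_summary_pose.gaze_range_deg
        assert h == pytest.approx(20.0, abs=0.05)
        assert v == pytest.approx(17.5, abs=0.05)

    def test_single_match_is_missing(self, poster, calib):
        s = make_series([(0.0, 0.0)] * 10)
        s.gaze_px[:] = [960.0, 540.0]
        matches = [gv.TargetMatch(5, fixation_at((0, 0), first=0, last=9), 0.0)]
        h, v = gaze_range(s, matches, calib)
        assert np.isnan(h) and np.isnan(v)

    def test_head_pointing_gives_near_zero_range(self, poster, calib):
        """Eye-in-head constant (gaze pixel fixed at the principal
        point) while the head re-aims at each target: range ~ 0."""
        s = make_series([(0.0, 0.0)] * 90)
        s.gaze_px[:] = [calib.cx, calib.cy]
        matches = [
            gv.TargetMatch(t.id, fixation_at((t.x, t.y), first=10 * i, last=10 * i + 9), 0.0)
            for i, t in enumerate(poster.targets)
        ]
        h, v = gaze_range(s, matches, calib)
        assert h == pytest.approx(0.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-9)


class TestErrorRatio:
    def test_equal_accuracies_give_100(self):
        a = DataQualityResult(target_id=1, accuracy_deg=0.8, rms_s2s_deg=0.1,
                              std_deg=0.05, matched=True)
        r = fixed_distance_error_ratio(a, a)
        assert r["accuracy_pct"] == pytest.approx(100.0)
        assert r["rms_s2s_pct"] == pytest.approx(100.0)

    def test_distance_mismatch_ratio(self):
        """Gaze 10 mm off a central target viewed from 800 mm but
        assumed at 600 mm inflates accuracy by atan(10/600)/atan(10/800)."""
        fixed = DataQualityResult(target_id=5, matched=True,
                                  accuracy_deg=np.degrees(np.arctan(10 / 600)))
        phys = DataQualityResult(target_id=5, matched=True,
                                 accuracy_deg=np.degrees(np.arctan(10 / 800)))
        r = fixed_distance_error_ratio(fixed, phys)
        assert r["accuracy_pct"] == pytest.approx(133.3, abs=0.05)

    def test_zero_denominator_flagged(self):
        fixed = DataQualityResult(target_id=1, accuracy_deg=0.5, matched=True)
        phys = DataQualityResult(target_id=1, accuracy_deg=0.0, matched=True)
        assert fixed_distance_error_ratio(fixed, phys)["accuracy_pct"] is None


class TestSummarize:
    @staticmethod
    def summary(accs, unmatched=0, name="rec1"):
        results = [
            DataQualityResult(target_id=i + 1, accuracy_deg=a, rms_s2s_deg=0.1,
                              std_deg=0.05, n_samples=50, matched=True)
            for i, a in enumerate(accs)
        ]
        results += [DataQualityResult(target_id=len(accs) + 1 + k)
                    for k in range(unmatched)]
        return gv.EpisodeSummary(
            results=results, data_loss_percent=0.0, gaze_range_deg=(20.0, 17.5),
            mode="pose_estimated",
            episode=gv.EpisodeAnnotation(0.0, 9000.0, "validation"),
            recording_name=name)

    def test_mean_over_targets(self):
        s = self.summary([0.5 + 0.1 * i for i in range(9)])
        df = summarize([s], average_over_targets=True)
        assert len(df) == 1
        assert df.iloc[0]["accuracy_deg"] == pytest.approx(0.9)

    def test_unmatched_excluded_from_average(self):
        s = self.summary([1.0] * 8, unmatched=1)
        df = summarize([s], average_over_targets=True)
        assert df.iloc[0]["accuracy_deg"] == pytest.approx(1.0)
        assert df.iloc[0]["n_unmatched"] == 1

    def test_row_per_target_and_episode(self):
        rows = summarize([self.summary([1.0] * 9, name="a"),
                          self.summary([1.0] * 9, name="b")])
        assert len(rows) == 18
        assert set(rows["recording"]) == {"a", "b"}
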