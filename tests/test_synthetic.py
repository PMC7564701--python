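import numpy as np
import pytest
from PIL import Image

from flygroom.dataset import CLASS_TO_ID
from flygroom.features import FeatureConfig, extract_stream, locate_roi, motion_energy
from flygroom.imaging import ColorThreshold, to_gray_square
from flygroom.synthetic import (
    DEFAULT_APPENDAGES,
    SyntheticScene,
    random_scene,
    render_feature_dataset,
    render_video,
)


class TestRenderVideo:
    def test_same_seed_bit_identical(self):
        scene = SyntheticScene(n_frames=10, schedule=(("wing", 0, 9),),
                               min_interval_frames=10, seed=7)
        a, _ = render_video(scene)
        b, _ = render_video(scene)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_lazy_and_eager_agree(self):
        scene = SyntheticScene(n_frames=8, seed=4)
        eager, _ = render_video(scene)
        lazy, _ = render_video(scene, lazy=True)
        for x, y in zip(eager, lazy):
            np.testing.assert_array_equal(x, y)

    def test_noiseless_motionless_scene_has_zero_motion_energy(self):
        scene = SyntheticScene(n_frames=9, noise_sigma=0.0, seed=0)
        frames, _ = render_video(scene)
        stack = np.stack([to_gray_square(f).astype(float) / 255 for f in frames[:7]])
        assert motion_energy(stack).max() == 0.0

    def test_roi_lands_in_head_patch(self, head_scene_frames):
        scene, frames, _ = head_scene_frames
        app = DEFAULT_APPENDAGES["head"]
        pr = scene.body_center[0] + app.offset[0]
        pc = scene.body_center[1] + app.offset[1]
        for start in range(0, 20, 5):
            stack = np.stack(
                [to_gray_square(f).astype(float) / 255 for f in frames[start : start + 7]]
            )
            r, c = locate_roi(motion_energy(stack))
            assert abs(r - pr) <= app.radius and abs(c - pc) <= app.radius

    def test_background_and_body_respect_threshold_window(self):
        scene = SyntheticScene(n_frames=3, noise_sigma=0.0, seed=0)
        frames, _ = render_video(scene)
        from flygroom.imaging import background_mask

        mask = background_mask(frames[0], ColorThreshold())
        rr, cc = np.mgrid[0 : scene.size, 0 : scene.size]
        r0, c0 = scene.body_center
        ar, ac = scene.body_axes
        d = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2
        assert (mask[d > 1.05] == 255).all()  # background passes the window
        assert (mask[d < 0.95] == 0).all()    # body fails it

    def test_ground_truth_matches_schedule(self):
        scene = SyntheticScene(
            n_frames=120,
            schedule=(("head", 10, 40), ("wing", 60, 100)),
            seed=0,
        )
        _, truth = render_video(scene)
        assert len(truth.intervals) == 2
        assert truth.labels[0] == CLASS_TO_ID["motionless"]
        assert (truth.labels[10:41] == CLASS_TO_ID["head"]).all()
        assert (truth.labels[60:101] == CLASS_TO_ID["wing"]).all()

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SyntheticScene(n_frames=200, schedule=(("head", 0, 50), ("wing", 30, 90)))
        with pytest.raises(ValueError, match="shorter"):
            SyntheticScene(n_frames=200, schedule=(("head", 0, 10),))
        with pytest.raises(ValueError, match="past the last"):
            SyntheticScene(n_frames=50, schedule=(("head", 0, 60),))
        with pytest.raises(ValueError, match="unknown"):
            SyntheticScene(n_frames=200, schedule=(("jumping", 0, 50),))

    def test_background_must_pass_and_body_fail_window(self):
        with pytest.raises(ValueError, match="background"):
            SyntheticScene(background=(40, 30, 20))
        with pytest.raises(ValueError, match="body"):
            SyntheticScene(body_color=(180, 140, 100))


class TestRenderFeatureDataset:
    def test_counts_and_manifest(self, tmp_path):
        m = render_feature_dataset(tmp_path, per_class=3, seed=1, scene_windows=3)
        assert m.class_counts == {c: 3 for c in m.class_counts}
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "head_1.png").exists()

    def test_reproducible_from_seed(self, tmp_path):
        m1 = render_feature_dataset(tmp_path / "a", classes=["head"], per_class=2, seed=9)
        m2 = render_feature_dataset(tmp_path / "b", classes=["head"], per_class=2, seed=9)
        for (p1, _), (p2, _) in zip(
            m1.records.itertuples(index=False), m2.records.itertuples(index=False)
        ):
            np.testing.assert_array_equal(
                np.asarray(Image.open(p1)), np.asarray(Image.open(p2))
            )

    def test_front_and_rear_classes_differ_in_red_mass_location(self, tmp_path):
        m = render_feature_dataset(
            tmp_path, classes=["head", "abdomen"], per_class=4, seed=2, scene_windows=4
        )
        rows = {"head": [], "abdomen": []}
        for path, label in m.records.itertuples(index=False):
            px = np.asarray(Image.open(path)).astype(float)
            red = px[..., 0]
            green = px[..., 1]
            rr = np.mgrid[0:100, 0:100][0]
            # body silhouette sits below a front patch, above a rear patch
            cls = "head" if label == CLASS_TO_ID["head"] else "abdomen"
            rows[cls].append((rr * green).sum() / green.sum())
        assert max(rows["head"]) > 55  # silhouette mass in the lower half
        assert min(rows["abdomen"]) < 45


class TestSceneYaml:
    def test_round_trip(self, tmp_path):
        from flygroom.synthetic import scene_from_yaml, scene_to_yaml

        scene = SyntheticScene(
            n_frames=120, schedule=(("wing", 10, 60),), noise_sigma=1.5, seed=9
        )
        path = tmp_path / "scene.yaml"
        scene_to_yaml(scene, path)
        assert scene_from_yaml(path) == scene


class TestRandomScene:
    def test_schedule_is_valid_and_fits(self):
        scene = random_scene(n_frames=2000, n_behaviors=5, seed=3)
        assert len(scene.schedule) == 5
        prev_end = -1
        for cls, start, end in scene.schedule:
            assert cls != "motionless"
            assert start > prev_end
            assert end - start + 1 >= 25
            prev_end = end
        assert prev_end < 2000

    def test_no_immediate_class_repeats(self):
        scene = random_scene(n_frames=4000, n_behaviors=8, seed=11)
        classes = [c for c, _, _ in scene.schedule]
        assert all(a != b for a, b in zip(classes, classes[1:]))

    def test_overfull_schedule_rejected(self):
        with pytest.raises(ValueError):
            random_scene(n_frames=200, n_behaviors=10, seed=0)
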