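"""Synthetic fly videos with known ground truth.

No footage is distributed with the package, so every pipeline stage is
exercised on parametric scenes that reproduce the properties the method
relies on: a warm-toned background whose RGB values sit strictly inside
the background color window, a dark elliptical fly body that fails the
window, and a localized oscillating appendage patch per behavior class.
Patch placement follows the animal's anatomy — forelegs and head are
groomed at the front of the body, abdomen and hind legs at the rear,
middle-leg and wing grooming laterally — so the spatial channels carry
the same front/rear context that separates real grooming classes.
Within a location pair (foreleg vs head, hindleg vs abdomen) the classes
differ in oscillation amplitude, patch size and period: fast leg rubbing
is high-energy, head/abdomen care is gentler.

Scenes are fully determined by their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

from .dataset import BEHAVIOR_CLASSES, CLASS_TO_ID, LabelManifest, build_manifest
from .ethogram import BehaviorInterval
from .features import FeatureConfig, extract_stream
from .imaging import ColorThreshold

__all__ = [
    "AppendageModel",
    "SyntheticScene",
    "GroundTruth",
    "DEFAULT_APPENDAGES",
    "render_video",
    "render_feature_dataset",
]


@dataclass(frozen=True)
class AppendageModel:
    """Oscillating-patch model of one grooming behavior.

    offset
        Patch center relative to the body center, (rows, cols); negative
        rows are anterior.
    radius
        Patch radius in pixels; intensity modulation falls off
        quadratically to zero at the rim so the motion energy peaks at
        the patch center.
    period
        Oscillation period in frames.
    amplitude, base
        Gray-level swing and midpoint of the patch brightness.
    """

    offset: tuple[float, float]
    radius: float = 12.0
    period: float = 4.0
    amplitude: float = 70.0
    base: float = 130.0


#: Anatomy-driven default appendage model per behavior class.
DEFAULT_APPENDAGES: dict[str, AppendageModel] = {
    "foreleg": AppendageModel(offset=(-105.0, 0.0), radius=12.0, period=3.0, amplitude=75.0),
    "head": AppendageModel(offset=(-95.0, 0.0), radius=16.0, period=7.0, amplitude=35.0),
    "mid": AppendageModel(offset=(0.0, 70.0), radius=12.0, period=5.0, amplitude=55.0),
    "abdomen": AppendageModel(offset=(95.0, 0.0), radius=16.0, period=7.0, amplitude=35.0),
    "hindleg": AppendageModel(offset=(105.0, 0.0), radius=12.0, period=3.0, amplitude=75.0),
    "wing": AppendageModel(offset=(60.0, 75.0), radius=24.0, period=5.0, amplitude=55.0),
}


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame labels and the scheduled behavior intervals."""

    labels: np.ndarray  #: int class id per frame; motionless where unscheduled
    intervals: tuple[BehaviorInterval, ...]


@dataclass(frozen=True)
class SyntheticScene:
    """Parametric description of one fake fly video."""

    n_frames: int = 100
    size: int = 500
    background: tuple[int, int, int] = (180, 140, 100)
    body_center: tuple[float, float] = (250.0, 250.0)
    body_axes: tuple[float, float] = (90.0, 55.0)
    body_color: tuple[int, int, int] = (40, 30, 20)
    schedule: tuple[tuple[str, int, int], ...] = ()
    appendages: dict[str, AppendageModel] = field(
        default_factory=lambda: dict(DEFAULT_APPENDAGES)
    )
    noise_sigma: float = 2.0
    fps: float = 25.0
    seed: int = 0
    min_interval_frames: int = 25

    def __post_init__(self) -> None:
        thr = ColorThreshold()
        lo, hi = np.asarray(thr.low), np.asarray(thr.high)
        bg, body = np.asarray(self.background), np.asarray(self.body_color)
        if not (np.all(bg > lo) and np.all(bg < hi)):
            raise ValueError(f"background {self.background} must lie inside {thr}")
        if np.all(body > lo) and np.all(body < hi):
            raise ValueError(f"body color {self.body_color} must violate {thr}")
        prev_end = -1
        for cls, start, end in self.schedule:
            if cls not in CLASS_TO_ID:
                raise ValueError(f"unknown behavior class {cls!r}")
            if start <= prev_end:
                raise ValueError("schedule intervals must be disjoint and ordered")
            if end - start + 1 < self.min_interval_frames:
                raise ValueError(
                    f"scheduled interval ({cls}, {start}, {end}) shorter than "
                    f"{self.min_interval_frames} frames"
                )
            if end >= self.n_frames:
                raise ValueError("schedule extends past the last frame")
            prev_end = end

    def ground_truth(self) -> GroundTruth:
        labels = np.full(self.n_frames, CLASS_TO_ID["motionless"], dtype=int)
        intervals = []
        for cls, start, end in self.schedule:
            if cls == "motionless":
                continue
            labels[start : end + 1] = CLASS_TO_ID[cls]
            intervals.append(
                BehaviorInterval(behavior=cls, start_frame=start, end_frame=end, fps=self.fps)
            )
        return GroundTruth(labels=labels, intervals=tuple(intervals))


def _base_frame(scene: SyntheticScene) -> np.ndarray:
    """Static background + body ellipse, float64 H x W x 3."""
    s = scene.size
    frame = np.empty((s, s, 3), dtype=np.float64)
    frame[:] = scene.background
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    r0, c0 = scene.body_center
    ar, ac = scene.body_axes
    inside = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    frame[inside] = scene.body_color
    return frame


def _patch_kernel(scene: SyntheticScene, app: AppendageModel) -> tuple[np.ndarray, np.ndarray]:
    """Boolean footprint and [0,1] radial weight of the patch."""
    s = scene.size
    pr = scene.body_center[0] + app.offset[0]
    pc = scene.body_center[1] + app.offset[1]
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    d2 = ((rr - pr) ** 2 + (cc - pc) ** 2) / app.radius**2
    weight = np.clip(1.0 - d2, 0.0, 1.0)
    return weight > 0, weight


def _iter_frames(scene: SyntheticScene) -> Iterator[np.ndarray]:
    rng = np.random.default_rng(scene.seed)
    base = _base_frame(scene)
    truth = scene.ground_truth()
    # one random phase per scheduled interval, drawn up front
    phases = {i: rng.uniform(0, 2 * math.pi) for i in range(len(scene.schedule))}
    kernels = {}
    sched = list(scene.schedule)
    for t in range(scene.n_frames):
        frame = base.copy()
        for i, (cls, start, end) in enumerate(sched):
            if not (start <= t <= end) or cls == "motionless":
                continue
            app = scene.appendages[cls]
            if cls not in kernels:
                kernels[cls] = _patch_kernel(scene, app)
            _, weight = kernels[cls]
            g = app.base + app.amplitude * math.sin(
                2 * math.pi * (t - start) / app.period + phases[i]
            )
            k = weight[..., None]
            frame = frame * (1.0 - k) + k * g
        if scene.noise_sigma > 0:
            frame = frame + rng.normal(0.0, scene.noise_sigma, size=frame.shape)
        yield frame.clip(0, 255).astype(np.uint8)


def render_video(
    scene: SyntheticScene, lazy: bool = False
) -> tuple[Sequence[np.ndarray] | Iterator[np.ndarray], GroundTruth]:
    """Render the scene into RGB uint8 frames plus its ground truth.

    With ``lazy=True`` the frames are a generator (constant memory, for
    long videos); otherwise a list.  Output is bit-identical for a given
    scene regardless of laziness.
    """
    frames = _iter_frames(scene)
    truth = scene.ground_truth()
    if lazy:
        return frames, truth
    return list(frames), truth


def scene_to_yaml(scene: SyntheticScene, path: str | Path) -> None:
    """Persist a scene spec as YAML."""
    import yaml

    data = {
        "n_frames": scene.n_frames,
        "size": scene.size,
        "background": list(scene.background),
        "body_center": list(scene.body_center),
        "body_axes": list(scene.body_axes),
        "body_color": list(scene.body_color),
        "schedule": [[c, int(s), int(e)] for c, s, e in scene.schedule],
        "appendages": {
            cls: {
                "offset": list(app.offset),
                "radius": app.radius,
                "period": app.period,
                "amplitude": app.amplitude,
                "base": app.base,
            }
            for cls, app in scene.appendages.items()
        },
        "noise_sigma": scene.noise_sigma,
        "fps": scene.fps,
        "seed": scene.seed,
        "min_interval_frames": scene.min_interval_frames,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scene_from_yaml(path: str | Path) -> SyntheticScene:
    """Load a scene spec written by :func:`scene_to_yaml`."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "appendages" in data:
        data["appendages"] = {
            cls: AppendageModel(
                offset=tuple(a["offset"]),
                radius=a["radius"],
                period=a["period"],
                amplitude=a["amplitude"],
                base=a["base"],
            )
            for cls, a in data["appendages"].items()
        }
    for key in ("background", "body_center", "body_axes", "body_color"):
        if key in data:
            data[key] = tuple(data[key])
    if "schedule" in data:
        data["schedule"] = tuple((c, int(s), int(e)) for c, s, e in data["schedule"])
    return SyntheticScene(**data)


def write_frames(frames: Sequence[np.ndarray], out_dir: str | Path) -> list[Path]:
    """Save frames as losslessly encoded, numerically named PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:06d}.png"
        Image.fromarray(frame).save(p)
        paths.append(p)
    return paths


def random_scene(
    n_frames: int = 3000,
    n_behaviors: int = 6,
    seed: int = 0,
    min_len: int = 80,
    max_len: int = 400,
    gap: tuple[int, int] = (40, 120),
) -> SyntheticScene:
    """A scene with ``n_behaviors`` randomly drawn grooming bouts
    separated by motionless gaps.

    Bout classes are drawn without immediate repeats; bout lengths are
    uniform in ``[min_len, max_len]`` and gaps in ``gap``, truncated if
    necessary so everything fits inside ``n_frames``.
    """
    rng = np.random.default_rng(seed)
    active = [c for c in BEHAVIOR_CLASSES if c != "motionless"]
    lengths = rng.integers(min_len, max_len + 1, size=n_behaviors)
    gaps = rng.integers(gap[0], gap[1] + 1, size=n_behaviors + 1)
    excess = int(lengths.sum() + gaps.sum()) - n_frames
    if excess > 0:
        # shrink draws proportionally toward their minima so the
        # schedule fits while bout lengths stay >= min_len
        slack_l = lengths - min_len
        slack_g = gaps - gap[0]
        pool = int(slack_l.sum() + slack_g.sum())
        if excess > pool:
            raise ValueError(
                f"{n_behaviors} bouts of >= {min_len} frames with >= {gap[0]}-frame "
                f"gaps do not fit in {n_frames} frames"
            )
        ratio = 1.0 - excess / pool
        lengths = min_len + np.floor(slack_l * ratio).astype(int)
        gaps = gap[0] + np.floor(slack_g * ratio).astype(int)
    schedule = []
    t = int(gaps[0])
    prev_cls = None
    for i in range(n_behaviors):
        cls = str(rng.choice([c for c in active if c != prev_cls]))
        schedule.append((cls, t, t + int(lengths[i]) - 1))
        t += int(lengths[i]) + int(gaps[i + 1])
        prev_cls = cls
    return SyntheticScene(
        n_frames=n_frames,
        schedule=tuple(schedule),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _jittered(
    app: AppendageModel, rng: np.random.Generator
) -> AppendageModel:
    return AppendageModel(
        offset=(
            app.offset[0] * rng.uniform(0.9, 1.1),
            app.offset[1] * rng.uniform(0.9, 1.1) + rng.uniform(-5, 5),
        ),
        radius=max(6.0, app.radius + rng.uniform(-2, 2)),
        period=app.period * rng.uniform(0.85, 1.2),
        amplitude=app.amplitude * rng.uniform(0.85, 1.15),
        base=app.base + rng.uniform(-10, 10),
    )


def render_feature_dataset(
    out_dir: str | Path,
    classes: Sequence[str] = BEHAVIOR_CLASSES,
    per_class: int = 300,
    seed: int = 0,
    cfg: FeatureConfig | None = None,
    scene_windows: int = 10,
) -> LabelManifest:
    """Render a labeled feature-image dataset with ``per_class`` images
    per behavior class.

    Each class is covered by several short single-behavior scenes with
    jittered body placement and appendage geometry (``scene_windows``
    feature images per scene), so the dataset varies in patch position,
    phase, period and amplitude.  Images are written as
    ``<class>_<n>.png`` and a ``manifest.csv`` alongside.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    if cfg is None:
        cfg = FeatureConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_frames = cfg.window + scene_windows - 1
    for cls in classes:
        n_written = 0
        counter = 0
        while n_written < per_class:
            center = (250.0 + rng.uniform(-25, 25), 250.0 + rng.uniform(-25, 25))
            apps = dict(DEFAULT_APPENDAGES)
            schedule: tuple[tuple[str, int, int], ...]
            if cls == "motionless":
                schedule = ()
            else:
                apps[cls] = _jittered(DEFAULT_APPENDAGES[cls], rng)
                schedule = ((cls, 0, n_frames - 1),)
            scene = SyntheticScene(
                n_frames=n_frames,
                body_center=center,
                schedule=schedule,
                appendages=apps,
                seed=int(rng.integers(0, 2**31 - 1)),
                min_interval_frames=min(25, n_frames),
            )
            frames, _ = render_video(scene, lazy=True)
            for fi in extract_stream(frames, cfg):
                if n_written >= per_class:
                    break
                counter += 1
                Image.fromarray(fi.pixels).save(out_dir / f"{cls}_{counter}.png")
                n_written += 1
    manifest = build_manifest(out_dir)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest
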