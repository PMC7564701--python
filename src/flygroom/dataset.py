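"""Labeled manifests of feature images and train/validation splitting.

Feature images are labeled by storing them in class-named folders and/or
naming them ``<class>_<n>.png`` (e.g. ``head_1.png`` ... ``head_5202.png``).
Seven behavior classes are recognised, with fixed integer ids:

====  ==========
 id   class
====  ==========
 0    foreleg
 1    head
 2    mid
 3    abdomen
 4    hindleg
 5    wing
 6    motionless
====  ==========

The head class merges feeler, mouth and eye grooming; mid covers all
grooming with middle-leg participation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BEHAVIOR_CLASSES",
    "CLASS_TO_ID",
    "ID_TO_CLASS",
    "LabelManifest",
    "build_manifest",
    "split_manifest",
]

BEHAVIOR_CLASSES: tuple[str, ...] = (
    "foreleg",
    "head",
    "mid",
    "abdomen",
    "hindleg",
    "wing",
    "motionless",
)
CLASS_TO_ID: dict[str, int] = {c: i for i, c in enumerate(BEHAVIOR_CLASSES)}
ID_TO_CLASS: dict[int, str] = {i: c for i, c in enumerate(BEHAVIOR_CLASSES)}

# <class>_<n> filename pattern; 'hind_leg'/'hindleg' both accepted.
_NAME_RE = re.compile(
    r"^(foreleg|head|mid|abdomen|hind_?leg|wing|motionless)[_\-]?\d*$",
    re.IGNORECASE,
)


def _class_of(token: str) -> str | None:
    m = _NAME_RE.match(token)
    if m is None:
        return None
    return m.group(1).lower().replace("_", "")


@dataclass
class LabelManifest:
    """Records of (image path, class id), with per-class counts."""

    records: pd.DataFrame  #: columns 'path' (str) and 'label' (int)
    rejects: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.records["label"].value_counts().to_dict()
        return {ID_TO_CLASS[i]: int(counts.get(i, 0)) for i in range(len(BEHAVIOR_CLASSES))}

    def write_csv(self, path: str | Path) -> None:
        df = self.records.copy()
        df["path"] = df["path"].str.replace("\\", "/", regex=False)
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabelManifest":
        df = pd.read_csv(path, dtype={"path": str, "label": int})
        if list(df.columns) != ["path", "label"]:
            raise ValueError(f"manifest {path} must have columns path,label")
        if len(df) and not df["label"].between(0, len(BEHAVIOR_CLASSES) - 1).all():
            raise ValueError("label ids must lie in 0..6")
        return cls(records=df)


def build_manifest(root: str | Path) -> LabelManifest:
    """Scan *root* for labeled feature images.

    The class is inferred from the filename prefix (``head_12.png`` ->
    head) with the parent folder name as fallback; files matching
    neither are skipped with a warning and listed in ``rejects``.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such dataset root: {root}")
    paths, labels, rejects = [], [], []
    for p in sorted(root.rglob("*")):
        if not p.is_file() or p.suffix.lower() not in {".png", ".jpg", ".jpeg", ".bmp"}:
            continue
        cls = _class_of(p.stem) or _class_of(p.parent.name)
        if cls is None:
            logger.warning("cannot infer class of %s; skipped", p)
            rejects.append(str(p))
            continue
        paths.append(p.as_posix())
        labels.append(CLASS_TO_ID[cls])
    df = pd.DataFrame({"path": paths, "label": np.asarray(labels, dtype=int)})
    return LabelManifest(records=df, rejects=rejects)


def split_manifest(
    manifest: LabelManifest,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[LabelManifest, LabelManifest]:
    """Stratified train/validation split (default ratio 7:3).

    Per class, ``floor(train_fraction * n)`` records go to the training
    set and the remainder to validation; shuffling depends only on
    *seed* and is invariant to the input record order.
    """
    df = manifest.records
    if df.empty:
        raise ValueError("cannot split an empty manifest")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for label, group in df.sort_values("path").groupby("label"):
        if len(group) < 2:
            raise ValueError(
                f"class {ID_TO_CLASS[int(label)]!r} has {len(group)} item(s); "
                "need >= 2 to stratify"
            )
        order = rng.permutation(len(group))
        n_train = int(np.floor(train_fraction * len(group)))
        shuffled = group.iloc[order]
        train_parts.append(shuffled.iloc[:n_train])
        val_parts.append(shuffled.iloc[n_train:])
    train = pd.concat(train_parts, ignore_index=True)
    val = pd.concat(val_parts, ignore_index=True)
    return LabelManifest(records=train), LabelManifest(records=val)
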