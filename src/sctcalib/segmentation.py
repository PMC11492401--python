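"""Intensity-threshold tissue segmentation of CT volumes.

Five classes are separated by four strictly increasing HU cut points. The
default boundaries sit at the midpoints between adjacent class CT means
(−548, −29.5, 128, 609.5 HU) and are config-overridable. An optional
morphological opening per class drops isolated boundary / partial-volume-like
voxels; voxels removed by opening are flagged unclassified, never reassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .phantom import StructureSet
from .tissues import CLASS_NAMES
from .volume import Volume3D

__all__ = ["ThresholdScheme", "segment_classes", "class_hu_stats"]


@dataclass(frozen=True)
class ThresholdScheme:
    """Ordered HU boundaries between the five classes, plus cleanup radius."""

    boundaries: tuple[float, float, float, float] = (-548.0, -29.5, 128.0, 609.5)
    opening_radius: int = 1  # voxels; 0 disables cleanup

    def __post_init__(self):
        b = self.boundaries
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError(f"boundaries must be 4 strictly increasing values, got {b}")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"boundaries": list(self.boundaries), "opening_radius": self.opening_radius},
                fh,
            )

    @classmethod
    def load(cls, path) -> "ThresholdScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(tuple(raw["boundaries"]), raw.get("opening_radius", 1))


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


def segment_classes(ct: Volume3D, scheme: ThresholdScheme | None = None) -> StructureSet:
    """Assign every voxel to a class by its HU interval, then clean up.

    Returns a StructureSet with the five class masks plus ``unclassified``
    (voxels dropped by the opening). Before cleanup the class masks exactly
    partition the grid; any finite HU maps to some interval.
    """
    scheme = scheme or ThresholdScheme()
    values = np.asarray(ct.values)
    if not np.all(np.isfinite(values)):
        raise ValueError("CT contains non-finite HU values")
    labels = np.digitize(values, scheme.boundaries)  # 0..4

    masks: dict[str, np.ndarray] = {}
    unclassified = np.zeros(ct.shape, dtype=bool)
    ball = _ball(scheme.opening_radius)
    for i, name in enumerate(CLASS_NAMES):
        raw = labels == i
        if scheme.opening_radius > 0:
            opened = ndimage.binary_opening(raw, structure=ball)
            unclassified |= raw & ~opened
            masks[name] = opened
        else:
            masks[name] = raw
    masks["unclassified"] = unclassified
    return StructureSet(masks, ct.spacing, ct.origin)


def class_hu_stats(ct: Volume3D, masks: StructureSet | dict) -> pd.DataFrame:
    """Per-class HU mean, population std and voxel count over the masks.

    Empty masks are reported with count 0 and NaN moments. Raises on mask /
    volume shape mismatch.
    """
    mask_dict = masks.class_masks() if isinstance(masks, StructureSet) else masks
    rows = []
    for name, mask in mask_dict.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ct.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != CT shape {ct.shape}")
        vals = ct.values[mask]
        n = int(vals.size)
        rows.append(
            {
                "class": name,
                "mean_hu": float(np.mean(vals)) if n else float("nan"),
                "std_hu": float(np.std(vals)) if n else float("nan"),  # population (÷N)
                "n_voxels": n,
            }
        )
    return pd.DataFrame(rows)
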