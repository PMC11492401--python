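"""Tissue-class definitions for bulk-density synthetic CT work.

Five classes cover the pelvis: air, adipose, soft tissue, inner (trabecular)
bone and outer (cortical) bone. Each class carries the CT HU statistics used
to synthesize patient-like CT volumes, the fixed bulk HU the vendor-style sCT
assigns, and the class relative electron density (RED, water = 1.0) used by
calibration curves and the dose engine.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

__all__ = [
    "TissueClassSpec",
    "CLASS_NAMES",
    "default_tissue_classes",
    "DEFAULT_RED_BY_CLASS",
    "save_tissue_classes",
    "load_tissue_classes",
]

CLASS_NAMES = ("air", "adipose", "soft_tissue", "inner_bone", "outer_bone")


@dataclass(frozen=True)
class TissueClassSpec:
    """One tissue class: CT HU distribution, sCT bulk HU, and RED."""

    name: str
    ct_mean_hu: float
    ct_std_hu: float
    sct_bulk_hu: float
    red: float

    def __post_init__(self):
        if self.name not in CLASS_NAMES:
            raise ValueError(f"unknown tissue class {self.name!r}")
        if self.ct_std_hu < 0:
            raise ValueError("ct_std_hu must be >= 0")
        if self.red < 0:
            raise ValueError("red must be >= 0")


# Pelvis defaults: CT column mean +/- std from a 10-patient prostate cohort;
# sCT bulk values are the vendor assignment for the same classes. Air RED is
# set to 1e-3 (near-vacuum) rather than 0 to keep path-length logs finite.
def default_tissue_classes() -> list[TissueClassSpec]:
    return [
        TissueClassSpec("air", -1000.0, 0.0, -1000.0, 0.001),
        TissueClassSpec("adipose", -96.0, 6.1, -75.0, 0.95),
        TissueClassSpec("soft_tissue", 37.0, 3.9, 0.0, 1.04),
        TissueClassSpec("inner_bone", 219.0, 14.0, 204.0, 1.10),
        TissueClassSpec("outer_bone", 1000.0, 23.0, 1170.0, 1.70),
    ]


DEFAULT_RED_BY_CLASS = {c.name: c.red for c in default_tissue_classes()}


def classes_by_name(classes) -> dict[str, TissueClassSpec]:
    out = {}
    for c in classes:
        if c.name in out:
            raise ValueError(f"duplicate tissue class {c.name!r}")
        out[c.name] = c
    return out


def save_tissue_classes(classes, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"tissue_classes": [asdict(c) for c in classes]}, fh)


def load_tissue_classes(path) -> list[TissueClassSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [TissueClassSpec(**d) for d in raw["tissue_classes"]]
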