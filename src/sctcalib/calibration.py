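"""HU -> relative-electron-density (RED) calibration curves.

A curve is an ordered list of (HU, RED) anchors with piecewise-linear
interpolation between anchors, constant extension below the lowest anchor,
and linear continuation of the last segment above the highest anchor clamped
at a configurable maximum RED (guards against fiducial-level HU producing
unphysical densities). Two standard constructions are provided:

* the *original* (vendor) curve, anchored at the bulk sCT HU values; and
* the *optimized* curve, anchored at cohort-averaged CT class means, with the
  bone anchors optionally kept at the vendor sCT values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tissues import CLASS_NAMES, DEFAULT_RED_BY_CLASS, TissueClassSpec, classes_by_name
from .volume import Volume3D

__all__ = [
    "CalibrationCurve",
    "CohortStats",
    "build_original_curve",
    "derive_optimized_curve",
    "eval_curve",
]

# classes that contribute anchors, in ascending-HU order for a pelvis
ANCHOR_CLASSES = ("air", "adipose", "soft_tissue", "inner_bone", "outer_bone")


@dataclass
class CalibrationCurve:
    """Ordered (HU, RED) anchors plus interpolation/extrapolation rules."""

    anchors: np.ndarray  # (k, 2): HU ascending, RED non-decreasing
    interpolation: str = "linear"
    extrapolation: str = "clamp-low,linear-high"
    max_red: float = 3.0
    provenance: str = "custom"

    def __post_init__(self):
        a = np.asarray(self.anchors, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
            raise ValueError("anchors must be an (k>=2, 2) array of (hu, red)")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"anchors must be finite, got {a}")
        if np.any(np.diff(a[:, 0]) <= 0):
            raise ValueError(f"anchor HU must be strictly increasing, got {a[:, 0]}")
        if np.any(a[:, 1] < 0):
            raise ValueError("relative electron density must be non-negative")
        if np.any(np.diff(a[:, 1]) < 0):
            raise ValueError(
                f"RED must be non-decreasing with HU (physical monotonicity), got {a[:, 1]}"
            )
        self.anchors = a

    # ---- evaluation -----------------------------------------------------

    def __call__(self, hu):
        if isinstance(hu, Volume3D):
            return hu.with_values(self._eval_array(hu.values))
        return self._eval_array(hu)

    def _eval_array(self, hu):
        arr = np.asarray(hu, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite HU passed to calibration curve")
        h, r = self.anchors[:, 0], self.anchors[:, 1]
        out = np.interp(arr, h, r)  # linear inside, clamped at both ends
        above = arr > h[-1]
        if np.any(above):
            slope = (r[-1] - r[-2]) / (h[-1] - h[-2])
            out = np.where(above, np.minimum(r[-1] + slope * (arr - h[-1]), self.max_red), out)
        if arr.ndim == 0:
            return float(out)
        return out

    # ---- IO -------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Two-column CSV plus a JSON sidecar with the rules and provenance."""
        path = Path(path)
        pd.DataFrame(self.anchors, columns=["hu", "relative_electron_density"]).to_csv(
            path, index=False
        )
        sidecar = {
            "interpolation": self.interpolation,
            "extrapolation": self.extrapolation,
            "max_red": self.max_red,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        path = Path(path)
        df = pd.read_csv(path)
        kwargs = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            kwargs = json.loads(sidecar.read_text())
        return cls(df[["hu", "relative_electron_density"]].to_numpy(), **kwargs)


def eval_curve(curve: CalibrationCurve, hu):
    """Functional alias for ``curve(hu)``."""
    return curve(hu)


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------


@dataclass
class CohortStats:
    """Per-patient per-class HU statistics with cohort aggregation.

    ``per_patient`` has columns (patient, class, mean_hu, std_hu, n_voxels).
    The cohort class mean is the unweighted mean of per-patient class means
    (robust to body-size differences); a voxel-pooled mode is available.
    """

    per_patient: pd.DataFrame

    @classmethod
    def from_patients(cls, stats_frames: list[pd.DataFrame]) -> "CohortStats":
        frames = []
        for i, df in enumerate(stats_frames):
            df = df.copy()
            df.insert(0, "patient", i)
            frames.append(df)
        return cls(pd.concat(frames, ignore_index=True))

    def class_means(self, pooled: bool = False) -> dict[str, float]:
        """Cohort class means; patients with no voxels in a class are skipped."""
        df = self.per_patient
        out = {}
        for name, grp in df.groupby("class"):
            grp = grp[grp["n_voxels"] > 0]
            if grp.empty:
                out[name] = float("nan")
            elif pooled:
                w = grp["n_voxels"].to_numpy(dtype=float)
                m = grp["mean_hu"].to_numpy()
                out[name] = float(np.sum(w * m) / np.sum(w))
            else:
                out[name] = float(grp["mean_hu"].mean())
        return out

    def class_sem(self) -> dict[str, float]:
        """Standard error of the cohort mean (across per-patient means)."""
        out = {}
        for name, grp in self.per_patient.groupby("class"):
            m = grp["mean_hu"].to_numpy()
            out[name] = float(np.std(m, ddof=1) / np.sqrt(len(m))) if len(m) > 1 else 0.0
        return out

    def n_patients(self) -> int:
        return int(self.per_patient["patient"].nunique())

    def to_csv(self, path) -> None:
        self.per_patient.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortStats":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# curve constructions
# ---------------------------------------------------------------------------


def derive_optimized_curve(
    cohort: CohortStats,
    red_by_class: dict[str, float] | None = None,
    keep_sct_bone: bool = True,
    sct_bone_hu: tuple[float, float] = (204.0, 1170.0),
) -> CalibrationCurve:
    """Anchor the curve at cohort CT class means, paired with class REDs.

    With ``keep_sct_bone`` (default) the inner/outer bone anchors stay at the
    vendor sCT values — bulk sCT bone values sit within the literature range
    and are left untouched; otherwise the cohort bone means are used. Raises
    if the resulting anchors are non-monotone (implausible cohort).
    """
    red_by_class = red_by_class or DEFAULT_RED_BY_CLASS
    means = cohort.class_means()
    missing = [
        c for c in ANCHOR_CLASSES if c not in means or not np.isfinite(means[c])
    ]
    if missing:
        raise ValueError(
            f"cohort statistics have no voxels for classes: {missing}"
        )
    hu = {c: means[c] for c in ANCHOR_CLASSES}
    if keep_sct_bone:
        hu["inner_bone"], hu["outer_bone"] = sct_bone_hu
    anchors = [(hu[c], red_by_class[c]) for c in ANCHOR_CLASSES]
    return CalibrationCurve(np.array(anchors), provenance="optimized")


def build_original_curve(
    classes: list[TissueClassSpec],
    red_by_class: dict[str, float] | None = None,
    reference_curve: CalibrationCurve | None = None,
) -> CalibrationCurve:
    """Curve anchored at the vendor bulk sCT HU values.

    By default each anchor is paired with the class RED. Alternatively a
    ``reference_curve`` (e.g. the cohort CT calibration) supplies the REDs by
    evaluation at the bulk HUs — this models the pre-commissioning situation
    where the sCT's bulk HU values are pushed through a CT-derived calibration
    and is what makes the vendor HU choice dosimetrically consequential.
    """
    by_name = classes_by_name(classes)
    hus = [by_name[c].sct_bulk_hu for c in ANCHOR_CLASSES]
    if len(set(hus)) != len(hus):
        raise ValueError(f"duplicate HU anchors in scheme: {hus}")
    if reference_curve is not None:
        reds = [float(reference_curve(h)) for h in hus]
    else:
        red_by_class = red_by_class or DEFAULT_RED_BY_CLASS
        reds = [red_by_class[c] for c in ANCHOR_CLASSES]
    return CalibrationCurve(np.array(list(zip(hus, reds))), provenance="original")
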