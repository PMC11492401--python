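"""CT vs sCT HU agreement: difference maps, MAE, and bulk-value overrides.

MAE is the mean absolute voxelwise HU difference between two co-registered
volumes, by default over all imaging voxels (a body-mask mode is available
since background air inflates agreement; reports record which was used).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import StructureSet
from .volume import Volume3D

__all__ = ["difference_map", "mae", "override_classes", "cohort_mae_table"]


def difference_map(ct: Volume3D, sct: Volume3D) -> Volume3D:
    """Voxelwise CT − sCT on the shared grid (signed)."""
    ct.assert_coregistered(sct)
    return ct.with_values(np.asarray(ct.values, dtype=float) - np.asarray(sct.values, dtype=float))


def mae(a: Volume3D, b: Volume3D, mask: np.ndarray | None = None) -> float:
    """Mean absolute HU difference over ``mask`` voxels (all voxels if None)."""
    a.assert_coregistered(b)
    diff = np.abs(np.asarray(a.values, dtype=float) - np.asarray(b.values, dtype=float))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {a.shape}")
        if not mask.any():
            raise ValueError("MAE over an empty mask is undefined")
        diff = diff[mask]
    return float(diff.mean())


def override_classes(
    sct: Volume3D, masks: StructureSet | dict, new_hu_by_class: dict[str, float]
) -> Volume3D:
    """Return a copy of ``sct`` with each named class mask set to a fixed HU."""
    mask_dict = masks.masks if isinstance(masks, StructureSet) else masks
    out = sct.copy()
    out.values = np.asarray(out.values, dtype=float)
    for name, hu in new_hu_by_class.items():
        mask = np.asarray(mask_dict[name], dtype=bool)
        if mask.shape != sct.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != sCT shape {sct.shape}")
        out.values[mask] = hu
    return out


def cohort_mae_table(
    pairs,
    masks_per_patient,
    override_hu: dict[str, float],
    use_body_mask: bool = False,
) -> pd.DataFrame:
    """Per-patient original vs modified MAE table with a cohort summary row.

    ``pairs`` is a list of (CT, sCT) volumes; ``masks_per_patient`` the
    CT-derived class masks for each. The modified sCT has the ``override_hu``
    classes (typically adipose / soft tissue set to cohort CT means) replaced;
    bone is reported for the original sCT only. Total MAE covers all voxels by
    default, or the body mask when ``use_body_mask``.
    """
    if not pairs:
        raise ValueError("cohort must contain at least one patient")
    rows = []
    for i, ((ct, sct), masks) in enumerate(zip(pairs, masks_per_patient)):
        modified = override_classes(sct, masks, override_hu)
        total_mask = masks["body"] if (use_body_mask and "body" in masks) else None
        soft = np.asarray(masks["soft_tissue"], dtype=bool)
        adipose = np.asarray(masks["adipose"], dtype=bool)
        bone = np.asarray(masks["inner_bone"], dtype=bool) | np.asarray(
            masks["outer_bone"], dtype=bool
        )
        rows.append(
            {
                "patient": i,
                "total_mae_original": mae(ct, sct, total_mask),
                "total_mae_modified": mae(ct, modified, total_mask),
                "soft_tissue_mae_original": mae(ct, sct, soft),
                "soft_tissue_mae_modified": mae(ct, modified, soft),
                "adipose_mae_original": mae(ct, sct, adipose),
                "adipose_mae_modified": mae(ct, modified, adipose),
                "total_bone_mae_original": mae(ct, sct, bone),
                "scope": "body" if total_mask is not None else "all_voxels",
            }
        )
    df = pd.DataFrame(rows)
    numeric = df.columns.drop(["patient", "scope"])
    means = df[numeric].mean()
    stds = df[numeric].std(ddof=1).fillna(0.0)
    scope = df["scope"].iloc[0]
    summary = pd.DataFrame(
        [
            {"patient": "mean", "scope": scope, **{c: float(means[c]) for c in numeric}},
            {"patient": "std", "scope": scope, **{c: float(stds[c]) for c in numeric}},
        ]
    )
    return pd.concat([df, summary], ignore_index=True)
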