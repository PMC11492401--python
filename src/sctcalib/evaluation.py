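"""Dose comparison: cumulative DVHs, D95 coverage ratios, and gamma analysis.

The gamma index combines a dose-difference criterion (percent, locally
normalized by default) with a distance-to-agreement (DTA) criterion: for each
reference voxel above the low-dose cutoff,

    gamma = min over nearby evaluated points of
            sqrt[ (dD / (tol * D_ref))^2 + (dr / DTA)^2 ]

with the evaluated dose trilinearly interpolated on a sub-voxel search
lattice. A voxel passes when gamma <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose import DoseVolume
from .volume import Volume3D

__all__ = ["DVH", "compute_dvh", "d95_ratio", "GammaCriteria", "GammaResult", "gamma_index"]


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    Stores the raw sorted dose samples; Dx / Vx metrics are derived by
    linear-interpolated order statistics (Dx = dose received by the hottest
    x% of the volume).
    """

    structure: str
    doses: np.ndarray  # sorted ascending, Gy

    def __post_init__(self):
        d = np.sort(np.asarray(self.doses, dtype=float).ravel())
        if d.size == 0:
            raise ValueError("DVH of an empty structure is undefined")
        self.doses = d

    def dose_at_volume(self, x: float) -> float:
        """D_x: dose (Gy) received by at least x% of the structure volume."""
        if not 0 <= x <= 100:
            raise ValueError("volume percentage must be in [0, 100]")
        return float(np.quantile(self.doses, 1.0 - x / 100.0))

    def volume_at_dose(self, d: float) -> float:
        """V_d: fraction of the structure receiving >= d Gy."""
        return float(np.mean(self.doses >= d))

    def cumulative(self, bins: int = 200) -> np.ndarray:
        """(dose, volume-fraction >= dose) table; non-increasing from 1."""
        edges = np.linspace(0.0, float(self.doses[-1]), bins)
        frac = 1.0 - np.searchsorted(self.doses, edges, side="left") / self.doses.size
        return np.column_stack([edges, frac])


def compute_dvh(dose: DoseVolume, mask: np.ndarray, structure: str = "structure") -> DVH:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.dose.shape:
        raise ValueError(f"mask shape {mask.shape} != dose shape {dose.dose.shape}")
    if not mask.any():
        raise ValueError("DVH mask is empty")
    return DVH(structure, np.asarray(dose.dose.values)[mask])


def d95_ratio(dose_sct: DoseVolume, dose_ct: DoseVolume, ptv: np.ndarray) -> float:
    """100 x D95(sCT dose) / D95(CT dose) on the PTV (percent)."""
    dose_sct.dose.assert_coregistered(dose_ct.dose)
    d95_s = compute_dvh(dose_sct, ptv, "ptv").dose_at_volume(95.0)
    d95_c = compute_dvh(dose_ct, ptv, "ptv").dose_at_volume(95.0)
    return 100.0 * d95_s / d95_c


# ---------------------------------------------------------------------------
# gamma index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaCriteria:
    """3%/3 mm local-normalization defaults with a 10%-of-prescription cutoff."""

    dose_tolerance: float = 0.03  # fraction of the normalization dose
    dta_mm: float = 3.0
    normalization: str = "local"  # local | global
    low_dose_cutoff: float = 0.10  # fraction of prescription
    search_radius_factor: float = 2.0  # search radius = factor * DTA
    search_step_divisor: float = 10.0  # step = DTA / divisor

    def __post_init__(self):
        if self.dose_tolerance <= 0 or self.dta_mm <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 <= self.low_dose_cutoff < 1:
            raise ValueError("low-dose cutoff must be in [0, 1)")
        if self.normalization not in ("local", "global"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class GammaResult:
    gamma_map: Volume3D  # NaN where not evaluated
    pass_rate: float  # percent of evaluated voxels with gamma <= 1
    n_evaluated: int
    criteria: GammaCriteria

    def __post_init__(self):
        if not 0 <= self.pass_rate <= 100:
            raise ValueError("pass rate must be in [0, 100]")


def _search_offsets(criteria: GammaCriteria, spacing):
    """Sub-voxel search offsets (mm) within the search radius, sorted by distance."""
    radius = criteria.search_radius_factor * criteria.dta_mm
    step = criteria.dta_mm / criteria.search_step_divisor
    k = int(np.floor(radius / step))
    axis = np.arange(-k, k + 1) * step
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist2 = np.sum(offsets**2, axis=1)
    keep = dist2 <= radius**2
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2, kind="stable")
    return offsets[order], dist2[order]


def gamma_index(
    reference: DoseVolume,
    evaluated: DoseVolume,
    criteria: GammaCriteria | None = None,
    prescription: float | None = None,
) -> GammaResult:
    """Gamma map and pass rate of ``evaluated`` against ``reference``.

    Reference voxels with dose below ``low_dose_cutoff * prescription`` are
    excluded (error if none remain). The minimum over the search neighborhood
    is found by scanning offsets in increasing-distance order with early
    termination once the distance term alone exceeds every remaining voxel's
    current best gamma — lossless with respect to the exhaustive search on
    the same lattice.
    """
    criteria = criteria or GammaCriteria()
    reference.dose.assert_coregistered(evaluated.dose)
    if prescription is None:
        prescription = float(np.max(reference.dose.values))
    ref_vals = np.asarray(reference.dose.values, dtype=float)
    cutoff = criteria.low_dose_cutoff * prescription
    eval_mask = ref_vals > cutoff
    if not eval_mask.any():
        raise ValueError("all reference voxels below the low-dose cutoff")

    spacing = np.array(reference.dose.spacing)
    origin = np.array(reference.dose.origin)
    idx = np.argwhere(eval_mask)
    pos = origin + idx * spacing  # world positions of evaluated voxels
    d_ref = ref_vals[eval_mask]
    denom = (
        criteria.dose_tolerance * d_ref
        if criteria.normalization == "local"
        else np.full_like(d_ref, criteria.dose_tolerance * prescription)
    )

    eval_arr = np.asarray(evaluated.dose.values, dtype=float)
    dta2 = criteria.dta_mm**2
    offsets, dist2 = _search_offsets(criteria, spacing)

    best = np.full(d_ref.shape, np.inf)
    active = np.arange(d_ref.size)
    pos_frac_base = (pos - origin) / spacing

    i = 0
    while i < len(offsets) and active.size:
        dist_term = dist2[i] / dta2
        # freeze voxels whose best gamma^2 can no longer improve
        still = best[active] > dist_term
        active = active[still]
        if not active.size:
            break
        coords = (pos_frac_base[active] + offsets[i] / spacing).T
        d_eval = ndimage.map_coordinates(eval_arr, coords, order=1, mode="nearest")
        g2 = ((d_eval - d_ref[active]) / denom[active]) ** 2 + dist_term
        np.minimum.at(best, active, g2)
        i += 1

    gamma_flat = np.sqrt(best)
    gamma_map = np.full(ref_vals.shape, np.nan)
    gamma_map[eval_mask] = gamma_flat
    pass_rate = 100.0 * float(np.mean(gamma_flat <= 1.0))
    return GammaResult(
        gamma_map=reference.dose.with_values(gamma_map),
        pass_rate=pass_rate,
        n_evaluated=int(d_ref.size),
        criteria=criteria,
    )
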