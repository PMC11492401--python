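"""Seeded digital pelvis phantoms: co-registered CT/sCT pairs with structures.

The generator emulates a prostate SBRT commissioning cohort. Each phantom is
an elliptical-cylinder body with an adipose shell, a soft-tissue interior, an
elliptical pelvic ring and two femoral heads (cortical shell + trabecular
core), and soft-tissue organs (PTV, bladder, rectum). The CT volume draws
independent Gaussian HU noise per class around the class CT mean; the sCT is
piecewise constant at the vendor bulk HU values. Three discrepancy artifacts
seen clinically between CT and sCT can be injected: a rectal gas pocket
present only on CT, intraprostatic fiducial markers present only on CT, and a
rigid femoral-head displacement present only on the sCT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .tissues import CLASS_NAMES, TissueClassSpec, classes_by_name, default_tissue_classes
from .volume import Volume3D, centered_origin

__all__ = [
    "PhantomSpec",
    "StructureSet",
    "generate_pair",
    "inject_artifacts",
    "generate_cohort",
]


class GeometryError(ValueError):
    """A phantom element does not fit where it must."""


@dataclass
class PhantomSpec:
    """Geometry, noise and artifact switches for one phantom.

    Lengths are mm; positions are world coordinates (grid centered at 0).
    The default grid (96 x 96 x 48 at 2 x 2 x 3 mm) is a 2x-coarsened version
    of a clinical ~1 x 1 x 1.5 mm pelvis acquisition so the full pipeline runs
    in minutes; clinical-scale grids are supported via these fields.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)

    body_semiaxes: tuple[float, float] = (80.0, 60.0)  # x, y of body ellipse
    adipose_thickness: float = 12.0  # subcutaneous shell

    ring_semiaxes: tuple[float, float] = (55.0, 40.0)  # pelvic ring path
    ring_tube_radius: float = 7.0
    ring_cortical_thickness: float = 3.0

    femoral_center: tuple[float, float, float] = (50.0, 0.0, -9.0)  # right; left mirrored
    femoral_radius: float = 15.0
    femoral_cortical_thickness: float = 3.0

    ptv_center: tuple[float, float, float] = (0.0, -12.0, -6.0)
    ptv_radius: float = 12.0
    bladder_center: tuple[float, float, float] = (0.0, 14.0, 0.0)
    bladder_radius: float = 14.0
    rectum_center: tuple[float, float, float] = (0.0, -34.0, -6.0)
    rectum_radius: float = 9.0

    # artifact switches (independent)
    gas_mismatch: bool = False
    gas_radius: float = 5.0
    fiducials: bool = False
    fiducial_hu: float = 1200.0
    bone_shift_mm: float = 0.0
    bone_shift_dir: tuple[float, float, float] = (-0.8, 0.0, 0.6)  # medial-superior

    seed: int = 0

    @property
    def origin(self) -> tuple[float, float, float]:
        return centered_origin(self.shape, self.spacing)


@dataclass
class StructureSet:
    """Named boolean masks sharing one grid (class masks + organs + body)."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks have inconsistent shapes: {shapes}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    def class_masks(self) -> dict[str, np.ndarray]:
        return {n: self.masks[n] for n in CLASS_NAMES if n in self.masks}

    def class_label_map(self) -> np.ndarray:
        """uint8 label map: 0 = unclassified, 1..5 in CLASS_NAMES order."""
        labels = np.zeros(self.shape, dtype=np.uint8)
        for i, name in enumerate(CLASS_NAMES, start=1):
            if name in self.masks:
                labels[self.masks[name]] = i
        return labels

    def to_nifti(self, path, legend_path=None) -> None:
        vol = Volume3D(self.class_label_map(), self.spacing, self.origin)
        vol.to_nifti(path)
        if legend_path is not None:
            legend = {str(i): n for i, n in enumerate(CLASS_NAMES, start=1)}
            legend["0"] = "unclassified"
            with open(legend_path, "w") as fh:
                json.dump(legend, fh, indent=1)


# ---------------------------------------------------------------------------
# geometry primitives (vectorized over the voxel grid)
# ---------------------------------------------------------------------------


def _grid_coords(spec: PhantomSpec):
    ref = Volume3D(np.zeros(spec.shape, dtype=np.float32), spec.spacing, spec.origin)
    return ref.voxel_centers()


def _ellipse_cylinder(x, y, ax, ay):
    return (x / ax) ** 2 + (y / ay) ** 2 <= 1.0


def _sphere(x, y, z, center, radius):
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def _ring_distance(x, y, z, semiaxes):
    """Pseudo-distance to an elliptical ring path in the z=0 plane.

    The nearest path point is approximated by the point at the same scaled
    polar angle; exact enough to define a smooth bony ring for a phantom.
    """
    rx, ry = semiaxes
    theta = np.arctan2(y / ry, x / rx)
    px = rx * np.cos(theta)
    py = ry * np.sin(theta)
    return np.sqrt((x - px) ** 2 + (y - py) ** 2 + z**2)


def _check_geometry(spec: PhantomSpec) -> None:
    half = [(n - 1) * s / 2.0 for n, s in zip(spec.shape, spec.spacing)]
    ax, ay = spec.body_semiaxes
    if ax > half[0] or ay > half[1]:
        raise GeometryError(
            f"body ellipse semi-axes {spec.body_semiaxes} exceed grid half-extent "
            f"({half[0]:.1f}, {half[1]:.1f}) mm"
        )
    if spec.adipose_thickness >= min(ax, ay):
        raise GeometryError("adipose shell thicker than the body semi-axes")
    for name, center, radius in [
        ("PTV", spec.ptv_center, spec.ptv_radius),
        ("bladder", spec.bladder_center, spec.bladder_radius),
        ("rectum", spec.rectum_center, spec.rectum_radius),
        ("right femoral head", spec.femoral_center, spec.femoral_radius),
    ]:
        cx, cy, cz = center
        # conservative containment check: bounding sphere inside the body ellipse
        scale = np.hypot(cx / ax, cy / ay)
        margin = radius / min(ax, ay)
        if scale + margin > 1.0:
            raise GeometryError(f"{name} extends outside the body ellipse")
        if abs(cz) + radius > half[2]:
            raise GeometryError(f"{name} extends outside the grid in z")


def _build_masks(spec: PhantomSpec) -> StructureSet:
    _check_geometry(spec)
    x, y, z = _grid_coords(spec)
    ax, ay = spec.body_semiaxes
    t = spec.adipose_thickness

    body = _ellipse_cylinder(x, y, ax, ay) & np.ones(spec.shape, dtype=bool)
    inner = _ellipse_cylinder(x, y, ax - t, ay - t) & np.ones(spec.shape, dtype=bool)

    ring_d = _ring_distance(x, y, z, spec.ring_semiaxes)
    ring = ring_d <= spec.ring_tube_radius
    ring_core = ring_d <= spec.ring_tube_radius - spec.ring_cortical_thickness

    fem_masks = {}
    bone = ring.copy()
    bone_core = ring_core.copy()
    cx, cy, cz = spec.femoral_center
    for side, sign in (("right", 1.0), ("left", -1.0)):
        c = (sign * cx, cy, cz)
        head = _sphere(x, y, z, c, spec.femoral_radius)
        core = _sphere(x, y, z, c, spec.femoral_radius - spec.femoral_cortical_thickness)
        fem_masks[f"femoral_head_{side}"] = head
        bone |= head
        bone_core |= core

    outer_bone = (bone & ~bone_core) & body
    inner_bone = bone_core & body

    # class partition by priority: bone > soft interior > adipose shell > air
    adipose = body & ~inner & ~outer_bone & ~inner_bone
    soft = inner & ~outer_bone & ~inner_bone
    air = ~body

    ptv = _sphere(x, y, z, spec.ptv_center, spec.ptv_radius)
    bladder = _sphere(x, y, z, spec.bladder_center, spec.bladder_radius)
    rectum = _sphere(x, y, z, spec.rectum_center, spec.rectum_radius)
    if np.any(ptv & (outer_bone | inner_bone)):
        raise GeometryError("PTV intersects bone")

    masks = {
        "air": air,
        "adipose": adipose,
        "soft_tissue": soft,
        "inner_bone": inner_bone,
        "outer_bone": outer_bone,
        "body": body,
        "ptv": ptv,
        "bladder": bladder,
        "rectum": rectum,
        "femoral_heads": fem_masks["femoral_head_right"] | fem_masks["femoral_head_left"],
        **fem_masks,
    }
    return StructureSet(masks, spec.spacing, spec.origin)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_pair(
    spec: PhantomSpec,
    classes: list[TissueClassSpec] | None = None,
    apply_artifacts: bool = True,
):
    """Generate one co-registered (CT, sCT, StructureSet) phantom triple.

    CT voxels are the class CT mean plus an independent Gaussian draw of the
    class std (seeded by ``spec.seed``); sCT voxels are exactly the class bulk
    HU. With ``apply_artifacts`` the phantom spec's artifact switches are honored.
    """
    classes = classes or default_tissue_classes()
    by_name = classes_by_name(classes)
    structs = _build_masks(spec)

    mean_map = np.zeros(spec.shape, dtype=np.float64)
    std_map = np.zeros(spec.shape, dtype=np.float64)
    bulk_map = np.zeros(spec.shape, dtype=np.float64)
    for name in CLASS_NAMES:
        c = by_name[name]
        m = structs[name]
        mean_map[m] = c.ct_mean_hu
        std_map[m] = c.ct_std_hu
        bulk_map[m] = c.sct_bulk_hu

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.shape)
    ct = Volume3D(mean_map + std_map * noise, spec.spacing, spec.origin)
    sct = Volume3D(bulk_map, spec.spacing, spec.origin)

    if apply_artifacts:
        ct, sct, structs = inject_artifacts(ct, sct, structs, spec, rng)
    return ct, sct, structs


def inject_artifacts(ct: Volume3D, sct: Volume3D, structs: StructureSet, spec: PhantomSpec, rng=None):
    """Apply the phantom spec's enabled CT/sCT discrepancy artifacts.

    gas_mismatch: an air pocket inside the rectum on CT only (bowel/rectal
    filling changed between scans). fiducials: three small high-HU markers in
    the PTV on CT only (gold seeds are signal voids on MRI and absent from the
    sCT). bone_shift_mm > 0: the right femoral head rigidly displaced on the
    sCT only, vacated voxels filled with soft-tissue bulk HU.

    Inputs are not mutated; with all switches off the originals are returned.
    """
    ct.assert_coregistered(sct)
    if not (spec.gas_mismatch or spec.fiducials or spec.bone_shift_mm):
        return ct, sct, structs

    classes = classes_by_name(default_tissue_classes())
    x, y, z = _grid_coords(spec)
    ct = ct.copy()
    sct = sct.copy()

    if spec.gas_mismatch:
        pocket = _sphere(x, y, z, spec.rectum_center, spec.gas_radius) & structs["rectum"]
        ct.values[pocket] = classes["air"].ct_mean_hu

    if spec.fiducials:
        px, py, pz = spec.ptv_center
        offsets = [(0.0, 0.0, 0.0), (5.0, 3.0, -3.0), (-5.0, -3.0, 3.0)]
        marker_r = 1.5 * min(spec.spacing)  # <= 3 voxel radius
        for ox, oy, oz in offsets:
            m = _sphere(x, y, z, (px + ox, py + oy, pz + oz), marker_r) & structs["ptv"]
            ct.values[m] = spec.fiducial_hu

    if spec.bone_shift_mm:
        d = np.asarray(spec.bone_shift_dir, dtype=float)
        d = d / np.linalg.norm(d)
        shift = tuple(spec.bone_shift_mm * d)
        cx, cy, cz = spec.femoral_center
        new_c = (cx + shift[0], cy + shift[1], cz + shift[2])
        # exact re-rasterization of the displaced head at its new center
        new_head = _sphere(x, y, z, new_c, spec.femoral_radius)
        new_core = _sphere(
            x, y, z, new_c, spec.femoral_radius - spec.femoral_cortical_thickness
        )
        # analytic containment: the displaced sphere must stay inside the body
        ax, ay = spec.body_semiaxes
        scale = np.hypot(new_c[0] / ax, new_c[1] / ay)
        if scale + spec.femoral_radius / min(ax, ay) > 1.0 or np.any(
            new_head & ~structs["body"]
        ):
            raise GeometryError("bone shift moves the femoral head outside the body")
        old_head = structs["femoral_head_right"]
        sct.values[old_head & ~new_head] = classes["soft_tissue"].sct_bulk_hu
        sct.values[new_head & ~new_core] = classes["outer_bone"].sct_bulk_hu
        sct.values[new_core] = classes["inner_bone"].sct_bulk_hu

    return ct, sct, structs


def patient_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Per-patient seed stream: SeedSequence(master, spawn_key=(index,)).

    Counter-based so a cohort can be extended without reshuffling existing
    patients.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    classes: list[TissueClassSpec] | None = None,
    jitter: float = 0.10,
    seed: int = 0,
):
    """Generate ``n`` independent phantom pairs with jittered geometry.

    Body semi-axes and organ radii are scaled by independent uniform factors
    in [1 - jitter, 1 + jitter] per patient, producing inter-patient MAE
    spread without claiming any particular anatomy. Fully reproducible from
    ``seed``; ``jitter=0, n=1`` reduces to ``generate_pair(base_spec)``.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base_spec = base_spec or PhantomSpec()
    out = []
    for i in range(n):
        ss = patient_seed(seed, i)
        rng = np.random.default_rng(ss)
        u = lambda: 1.0 + rng.uniform(-jitter, jitter)
        spec_i = replace(
            base_spec,
            body_semiaxes=(base_spec.body_semiaxes[0] * u(), base_spec.body_semiaxes[1] * u()),
            ptv_radius=base_spec.ptv_radius * u(),
            bladder_radius=base_spec.bladder_radius * u(),
            rectum_radius=base_spec.rectum_radius * u(),
            femoral_radius=base_spec.femoral_radius * u(),
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        out.append(generate_pair(spec_i, classes))
    return out


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump({"phantom": asdict(spec)}, fh)


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)["phantom"]
    for key in (
        "shape",
        "spacing",
        "body_semiaxes",
        "ring_semiaxes",
        "femoral_center",
        "ptv_center",
        "bladder_center",
        "rectum_center",
        "bone_shift_dir",
    ):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomSpec(**raw)
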