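"""End-to-end study replica: cohort -> segmentation -> curves -> HU and dose
comparison.

Per patient the workflow mirrors an MRI-only commissioning study: a plan is
built and normalized once on the CT-derived density volume, then recomputed
with frozen parameters on the sCT under two calibration arms:

* **original** — the vendor bulk sCT pushed through a curve anchored at the
  bulk HU values whose REDs come from evaluating the cohort CT calibration at
  those HUs (the pre-commissioning situation; wrong bulk HUs yield wrong
  effective path lengths);
* **optimized** — the modified sCT (the sCT's own adipose / soft-tissue bulk
  values remapped to the cohort CT class means, bone untouched) converted
  through the cohort-derived optimized curve.

The CT itself is converted with the cohort curve anchored at the CT class
means (bone included), the clinical CT-calibration analogue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve, CohortStats, build_original_curve, derive_optimized_curve
from .dose import compute_dose, make_plan
from .evaluation import GammaCriteria, compute_dvh, d95_ratio, gamma_index
from .hu_compare import cohort_mae_table, override_classes
from .phantom import PhantomSpec, generate_cohort, patient_seed
from .segmentation import ThresholdScheme, class_hu_stats, segment_classes
from .tissues import DEFAULT_RED_BY_CLASS, default_tissue_classes

logger = logging.getLogger("sctcalib")

__all__ = ["RunConfig", "CohortReport", "run_study"]


@dataclass
class RunConfig:
    """Everything a study run depends on, fixed before any stochastic step."""

    n_patients: int = 10
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(gas_mismatch=True, fiducials=True))
    thresholds: ThresholdScheme = field(default_factory=ThresholdScheme)
    red_by_class: dict = field(default_factory=lambda: dict(DEFAULT_RED_BY_CLASS))
    keep_sct_bone: bool = True
    plan_styles: tuple[str, ...] = ("arc", "robotic")
    prescription: float = 40.0
    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    jitter: float = 0.10
    noise_scale: float = 1.0  # multiplies every class's CT noise std
    master_seed: int = 17
    write_volumes: bool = False

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = _phantom_from_dict(kwargs["phantom"])
        if "thresholds" in kwargs:
            t = kwargs["thresholds"]
            kwargs["thresholds"] = ThresholdScheme(
                tuple(t["boundaries"]), t.get("opening_radius", 1)
            )
        if "gamma" in kwargs:
            kwargs["gamma"] = GammaCriteria(**kwargs["gamma"])
        if "plan_styles" in kwargs:
            kwargs["plan_styles"] = tuple(kwargs["plan_styles"])
        return cls(**kwargs)


def _phantom_from_dict(raw: dict) -> PhantomSpec:
    raw = dict(raw)
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


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class CohortReport:
    """Aggregated per-patient metrics plus the artifacts that produced them."""

    hu_stats: pd.DataFrame  # per-patient per-class HU statistics
    mae_table: pd.DataFrame  # original vs modified sCT MAE per patient
    plan_table: pd.DataFrame  # gamma pass rate and D95 ratio per style/arm
    curves: dict[str, CalibrationCurve]
    config_hash: str
    seeds: dict[str, int]

    def summary(self) -> pd.DataFrame:
        """Cohort mean ± std and min–max of gamma pass rate and D95 ratio."""
        rows = []
        for (style, arm), grp in self.plan_table.groupby(["style", "arm"]):
            for metric in ("gamma_pass_pct", "d95_ratio_pct"):
                v = grp[metric].to_numpy(dtype=float)
                rows.append(
                    {
                        "style": style,
                        "arm": arm,
                        "metric": metric,
                        "mean": v.mean(),
                        "std": v.std(ddof=1) if len(v) > 1 else 0.0,
                        "min": v.min(),
                        "max": v.max(),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.hu_stats.to_csv(out / "hu_stats.csv", index=False)
        self.mae_table.to_csv(out / "mae_table.csv", index=False)
        self.plan_table.to_csv(out / "plan_table.csv", index=False)
        self.summary().to_csv(out / "summary.csv", index=False)
        for name, curve in self.curves.items():
            curve.to_csv(out / f"curve_{name}.csv")
        meta = {"config_hash": self.config_hash, "seeds": self.seeds}
        (out / "provenance.json").write_text(json.dumps(meta, indent=1))
        (out / "report.md").write_text(self._markdown())

    def _markdown(self) -> str:
        lines = [
            f"# Cohort report (config {self.config_hash})",
            "",
            "## Per-class HU statistics (CT)",
            self.hu_stats.groupby("class")[["mean_hu", "std_hu"]].mean().to_markdown(),
            "",
            "## MAE, original vs modified sCT (HU)",
            self.mae_table.to_markdown(index=False),
            "",
            "## Gamma pass rate and D95 ratio per plan style and curve arm",
            self.summary().to_markdown(index=False),
            "",
        ]
        return "\n".join(lines)


def run_study(config: RunConfig, out_dir=None) -> CohortReport:
    """Run the full replica; bit-identical reports for identical configs."""
    t_start = time.time()
    from dataclasses import replace as _replace

    classes = [
        _replace(c, ct_std_hu=c.ct_std_hu * config.noise_scale)
        for c in default_tissue_classes()
    ]
    chash = config.config_hash()
    logger.info("run_study start: %d patients, hash %s", config.n_patients, chash)

    cohort = generate_cohort(
        config.n_patients, config.phantom, classes, config.jitter, config.master_seed
    )

    seg_sets, stats_frames, mask_dicts = [], [], []
    for i, (ct, sct, structs) in enumerate(cohort):
        seg = segment_classes(ct, config.thresholds)
        seg_sets.append(seg)
        stats_frames.append(class_hu_stats(ct, seg))
        mask_dicts.append({**seg.masks, "body": structs["body"]})
    cohort_stats = CohortStats.from_patients(stats_frames)
    logger.info("segmentation done (%.1f s)", time.time() - t_start)

    ct_curve = derive_optimized_curve(
        cohort_stats, config.red_by_class, keep_sct_bone=False
    )
    ct_curve.provenance = "ct_reference"
    # a tabulated clinical curve ends at its densest commissioned point;
    # cap extrapolation there so HU above the top anchor (dense cortex,
    # fiducials) saturates at the cortical-bone RED rather than over-densify
    ct_curve.max_red = float(ct_curve.anchors[-1, 1])
    optimized = derive_optimized_curve(
        cohort_stats, config.red_by_class, keep_sct_bone=config.keep_sct_bone
    )
    original = build_original_curve(classes, reference_curve=ct_curve)

    means = cohort_stats.class_means()
    override_hu = {"adipose": means["adipose"], "soft_tissue": means["soft_tissue"]}
    pairs = [(ct, sct) for ct, sct, _ in cohort]
    mae_table = cohort_mae_table(pairs, mask_dicts, override_hu)
    logger.info("HU comparison done (%.1f s)", time.time() - t_start)

    plan_rows = []
    for style in config.plan_styles:
        for i, (ct, sct, structs) in enumerate(cohort):
            seed_i = int(patient_seed(config.master_seed, 1000 + i).generate_state(1)[0] % (2**31))
            body = structs["body"]
            ptv = structs["ptv"]
            red_ct = ct_curve(ct)
            plan = make_plan(
                style, ptv, red_ct, body, prescription=config.prescription, seed=seed_i
            )
            dose_ct = compute_dose(plan, red_ct, body)
            # modified sCT: remap the sCT's own bulk palette (keeps any
            # sCT-only bone discrepancy in place, unlike a CT-mask override)
            sct_class_masks = {
                c.name: np.asarray(sct.values) == c.sct_bulk_hu
                for c in classes
                if c.name in override_hu
            }
            sct_mod = override_classes(sct, sct_class_masks, override_hu)
            arms = {
                "original": original(sct),
                "optimized": optimized(sct_mod),
            }
            for arm, red_sct in arms.items():
                dose_sct = compute_dose(plan, red_sct, body)
                gr = gamma_index(dose_ct, dose_sct, config.gamma, config.prescription)
                plan_rows.append(
                    {
                        "patient": i,
                        "style": style,
                        "arm": arm,
                        "gamma_pass_pct": gr.pass_rate,
                        "d95_ratio_pct": d95_ratio(dose_sct, dose_ct, ptv),
                        "d95_ct_gy": compute_dvh(dose_ct, ptv).dose_at_volume(95.0),
                        "d95_sct_gy": compute_dvh(dose_sct, ptv).dose_at_volume(95.0),
                        "n_gamma_voxels": gr.n_evaluated,
                        "plan_seed": seed_i,
                    }
                )
            logger.info(
                "patient %d style %s done (%.1f s)", i, style, time.time() - t_start
            )

    report = CohortReport(
        hu_stats=cohort_stats.per_patient,
        mae_table=mae_table,
        plan_table=pd.DataFrame(plan_rows),
        curves={"ct_reference": ct_curve, "original": original, "optimized": optimized},
        config_hash=chash,
        seeds={"master": config.master_seed},
    )
    if out_dir is not None:
        report.write(out_dir)
        if config.write_volumes:
            out = Path(out_dir)
            for i, (ct, sct, structs) in enumerate(cohort):
                ct.to_nifti(out / f"patient{i:02d}_ct.nii.gz")
                sct.to_nifti(out / f"patient{i:02d}_sct.nii.gz")
                structs.to_nifti(
                    out / f"patient{i:02d}_classes.nii.gz",
                    out / f"patient{i:02d}_classes.json",
                )
    logger.info("run_study finished in %.1f s", time.time() - t_start)
    return report
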