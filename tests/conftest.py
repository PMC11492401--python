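"""Shared fixtures: small phantoms for unit tests, a session-scoped default
cohort (with its segmentations and curves) for the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

import sctcalib as sc
from sctcalib.calibration import CohortStats
from sctcalib.segmentation import class_hu_stats, segment_classes


@pytest.fixture(scope="session")
def classes():
    return sc.default_tissue_classes()


@pytest.fixture()
def small_spec():
    """A compact phantom grid for fast unit tests."""
    return sc.PhantomSpec(shape=(64, 64, 32), spacing=(3.0, 3.0, 4.0), seed=11)


@pytest.fixture()
def noise_free_spec(small_spec):
    return small_spec


@pytest.fixture(scope="session")
def zero_noise_classes(classes):
    from dataclasses import replace

    return [replace(c, ct_std_hu=0.0) for c in classes]


@pytest.fixture(scope="session")
def default_cohort(classes):
    """Ten default-geometry phantoms with the clinically seen artifacts on."""
    base = sc.PhantomSpec(gas_mismatch=True, fiducials=True)
    return sc.generate_cohort(10, base, classes, jitter=0.10, seed=17)


@pytest.fixture(scope="session")
def cohort_segmentations(default_cohort):
    return [segment_classes(ct) for ct, _, _ in default_cohort]


@pytest.fixture(scope="session")
def cohort_stats(default_cohort, cohort_segmentations):
    frames = [
        class_hu_stats(ct, seg)
        for (ct, _, _), seg in zip(default_cohort, cohort_segmentations)
    ]
    return CohortStats.from_patients(frames)
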